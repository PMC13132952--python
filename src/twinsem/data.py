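"""Twin-pair data containers, readers, correlations and screening.

The central container is :class:`TwinDataset`, a thin wrapper around a wide
pandas DataFrame with one row per twin pair.  Columns follow a canonical
naming scheme ``"{variable}{wave}_{twin}"`` (e.g. ``wb1_1`` is twin 1's
wellbeing at wave 1) plus ``family_id``, ``zygosity`` and optional
``sex_1``/``sex_2``.  Missing values are represented as NaN internally;
readers normalise configurable missing codes to NaN on the way in.

Measures
--------
wb
    Cantril-ladder wellbeing, an ordinal 1-10 self-anchoring scale
    (1 = worst possible life, 10 = best possible life), treated as
    continuous in all models.
negdep, negind, posdep
    Counts of negative dependent (0-14), negative independent (0-19) and
    positive dependent (0-5) life events reported over the past year.
age
    Age in years at each wave.
"""

from __future__ import annotations

import io
import json
import math
import warnings
from dataclasses import dataclass, field, asdict
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MEASURE_BOUNDS",
    "WAVES",
    "TWINS",
    "TwinDataset",
    "CorrelationReport",
    "ScreeningDecision",
    "column_name",
    "read_twin_table",
    "phenotypic_correlations",
    "correlation_matrix",
    "twin_correlations",
    "residualize_on_age",
    "screen_event_category",
]

#: admissible [lo, hi] range of each bounded measure
MEASURE_BOUNDS: dict[str, tuple[float, float]] = {
    "wb": (1.0, 10.0),
    "negdep": (0.0, 14.0),
    "negind": (0.0, 19.0),
    "posdep": (0.0, 5.0),
}

WAVES: tuple[int, ...] = (1, 2, 3)
TWINS: tuple[int, ...] = (1, 2)

ZYGOSITY_CODES: dict[str, str] = {
    "MZ": "MZ", "DZ": "DZ", "mz": "MZ", "dz": "DZ",
    "1": "MZ", "2": "DZ", "monozygotic": "MZ", "dizygotic": "DZ",
}

DEFAULT_MISSING_CODES: tuple[str, ...] = ("", "NA", "NaN", "nan", ".", "-99", "-999")


def column_name(variable: str, wave: int, twin: int) -> str:
    """Canonical wide-format column name, e.g. ``column_name("wb", 1, 2) == "wb1_2"``."""
    return f"{variable}{wave}_{twin}"


def measure_columns(variables: Iterable[str] = MEASURE_BOUNDS) -> list[str]:
    return [column_name(v, w, t) for v in variables for w in WAVES for t in TWINS]


class TwinDataError(ValueError):
    """Raised for malformed or out-of-range twin-table input."""


@dataclass
class TwinDataset:
    """Wide-format collection of twin-pair records.

    Parameters
    ----------
    df : pandas.DataFrame
        One row per pair.  Must contain ``family_id`` and ``zygosity``
        ("MZ"/"DZ"); measure columns follow the canonical naming scheme.
    continuous : bool
        If True the bounded-measure range checks are skipped (used for
        simulated data before discretisation).
    """

    df: pd.DataFrame
    continuous: bool = False

    def __post_init__(self) -> None:
        if "family_id" not in self.df.columns or "zygosity" not in self.df.columns:
            raise TwinDataError("twin table needs 'family_id' and 'zygosity' columns")
        bad = set(self.df["zygosity"].dropna()) - {"MZ", "DZ"}
        if bad:
            raise TwinDataError(f"unknown zygosity codes: {sorted(bad)}")
        if self.df["zygosity"].isna().any():
            raise TwinDataError("zygosity missing for some records")
        if self.df["family_id"].duplicated().any():
            dups = self.df["family_id"][self.df["family_id"].duplicated()].tolist()
            raise TwinDataError(f"duplicate family_id values: {dups[:5]}")

    # -- basic views ---------------------------------------------------
    @property
    def n_pairs(self) -> int:
        return len(self.df)

    @property
    def variables(self) -> list[str]:
        """Measures present in the table (catalogue of base variable names)."""
        present = []
        for v in list(MEASURE_BOUNDS) + ["age"]:
            if any(column_name(v, w, t) in self.df.columns for w in WAVES for t in TWINS):
                present.append(v)
        return present

    def group(self, zygosity: str) -> "TwinDataset":
        sub = self.df[self.df["zygosity"] == zygosity].reset_index(drop=True)
        return TwinDataset(sub, continuous=self.continuous)

    @property
    def mz(self) -> "TwinDataset":
        return self.group("MZ")

    @property
    def dz(self) -> "TwinDataset":
        return self.group("DZ")

    def __len__(self) -> int:
        return len(self.df)

    # -- validation ----------------------------------------------------
    def validation_errors(self) -> list[str]:
        """Range violations for bounded measures, one message per offending cell."""
        if self.continuous:
            return []
        problems: list[str] = []
        for var, (lo, hi) in MEASURE_BOUNDS.items():
            for w in WAVES:
                for t in TWINS:
                    col = column_name(var, w, t)
                    if col not in self.df.columns:
                        continue
                    vals = self.df[col]
                    bad = vals.notna() & ((vals < lo) | (vals > hi))
                    for idx in self.df.index[bad]:
                        problems.append(
                            f"row {idx} (family {self.df.at[idx, 'family_id']}): "
                            f"{col}={float(vals[idx]):g} outside [{lo:g}, {hi:g}]"
                        )
        return problems

    def validate(self) -> None:
        problems = self.validation_errors()
        if problems:
            raise TwinDataError(
                "out-of-range values:\n" + "\n".join(problems[:20])
                + ("" if len(problems) <= 20 else f"\n... and {len(problems) - 20} more")
            )

    # -- matrix extraction for model fitting ---------------------------
    def pair_matrix(self, columns_per_twin: Sequence[tuple[str, int]]) -> dict[str, np.ndarray]:
        """Stacked per-pair observation matrices by zygosity group.

        ``columns_per_twin`` lists (variable, wave) in the within-twin
        observed order; the returned arrays have twin 1's block followed by
        twin 2's.  Rows with no observed value at all are dropped.
        """
        out: dict[str, np.ndarray] = {}
        for zyg in ("MZ", "DZ"):
            sub = self.df[self.df["zygosity"] == zyg]
            cols = [column_name(v, w, t) for t in TWINS for (v, w) in columns_per_twin]
            missing_cols = [c for c in cols if c not in sub.columns]
            if missing_cols:
                raise TwinDataError(f"columns absent from table: {missing_cols}")
            arr = sub[cols].to_numpy(dtype=float)
            keep = ~np.all(np.isnan(arr), axis=1)
            out[zyg] = arr[keep]
        return out

    def individuals(self, variables: Sequence[str] | None = None) -> pd.DataFrame:
        """Long view with twins as individual rows.

        Columns are ``"{var}{wave}"`` per measure plus family_id, zygosity
        and twin index.  Used for phenotypic correlations and
        age residualisation, where co-twins are treated as separate
        observations.
        """
        variables = list(variables) if variables is not None else self.variables
        frames = []
        for t in TWINS:
            cols = {column_name(v, w, t): f"{v}{w}"
                    for v in variables for w in WAVES
                    if column_name(v, w, t) in self.df.columns}
            sub = self.df[["family_id", "zygosity", *cols]].rename(columns=cols)
            sub = sub.assign(twin=t)
            frames.append(sub)
        return pd.concat(frames, ignore_index=True)

    # -- i/o -------------------------------------------------------------
    def to_csv(self, path_or_buf) -> None:
        """Write the canonical wide CSV dialect (UTF-8, header, NaN as empty)."""
        self.df.to_csv(path_or_buf, index=False)

    def copy(self) -> "TwinDataset":
        return TwinDataset(self.df.copy(), continuous=self.continuous)

    def __eq__(self, other: object) -> bool:  # type: ignore[override]
        if not isinstance(other, TwinDataset):
            return NotImplemented
        if list(self.df.columns) != list(other.df.columns) or len(self.df) != len(other.df):
            return False
        for c in self.df.columns:
            a, b = self.df[c], other.df[c]
            if a.dtype.kind in "fc" or b.dtype.kind in "fc":
                av = a.to_numpy(dtype=float)
                bv = b.to_numpy(dtype=float)
                same = np.isclose(av, bv, rtol=0, atol=1e-9) | (np.isnan(av) & np.isnan(bv))
                if not same.all():
                    return False
            elif not a.equals(b):
                return False
        return True


def read_twin_table(
    source,
    schema: Mapping[str, str] | None = None,
    missing_codes: Sequence[str] = DEFAULT_MISSING_CODES,
    zygosity_map: Mapping[str, str] | None = None,
    on_invalid: str = "error",
    continuous: bool = False,
) -> TwinDataset:
    """Read a wide twin-pair CSV into a :class:`TwinDataset`.

    Parameters
    ----------
    source : path or file-like
    schema : mapping, optional
        Maps external column names to canonical names
        (``{"wellbeing_w1_twin1": "wb1_1", ...}``).  Columns already in
        canonical form need no entry.
    missing_codes : sequence of str
        Tokens normalised to NaN.
    zygosity_map : mapping, optional
        Extra zygosity recodings merged over the defaults
        (MZ/DZ/mz/dz/1/2/monozygotic/dizygotic).
    on_invalid : {"error", "warn", "ignore"}
        What to do with out-of-range bounded measures.
    continuous : bool
        Mark the dataset as continuous (skip range checks), for simulated
        non-discretised data.
    """
    df = pd.read_csv(source, na_values=list(missing_codes), keep_default_na=True)
    if schema:
        df = df.rename(columns=dict(schema))
    if "zygosity" not in df.columns:
        raise TwinDataError("no zygosity column after applying schema")
    codes = dict(ZYGOSITY_CODES)
    if zygosity_map:
        codes.update(zygosity_map)
    zyg_raw = df["zygosity"].astype(str).str.strip()
    unknown = sorted(set(zyg_raw[~zyg_raw.isin(codes)]))
    if unknown:
        raise TwinDataError(f"unknown zygosity code(s): {unknown}")
    df["zygosity"] = zyg_raw.map(codes)
    for c in df.columns:
        if c in ("family_id", "zygosity") or c.startswith("sex"):
            continue
        df[c] = pd.to_numeric(df[c], errors="coerce")
    ds = TwinDataset(df, continuous=continuous)
    if not continuous:
        problems = ds.validation_errors()
        if problems:
            if on_invalid == "error":
                ds.validate()  # raises with the message
            elif on_invalid == "warn":
                warnings.warn(f"{len(problems)} out-of-range cells (first: {problems[0]})")
    return ds


# ---------------------------------------------------------------------------
# correlations
# ---------------------------------------------------------------------------

@dataclass
class CorrelationReport:
    """One pairwise Pearson correlation with its pairwise-complete n and p."""

    var1: str
    var2: str
    r: float
    n: int
    p: float
    significant: bool

    def to_dict(self) -> dict:
        return asdict(self)


def _pearson(x: np.ndarray, y: np.ndarray) -> tuple[float, int, float]:
    ok = ~(np.isnan(x) | np.isnan(y))
    n = int(ok.sum())
    if n < 3:
        return math.nan, n, math.nan
    xv, yv = x[ok], y[ok]
    if np.std(xv) == 0 or np.std(yv) == 0:
        return math.nan, n, math.nan
    r = float(np.corrcoef(xv, yv)[0, 1])
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * math.sqrt((n - 2) / (1 - r * r))
        p = 2 * stats.t.sf(abs(t), n - 2)
    return r, n, float(p)


def phenotypic_correlations(
    ds: TwinDataset,
    variables: Sequence[str],
    alpha: float = 0.05,
) -> list[CorrelationReport]:
    """All pairwise Pearson correlations between wave-specific variables.

    Twins are treated as individual observations with pairwise-complete
    deletion; p-values are naive two-sided t-transform values and do not
    correct for the family clustering of co-twins.

    ``variables`` are wave-specific labels such as ``"wb1"`` or
    ``"negdep3"`` (measure name followed by wave number).
    """
    long = ds.individuals()
    missing = [v for v in variables if v not in long.columns]
    if missing:
        raise TwinDataError(f"variables not in dataset: {missing}")
    reports = []
    for i, v1 in enumerate(variables):
        for v2 in variables[i:]:
            r, n, p = _pearson(long[v1].to_numpy(float), long[v2].to_numpy(float))
            if v1 == v2 and n >= 3:
                r, p = 1.0, 0.0
            reports.append(CorrelationReport(v1, v2, r, n, p,
                                             significant=bool(p == p and p < alpha)))
    return reports


def correlation_matrix(reports: Sequence[CorrelationReport]) -> pd.DataFrame:
    """Symmetric unit-diagonal matrix assembled from a report list."""
    labels = list(dict.fromkeys([r.var1 for r in reports] + [r.var2 for r in reports]))
    mat = pd.DataFrame(np.nan, index=labels, columns=labels)
    for rep in reports:
        mat.loc[rep.var1, rep.var2] = rep.r
        mat.loc[rep.var2, rep.var1] = rep.r
    for v in labels:
        mat.loc[v, v] = 1.0
    return mat


def reports_to_frame(reports: Sequence[CorrelationReport]) -> pd.DataFrame:
    return pd.DataFrame([r.to_dict() for r in reports])


def fisher_ci(r: float, n: int, level: float = 0.95) -> tuple[float, float]:
    """Fisher-z confidence interval tanh(atanh(r) +/- z/sqrt(n-3))."""
    if n <= 3 or not math.isfinite(r):
        return math.nan, math.nan
    z = stats.norm.ppf(0.5 + level / 2)
    h = z / math.sqrt(n - 3)
    return math.tanh(math.atanh(r) - h), math.tanh(math.atanh(r) + h)


def _profile_twin_ci(pairs: np.ndarray, level: float) -> tuple[float, float]:
    """Profile-likelihood CI for the cross-twin correlation.

    Fits the exchangeable bivariate-normal pair model (common mean and SD,
    correlation r = tanh(z)) by maximum likelihood and profiles z across
    the chi-square(1) likelihood-ratio boundary.
    """
    from .fiml import SourceLoadingModel, fit_source_model, profile_ci

    def loadings(th, g):
        s = th[1]
        r = math.tanh(th[2])
        return s * np.array([[1.0, 0.0], [r, math.sqrt(max(1 - r * r, 1e-12))]])

    model = SourceLoadingModel(
        "twin_pair", ["mu", "s", "z"], [(None, None), (1e-6, None), (-5.0, 5.0)],
        2, loadings=loadings, means=lambda th, g: np.array([th[0], th[0]]),
        start=lambda d: np.array([np.nanmean(pairs), max(np.nanstd(pairs), 1e-3), 0.0]))
    data = {"MZ": pairs}
    res = fit_source_model(model, data, n_starts=1)
    lo, hi = profile_ci(model, data, res, "z", level=level)
    return math.tanh(lo), math.tanh(hi)


def twin_correlations(
    ds: TwinDataset,
    variable: str,
    ci_level: float = 0.95,
    double_entry: bool = False,
    ci_method: str = "fisher",
) -> dict[str, dict]:
    """Cross-twin Pearson correlations by zygosity for one wave-specific variable.

    Parameters
    ----------
    variable : str
        Wave-specific label, e.g. ``"wb1"``.
    double_entry : bool
        If True each pair enters twice, as (twin1, twin2) and (twin2, twin1),
        which makes the estimate exactly invariant to twin ordering.  The
        Fisher CI then still uses the number of distinct pairs.
    ci_method : {"fisher", "profile", "none"}
        Fisher-z interval (default) or a profile-likelihood interval from
        an exchangeable bivariate-normal pair model.

    Returns ``{"MZ": {"r":..., "n":..., "ci": (lo, hi)}, "DZ": {...}}``.
    """
    out: dict[str, dict] = {}
    # variable like "wb1" -> base "wb", wave 1
    base = variable.rstrip("0123456789")
    wave = int(variable[len(base):])
    for zyg in ("MZ", "DZ"):
        sub = ds.df[ds.df["zygosity"] == zyg]
        x = sub[column_name(base, wave, 1)].to_numpy(float)
        y = sub[column_name(base, wave, 2)].to_numpy(float)
        ok = ~(np.isnan(x) | np.isnan(y))
        n = int(ok.sum())
        if n < 3:
            out[zyg] = {"r": math.nan, "n": n, "ci": (math.nan, math.nan),
                        "note": "fewer than 3 complete pairs"}
            continue
        xv, yv = x[ok], y[ok]
        if double_entry:
            xa = np.concatenate([xv, yv])
            ya = np.concatenate([yv, xv])
            r = float(np.corrcoef(xa, ya)[0, 1])
        else:
            r = float(np.corrcoef(xv, yv)[0, 1])
        if ci_method == "fisher":
            ci = fisher_ci(r, n, ci_level)
        elif ci_method == "profile":
            ci = _profile_twin_ci(np.column_stack([xv, yv]), ci_level)
        else:
            ci = (math.nan, math.nan)
        out[zyg] = {"r": r, "n": n, "ci": ci}
    return out


# ---------------------------------------------------------------------------
# age residualisation
# ---------------------------------------------------------------------------

def residualize_on_age(ds: TwinDataset, variable: str = "wb") -> TwinDataset:
    """Replace a measure by its within-wave OLS residual on age.

    Per wave, the measure is regressed on age across all twins as
    individuals, and each observation is replaced by its residual.
    Observations whose age is missing become missing in the output (the
    wave-specific age effect cannot be removed for them); the measure's
    missingness pattern is otherwise preserved.  If all ages in a wave are
    identical the slope is undefined and the measure is mean-centred with a
    warning.
    """
    out = ds.df.copy()
    for w in WAVES:
        ycols = [column_name(variable, w, t) for t in TWINS]
        acols = [column_name("age", w, t) for t in TWINS]
        for c in ycols + acols:
            if c not in out.columns:
                raise TwinDataError(f"column {c} required for age residualisation")
        y = np.concatenate([out[c].to_numpy(float) for c in ycols])
        a = np.concatenate([out[c].to_numpy(float) for c in acols])
        ok = ~(np.isnan(y) | np.isnan(a))
        resid = np.full_like(y, np.nan)
        if ok.sum() >= 2:
            av, yv = a[ok], y[ok]
            if np.ptp(av) == 0:
                warnings.warn(f"wave {w}: all ages identical; mean-centering instead")
                resid[ok] = yv - yv.mean()
            else:
                X = np.column_stack([np.ones(ok.sum()), av])
                beta, *_ = np.linalg.lstsq(X, yv, rcond=None)
                resid[ok] = yv - X @ beta
        half = len(out)
        out[ycols[0]] = resid[:half]
        out[ycols[1]] = resid[half:]
    return TwinDataset(out, continuous=True)


# ---------------------------------------------------------------------------
# event-category screening
# ---------------------------------------------------------------------------

@dataclass
class ScreeningDecision:
    """Include/exclude decision for a life-event category, with its rationale."""

    category: str
    include: bool
    threshold: float
    alpha: float
    driving: list[CorrelationReport] = field(default_factory=list)

    @property
    def rationale(self) -> str:
        if self.include:
            why = "; ".join(
                f"{c.var1}~{c.var2}: r={c.r:.2f} (p={c.p:.3g})" for c in self.driving
            )
            return f"included: non-negligible same-wave association with wellbeing ({why})"
        return (f"excluded: no same-wave correlation with wellbeing is both "
                f"non-negligible (|r| >= {self.threshold:g}) and significant "
                f"at alpha={self.alpha:g}")

    def to_json(self) -> str:
        d = {"category": self.category, "include": self.include,
             "threshold": self.threshold, "alpha": self.alpha,
             "rationale": self.rationale,
             "driving": [c.to_dict() for c in self.driving]}
        return json.dumps(d, indent=2)


def screen_event_category(
    reports: Sequence[CorrelationReport],
    category: str,
    wellbeing: str = "wb",
    threshold: float = 0.10,
    alpha: float = 0.05,
) -> ScreeningDecision:
    """Decide whether an event category enters the twin analyses.

    The category is kept only when at least one same-wave correlation with
    wellbeing is both non-negligible (|r| at or above ``threshold``) and
    significant; otherwise its associations are deemed negligible and it
    is excluded.
    """
    same_wave = []
    for rep in reports:
        pair = {rep.var1, rep.var2}
        for w in WAVES:
            if pair == {f"{wellbeing}{w}", f"{category}{w}"}:
                same_wave.append(rep)
    if not same_wave:
        raise TwinDataError(
            f"no same-wave correlations between '{category}' and '{wellbeing}' in reports"
        )
    driving = [c for c in same_wave
               if abs(c.r) >= threshold and c.r == c.r and c.significant]
    if driving:
        return ScreeningDecision(category, True, threshold, alpha, driving)
    return ScreeningDecision(category, False, threshold, alpha, same_wave)
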