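"""Genetically informative bivariate random-intercept cross-lagged panel model.

The RI-CLPM separates each of two traits — wellbeing (X) and a life-event
cluster (Y) — measured at three waves into a stable between-person part
(the random intercept, loading 1 on every wave) and wave-specific
within-person deviations.  Within-person deviations follow a first-order
vector autoregression

    w_1 = s_1,    w_{t+1} = T_t w_t + s_{t+1},

where T_t = [[beta_x, gamma_xy], [gamma_yx, beta_y]] carries the
autoregressive (beta) and cross-lagged (gamma) transmission, and the s_t
are wave-specific innovations.  Transmission is phenotypic: the lagged
paths act on the total within-person factors, while the random intercept,
the wave-1 deviation and each innovation are decomposed into additive
genetic (A), optionally shared environmental (C), and nonshared
environmental (E) parts via per-component 2x2 lower-triangular Cholesky
blocks.  A trait that excludes a component has that component's row and
column structurally zeroed.  Genetic sources correlate 1.0 across MZ and
0.5 across DZ co-twins; C is fully shared; E is twin-specific.

The observed vector of one pair stacks (X1, Y1, X2, Y2, X3, Y3) for each
twin; every observed variance decomposes exactly as
var(RI) + var(within) since all factor loadings are fixed at one.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data import TwinDataset
from .fiml import (
    FitResult,
    GENETIC_CORRELATION,
    SourceLoadingModel,
    delta_method,
    expected_moments,
    fit_independence,
    fit_saturated,
    fit_indices,
    fit_source_model,
    fix_params,
    likelihood_ratio_test,
    parameter_covariance,
    twin_source_columns,
)

__all__ = [
    "TraitComponentConfig",
    "RiclpmParams",
    "build_riclpm_model",
    "riclpm_param_names",
    "within_covariances",
    "ri_variance_shares",
    "standardize_paths",
    "variance_explained",
    "GeneticRICLPM",
    "GeneticRiclpmResults",
    "CONSTRAINT_SETS",
]

LEVELS = ("ri", "w1", "i2", "i3")
_LEVEL_DOC = {"ri": "random intercept", "w1": "wave-1 within", "i2": "innovation w2",
              "i3": "innovation w3"}
_PATHS = ("xx", "xy", "yx", "yy")  # T[0,0], T[0,1], T[1,0], T[1,1]

#: named nested-model constraint sets (paths fixed at zero);
#: "xy" means the effect of trait Y at wave w on trait X at wave w+1
CONSTRAINT_SETS: dict[str, tuple[str, ...]] = {
    "no_crosslags": ("t1_xy", "t1_yx", "t2_xy", "t2_yx"),
    "no_events_to_wb": ("t1_xy", "t2_xy"),
    "no_wb_to_events": ("t1_yx", "t2_yx"),
    "no_autoregressive": ("t1_xx", "t1_yy", "t2_xx", "t2_yy"),
    "no_lagged": ("t1_xx", "t1_xy", "t1_yx", "t1_yy",
                  "t2_xx", "t2_xy", "t2_yx", "t2_yy"),
}


@dataclass(frozen=True)
class TraitComponentConfig:
    """Which A/C/E components each trait's variance is decomposed into.

    E is mandatory for both traits (it absorbs measurement error).  The
    default matches the study design: wellbeing AE, and AE for negative
    dependent events or ACE for negative independent events.
    """

    x_components: tuple[str, ...] = ("A", "E")
    y_components: tuple[str, ...] = ("A", "E")

    def __post_init__(self):
        for name, comps in (("x", self.x_components), ("y", self.y_components)):
            bad = set(comps) - {"A", "C", "E"}
            if bad:
                raise ValueError(f"unknown components for {name}: {sorted(bad)}")
            if "E" not in comps:
                raise ValueError(f"trait {name} must include E")

    @property
    def union(self) -> tuple[str, ...]:
        return tuple(c for c in ("A", "C", "E")
                     if c in self.x_components or c in self.y_components)

    def traits_with(self, comp: str) -> tuple[bool, bool]:
        return (comp in self.x_components, comp in self.y_components)


def _block_entries(config: TraitComponentConfig, comp: str) -> list[str]:
    in_x, in_y = config.traits_with(comp)
    if in_x and in_y:
        return ["11", "21", "22"]
    return ["11"] if in_x else ["22"]


def riclpm_param_names(config: TraitComponentConfig) -> list[str]:
    names = []
    for level in LEVELS:
        for comp in config.union:
            names += [f"{level}_{comp.lower()}_{e}" for e in _block_entries(config, comp)]
    for t in ("t1", "t2"):
        names += [f"{t}_{p}" for p in _PATHS]
    names += [f"mu_{tr}{w}" for w in (1, 2, 3) for tr in ("x", "y")]
    return names


@dataclass
class RiclpmParams:
    """Raw parameters of the genetic RI-CLPM.

    ``blocks[level][comp]`` is the 2x2 lower-triangular Cholesky factor of
    that component's covariance contribution over (X, Y) at that level;
    ``t1``/``t2`` are the lagged-path matrices of the two transitions;
    ``mu`` holds the six means in observed order (x1, y1, x2, y2, x3, y3).
    """

    blocks: dict[str, dict[str, np.ndarray]]
    t1: np.ndarray
    t2: np.ndarray
    mu: np.ndarray
    config: TraitComponentConfig = field(default_factory=TraitComponentConfig)

    def transition(self, w: int) -> np.ndarray:
        return self.t1 if w == 1 else self.t2

    def block_cov(self, level: str, comp: str) -> np.ndarray:
        B = self.blocks[level].get(comp)
        if B is None:
            return np.zeros((2, 2))
        return B @ B.T

    def level_cov(self, level: str) -> np.ndarray:
        return sum((self.block_cov(level, c) for c in self.config.union),
                   np.zeros((2, 2)))

    def to_theta(self) -> np.ndarray:
        out = []
        for level in LEVELS:
            for comp in self.config.union:
                B = self.blocks[level][comp]
                for e in _block_entries(self.config, comp):
                    i, j = int(e[0]) - 1, int(e[1]) - 1
                    out.append(B[i, j])
        out += list(self.t1.ravel())
        out += list(self.t2.ravel())
        out += list(self.mu)
        return np.array(out, dtype=float)

    @classmethod
    def from_theta(cls, theta: np.ndarray,
                   config: TraitComponentConfig) -> "RiclpmParams":
        theta = np.asarray(theta, dtype=float)
        pos = 0
        blocks: dict[str, dict[str, np.ndarray]] = {}
        for level in LEVELS:
            blocks[level] = {}
            for comp in config.union:
                B = np.zeros((2, 2))
                for e in _block_entries(config, comp):
                    i, j = int(e[0]) - 1, int(e[1]) - 1
                    B[i, j] = theta[pos]
                    pos += 1
                blocks[level][comp] = B
        t1 = theta[pos:pos + 4].reshape(2, 2); pos += 4
        t2 = theta[pos:pos + 4].reshape(2, 2); pos += 4
        mu = theta[pos:pos + 6]
        return cls(blocks=blocks, t1=t1, t2=t2, mu=mu, config=config)


def build_riclpm_model(
    config: TraitComponentConfig = TraitComponentConfig(),
    constraints: Iterable[str] | str | None = None,
) -> SourceLoadingModel:
    """Source-loading model of the genetic RI-CLPM over one twin pair.

    Free parameters: per level (RI, wave-1, two innovations) one Cholesky
    block per included component, the eight lagged paths, and six means
    equated across co-twins and zygosity groups.  AE/AE gives q=38; adding
    C on one trait gives q=42.  ``constraints`` fixes named paths at zero
    (a name from :data:`CONSTRAINT_SETS` or an iterable of parameter
    names), producing the nested models used in likelihood-ratio tests.
    """
    names = riclpm_param_names(config)
    bounds: list[tuple] = []
    for n in names:
        if n.startswith(("t1_", "t2_")):
            bounds.append((-3.0, 3.0))
        elif n.startswith("mu_"):
            bounds.append((None, None))
        elif n.endswith(("_11", "_22")):
            bounds.append((0.0, None))   # Cholesky diagonals: sign convention
        else:
            bounds.append((None, None))

    I2 = np.eye(2)
    Z2 = np.zeros((2, 2))

    def loadings(theta, group):
        p = RiclpmParams.from_theta(theta, config)
        rbar = GENETIC_CORRELATION[group]
        phi = {
            "ri": np.vstack([I2, I2, I2]),
            "w1": np.vstack([I2, p.t1, p.t2 @ p.t1]),
            "i2": np.vstack([Z2, I2, p.t2]),
            "i3": np.vstack([Z2, Z2, I2]),
        }
        cols: list[np.ndarray] = []
        for level in LEVELS:
            for comp in config.union:
                M = phi[level] @ p.blocks[level][comp]
                cols += twin_source_columns(M, comp, rbar)
        return np.hstack(cols)

    def means(theta, group):
        mu = theta[-6:]
        return np.concatenate([mu, mu])

    def start(data):
        stacked = np.vstack([np.asarray(Y, float) for Y in data.values() if len(Y)])
        mu0 = np.empty(6)
        var_x = []
        var_y = []
        for j in range(6):
            vals = np.concatenate([stacked[:, j], stacked[:, j + 6]])
            vals = vals[~np.isnan(vals)]
            mu0[j] = np.mean(vals) if vals.size else 0.0
            v = float(np.var(vals)) if vals.size > 1 else 1.0
            (var_x if j % 2 == 0 else var_y).append(max(v, 1e-3))
        vbar = (float(np.mean(var_x)), float(np.mean(var_y)))
        theta0 = []
        for level in LEVELS:
            frac = 0.3 if level == "ri" else 0.7
            for comp in config.union:
                in_x, in_y = config.traits_with(comp)
                k = (len(config.x_components), len(config.y_components))
                for e in _block_entries(config, comp):
                    if e == "21":
                        theta0.append(0.0)
                    elif e == "11":
                        theta0.append(math.sqrt(frac * vbar[0] / k[0]))
                    else:
                        theta0.append(math.sqrt(frac * vbar[1] / k[1]))
        theta0 += [0.2, 0.0, 0.0, 0.2]   # t1
        theta0 += [0.2, 0.0, 0.0, 0.2]   # t2
        theta0 += list(mu0)
        return np.array(theta0)

    slm = SourceLoadingModel(
        name=f"riclpm_x{''.join(config.x_components)}_y{''.join(config.y_components)}",
        param_names=names, bounds=bounds, n_observed=12,
        loadings=loadings, means=means, start=start,
    )
    if constraints:
        if isinstance(constraints, str):
            constraints = CONSTRAINT_SETS[constraints]
        slm = fix_params(slm, {c: 0.0 for c in constraints})
    return slm


# ---------------------------------------------------------------------------
# derived quantities
# ---------------------------------------------------------------------------

def within_covariances(params: RiclpmParams) -> list[np.ndarray]:
    """Within-person factor covariances V1, V2, V3 from the lag recursion."""
    V1 = params.level_cov("w1")
    V2 = params.t1 @ V1 @ params.t1.T + params.level_cov("i2")
    V3 = params.t2 @ V2 @ params.t2.T + params.level_cov("i3")
    return [V1, V2, V3]


def ri_variance_shares(params: RiclpmParams) -> pd.DataFrame:
    """Random-intercept variance shares and the A/C/E split of the RI.

    Rows x (wellbeing) and y (events); columns ``wave{w}`` give the share
    of total observed variance due to the random intercept at that wave,
    and one column per component gives that component's share of the RI
    variance (the component columns sum to 1 per trait).
    """
    ri_total = params.level_cov("ri")
    V = within_covariances(params)
    rows = {}
    for i, trait in enumerate(("x", "y")):
        total_ri = ri_total[i, i]
        row = {}
        for w in range(3):
            tot = total_ri + V[w][i, i]
            if tot <= 0:
                raise ValueError(f"non-positive total variance ({trait}, wave {w+1})")
            row[f"wave{w + 1}"] = total_ri / tot
        for comp in params.config.union:
            row[comp] = (params.block_cov("ri", comp)[i, i] / total_ri
                         if total_ri > 0 else math.nan)
        rows[trait] = row
    return pd.DataFrame(rows).T


def standardize_paths(params: RiclpmParams) -> pd.DataFrame:
    """Standardised lagged paths: raw * SD(predictor factor) / SD(outcome factor).

    One row per path and transition; ``xy`` is the cross-lag from Y at
    wave w to X at wave w+1.
    """
    V = within_covariances(params)
    sd = [np.sqrt(np.diag(v)) for v in V]
    recs = []
    for w in (1, 2):
        T = params.transition(w)
        for i, out_tr in enumerate(("x", "y")):
            for j, pred_tr in enumerate(("x", "y")):
                raw = T[i, j]
                denom = sd[w][i]
                std = raw * sd[w - 1][j] / denom if denom > 0 else math.nan
                recs.append({
                    "path": f"t{w}_{out_tr}{pred_tr}",
                    "transition": f"w{w}->w{w + 1}",
                    "outcome": out_tr, "predictor": pred_tr,
                    "raw": raw, "std": std,
                })
    return pd.DataFrame(recs).set_index("path")


def variance_explained(std_coef: float) -> float:
    """Fraction of outcome variance a standardized lagged path accounts for."""
    return float(std_coef) ** 2


def _derived_vector(theta: np.ndarray, config: TraitComponentConfig) -> np.ndarray:
    """Flattened (shares | std paths) map used for delta-method SEs."""
    p = RiclpmParams.from_theta(theta, config)
    shares = ri_variance_shares(p).to_numpy().ravel()
    paths = standardize_paths(p)["std"].to_numpy()
    return np.concatenate([shares, paths])


# ---------------------------------------------------------------------------
# Model / Results
# ---------------------------------------------------------------------------

class GeneticRICLPM:
    """Genetically informative RI-CLPM for wellbeing and one event cluster.

    Parameters
    ----------
    data : TwinDataset or mapping
        Dataset, or prebuilt ``{"MZ": array, "DZ": array}`` of stacked
        12-column pair observations in order (X1,Y1,X2,Y2,X3,Y3) x twin.
    wellbeing, events : str
        Base measure names (trait X and trait Y).
    event_components : str, optional
        "AE" or "ACE" for the event trait.  Defaults by cluster:
        negative dependent events AE, negative independent events ACE
        (shared environment matters for events outside the person's
        control, e.g. parental divorce hits both co-twins).
    constraints : str or iterable, optional
        Paths fixed at zero (see :data:`CONSTRAINT_SETS`).
    """

    def __init__(self, data, wellbeing: str = "wb", events: str = "negdep",
                 event_components: str | None = None,
                 waves: Sequence[int] = (1, 2, 3),
                 constraints: Iterable[str] | str | None = None):
        if event_components is None:
            event_components = "ACE" if events == "negind" else "AE"
        self.wellbeing = wellbeing
        self.events = events
        self.waves = tuple(waves)
        self.config = TraitComponentConfig(("A", "E"), tuple(event_components))
        self.constraints = constraints
        if isinstance(data, TwinDataset):
            cols = [(v, w) for w in self.waves for v in (wellbeing, events)]
            self.data = data.pair_matrix(cols)
        else:
            self.data = {g: np.asarray(Y, float) for g, Y in data.items()}
        self.slm = build_riclpm_model(self.config, constraints)

    def fit(self, n_starts: int = 3, seed: int | None = 0, compute_se: bool = True,
            start: np.ndarray | None = None, **fit_kwargs) -> "GeneticRiclpmResults":
        fr = fit_source_model(self.slm, self.data, n_starts=n_starts, seed=seed,
                              start=start, **fit_kwargs)
        cov = None
        if compute_se:
            cov = parameter_covariance(self.slm, fr, self.data)
            fr.bse = np.sqrt(np.where(np.diag(cov) > 0, np.diag(cov), np.nan))
            fr.bse_reliable = bool(np.isfinite(fr.bse).all())
        return GeneticRiclpmResults(self, fr, cov=cov)


class GeneticRiclpmResults:
    """Fitted genetic RI-CLPM: variance shares, standardised paths, LRTs."""

    def __init__(self, model: GeneticRICLPM, fitresult: FitResult,
                 cov: np.ndarray | None = None):
        self.model = model
        self.fitresult = fitresult
        self.cov = cov

    # -- parameter access ------------------------------------------------
    def _full_theta(self, theta: np.ndarray | None = None) -> np.ndarray:
        th = self.fitresult.params if theta is None else theta
        expand = getattr(self.model.slm, "expand", None)
        return expand(th) if expand is not None else np.asarray(th, float)

    @property
    def params(self) -> RiclpmParams:
        return RiclpmParams.from_theta(self._full_theta(), self.model.config)

    @property
    def minus2ll(self) -> float:
        return self.fitresult.minus2ll

    @property
    def aic(self) -> float:
        return self.fitresult.aic

    @property
    def converged(self) -> bool:
        return self.fitresult.converged

    def implied_moments(self, group: str):
        return expected_moments(self.model.slm, self.fitresult.params, group)

    # -- derived quantities ----------------------------------------------
    def _derived(self, with_se: bool) -> tuple[np.ndarray, np.ndarray | None]:
        cfg = self.model.config
        fun = lambda th: _derived_vector(self._full_theta(th), cfg)
        vals = fun(self.fitresult.params)
        if not with_se or self.cov is None:
            return vals, None
        vals, ses = delta_method(fun, self.fitresult.params, self.cov)
        return vals, ses

    def ri_variance_shares(self, ci: bool = True) -> pd.DataFrame:
        """RI share of total variance per wave and A/C/E split of the RI."""
        table = ri_variance_shares(self.params)
        vals, ses = self._derived(ci)
        if ses is not None:
            n = table.shape[1]
            se_mat = ses[:2 * n].reshape(2, n)
            for j, col in enumerate(list(table.columns)):
                table[f"{col}_se"] = se_mat[:, j]
        return table

    def standardized_paths(self, ci: bool = True) -> pd.DataFrame:
        """Raw and standardised lagged paths, with delta-method SEs."""
        table = standardize_paths(self.params)
        if self.fitresult.bse is not None:
            raw_se = dict(zip(self.fitresult.param_names, self.fitresult.bse))
            table["raw_se"] = [raw_se.get(p, math.nan) for p in table.index]
        vals, ses = self._derived(ci)
        if ses is not None:
            n_shares = ri_variance_shares(self.params).size
            table["std_se"] = ses[n_shares:]
            z = table["std"] / table["std_se"]
            table["significant"] = np.abs(z) > stats.norm.ppf(0.975)
        return table

    # -- nested-model tests ----------------------------------------------
    def test_lagged_paths(self, which: str | Iterable[str] = "no_crosslags",
                          n_starts: int = 1, **fit_kwargs) -> dict:
        """LRT of the full model against one with the named paths fixed at 0.

        ``which`` is a name from :data:`CONSTRAINT_SETS` or an iterable of
        path parameter names.  The nested fit starts from the full-model
        solution with the constrained entries removed.
        """
        if self.model.constraints:
            raise ValueError("LRT must start from the unconstrained model")
        names = CONSTRAINT_SETS[which] if isinstance(which, str) else tuple(which)
        sub = fix_params(self.model.slm, {n: 0.0 for n in names})
        keep = [i for i, n in enumerate(self.model.slm.param_names) if n not in names]
        start = self.fitresult.params[keep]
        nested = fit_source_model(sub, self.model.data, n_starts=n_starts,
                                  start=start, **fit_kwargs)
        lrt = likelihood_ratio_test(self.fitresult, nested)
        return {"constrained": list(names), "nested": nested, "lrt": lrt}

    def fit_statistics(self):
        sat = fit_saturated(self.model.data)
        ind = fit_independence(self.model.data)
        return fit_indices(self.fitresult, sat, ind)

    # -- reports -----------------------------------------------------------
    def _trait_label(self, tr: str) -> str:
        return self.model.wellbeing if tr == "x" else self.model.events

    def stability_table(self) -> pd.DataFrame:
        """RI variance shares per wave and the RI component split, as percents."""
        tab = self.ri_variance_shares(ci=False)
        out = (100 * tab).round(0).astype(int)
        out.index = [self._trait_label(t) for t in out.index]
        return out

    def crosslag_table(self) -> pd.DataFrame:
        """Cross-lagged standardised estimates in report style ('est (se)')."""
        tab = self.standardized_paths(ci=True)
        cross = tab[tab["outcome"] != tab["predictor"]].copy()
        rows = []
        for p, r in cross.iterrows():
            wav = int(r["transition"][1])
            label = (f"{self._trait_label(r['predictor'])}_w{wav} -> "
                     f"{self._trait_label(r['outcome'])}_w{wav + 1}")
            cell = f"{r['std']:.2f}"
            if "std_se" in cross.columns and r["std_se"] == r["std_se"]:
                cell += f" ({r['std_se']:.3f})"
            rows.append({"path": label, "standardized": cell})
        return pd.DataFrame(rows).set_index("path")

    def summary(self) -> str:
        lines = [
            f"Genetic RI-CLPM: X={self.model.wellbeing} "
            f"({''.join(self.model.config.x_components)}), "
            f"Y={self.model.events} ({''.join(self.model.config.y_components)})",
            f"  -2lnL = {self.minus2ll:.3f}   AIC = {self.aic:.3f}   "
            f"q = {self.fitresult.n_free}   converged = {self.converged}",
            f"  pairs: " + ", ".join(f"{g}={n}" for g, n in self.fitresult.n_rows.items()),
            "",
            "Random-intercept variance shares (of total, per wave) and RI split:",
        ]
        tab = self.ri_variance_shares(ci=False)
        for t, row in tab.iterrows():
            lines.append(
                f"  {self._trait_label(t)}: " +
                "  ".join(f"{c}={100 * v:.0f}%" for c, v in row.items()))
        lines += ["", "Standardised lagged paths:"]
        sp = self.standardized_paths(ci=self.cov is not None)
        for p, r in sp.iterrows():
            se = f" ({r['std_se']:.3f})" if "std_se" in sp.columns else ""
            lines.append(f"  {p} [{r['transition']}]: std={r['std']:+.3f}{se} "
                         f"raw={r['raw']:+.3f}")
        return "\n".join(lines)

    def to_json(self) -> str:
        d = self.fitresult.to_dict()
        d["ri_variance_shares"] = json.loads(self.ri_variance_shares(ci=False).to_json())
        d["standardized_paths"] = json.loads(
            self.standardized_paths(ci=self.cov is not None).to_json())
        return json.dumps(d, indent=2)
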