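"""Synthetic twin-pair data with the covariance structure the models assume.

The generator draws independent standard-normal sources per pair, maps
them through a model's loading matrix (genetic sources shared via the
MZ/DZ splitting rule, C shared, E twin-specific) and adds the means, so
simulated data match :func:`twinsem.fiml.expected_moments` by
construction.  Wave participation is injected as a missing-completely-at-
random draw over the seven observed participation patterns, and an
optional discretisation step coarsens the continuous values to the
bounded ordinal scales of the questionnaire measures.

Study-scale defaults emulate the source cohort: 2,879 twins from 1,483
families (1,094 MZ / 1,785 DZ twins, here 550 MZ and 890 DZ complete
pairs), participation counts (1132, 613, 179, 78, 710, 97, 70) over the
patterns (123, 12, 13, 23, 1, 2, 3), and per-wave ages 15.2 (1.9),
16.9 (2.0) and 19.6 (1.9) years.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cholesky import CholeskyParams, build_cholesky_model
from .data import MEASURE_BOUNDS, TwinDataset, column_name
from .riclpm import RiclpmParams, TraitComponentConfig, build_riclpm_model

__all__ = [
    "PARTICIPATION_PATTERNS",
    "PARTICIPATION_COUNTS",
    "STUDY",
    "study_pattern_weights",
    "DiscretizeRule",
    "DEFAULT_DISCRETIZE_RULES",
    "SimulationScenario",
    "simulate_pairs",
    "apply_missingness",
    "discretize",
    "wellbeing_cholesky_params",
    "riclpm_study_params",
    "study_scenario",
]

#: the seven wave-participation patterns (waves a twin responded in)
PARTICIPATION_PATTERNS: tuple[str, ...] = ("123", "12", "13", "23", "1", "2", "3")

#: twins observed with each pattern in the source cohort
PARTICIPATION_COUNTS: tuple[int, ...] = (1132, 613, 179, 78, 710, 97, 70)

#: source-cohort facts used for study-scale presets
STUDY: dict = {
    "n_twins": 2879,
    "n_families": 1483,
    "n_mz_twins": 1094,
    "n_dz_twins": 1785,
    "n_mz_pairs": 550,
    "n_dz_pairs": 890,
    "age_mean": (15.2, 16.9, 19.6),
    "age_sd": (1.9, 2.0, 1.9),
    "female_fraction": 0.56,
}


def study_pattern_weights() -> np.ndarray:
    w = np.array(PARTICIPATION_COUNTS, dtype=float)
    return w / w.sum()


@dataclass(frozen=True)
class DiscretizeRule:
    """Affine rescale to (target_mean, target_sd), round half-up, clamp to [lo, hi]."""

    target_mean: float | None
    target_sd: float | None
    lo: float
    hi: float


DEFAULT_DISCRETIZE_RULES: dict[str, DiscretizeRule] = {
    "wb": DiscretizeRule(7.5, 1.6, *MEASURE_BOUNDS["wb"]),
    "negdep": DiscretizeRule(2.5, 2.0, *MEASURE_BOUNDS["negdep"]),
    "negind": DiscretizeRule(1.5, 1.4, *MEASURE_BOUNDS["negind"]),
    "posdep": DiscretizeRule(2.0, 1.2, *MEASURE_BOUNDS["posdep"]),
}


@dataclass
class SimulationScenario:
    """Everything needed to draw one synthetic twin dataset.

    ``kind`` selects the generating model ("cholesky" or "riclpm");
    ``params`` is the matching parameter object.  ``pattern_weights`` is
    None for complete data or a 7-vector over
    :data:`PARTICIPATION_PATTERNS`; ``discretize`` turns coarsening on
    (off by default, so recovery isolates estimator bias from coarsening
    bias).
    """

    kind: str
    params: CholeskyParams | RiclpmParams
    n_mz: int = STUDY["n_mz_pairs"]
    n_dz: int = STUDY["n_dz_pairs"]
    pattern_weights: Sequence[float] | None = None
    discretize: bool = False
    discretize_rules: Mapping[str, DiscretizeRule] = field(
        default_factory=lambda: dict(DEFAULT_DISCRETIZE_RULES))
    include_age: bool = False
    seed: int = 0
    x_var: str = "wb"
    y_var: str = "negdep"

    def __post_init__(self):
        if self.kind not in ("cholesky", "riclpm"):
            raise ValueError("kind must be 'cholesky' or 'riclpm'")
        if self.n_mz < 1 or self.n_dz < 1:
            raise ValueError("need at least one pair per zygosity group")
        if self.pattern_weights is not None:
            w = np.asarray(self.pattern_weights, dtype=float)
            if w.shape != (len(PARTICIPATION_PATTERNS),) or (w < 0).any() or w.sum() <= 0:
                raise ValueError("pattern_weights must be 7 non-negative weights")

    def model(self):
        if self.kind == "cholesky":
            return build_cholesky_model(self.params.components, self.params.n_vars)
        return build_riclpm_model(self.params.config)

    def observed_layout(self) -> list[tuple[str, int]]:
        """(variable, wave) pairs in within-twin observed order."""
        if self.kind == "cholesky":
            return [(self.x_var, w) for w in range(1, self.params.n_vars + 1)]
        return [(v, w) for w in (1, 2, 3) for v in (self.x_var, self.y_var)]

    def with_seed(self, seed: int) -> "SimulationScenario":
        return replace(self, seed=int(seed))


def simulate_pairs(scenario: SimulationScenario,
                   rng: np.random.Generator | None = None) -> TwinDataset:
    """Draw a twin dataset from the scenario's generating model.

    Deterministic given the scenario seed.  Missingness and
    discretisation are applied when the scenario requests them.
    """
    rng = np.random.default_rng(scenario.seed) if rng is None else rng
    model = scenario.model()
    theta = scenario.params.to_theta()
    layout = scenario.observed_layout()
    frames = []
    fam = 0
    for zyg, n in (("MZ", scenario.n_mz), ("DZ", scenario.n_dz)):
        L = model.loadings(theta, zyg)
        mu = model.means(theta, zyg)
        Z = rng.standard_normal((n, L.shape[1]))
        X = Z @ L.T + mu
        cols = {}
        k = len(layout)
        for t in (1, 2):
            for j, (v, w) in enumerate(layout):
                cols[column_name(v, w, t)] = X[:, (t - 1) * k + j]
        df = pd.DataFrame(cols)
        df.insert(0, "family_id", [f"F{fam + i:05d}" for i in range(n)])
        df.insert(1, "zygosity", zyg)
        fam += n
        frames.append(df)
    df = pd.concat(frames, ignore_index=True)
    if scenario.include_age:
        for w in (1, 2, 3):
            age = rng.normal(STUDY["age_mean"][w - 1], STUDY["age_sd"][w - 1], len(df))
            df[column_name("age", w, 1)] = age   # co-twins share birth date
            df[column_name("age", w, 2)] = age
    ds = TwinDataset(df, continuous=True)
    if scenario.pattern_weights is not None:
        ds = apply_missingness(ds, scenario.pattern_weights, rng=rng)
    if scenario.discretize:
        ds = discretize(ds, scenario.discretize_rules)
    return ds


def apply_missingness(
    ds: TwinDataset,
    pattern_weights: Sequence[float],
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> TwinDataset:
    """MCAR wave-participation injection over the seven patterns.

    Each twin independently draws a pattern; all measures of waves the
    twin did not participate in are blanked (ages too — age is recorded at
    participation).  Every pattern includes at least one wave, so all
    families are retained.
    """
    w = np.asarray(pattern_weights, dtype=float)
    if w.shape != (len(PARTICIPATION_PATTERNS),) or (w < 0).any() or w.sum() <= 0:
        raise ValueError("pattern_weights must be 7 non-negative weights with mass")
    w = w / w.sum()
    rng = np.random.default_rng(seed) if rng is None else rng
    df = ds.df.copy()
    n = len(df)
    measures = [c for c in df.columns
                if c not in ("family_id", "zygosity") and not c.startswith("sex")]
    for t in (1, 2):
        picks = rng.choice(len(PARTICIPATION_PATTERNS), size=n, p=w)
        for i, pat in enumerate(PARTICIPATION_PATTERNS):
            rows = picks == i
            if not rows.any():
                continue
            for wave in (1, 2, 3):
                if str(wave) in pat:
                    continue
                for c in measures:
                    if c.endswith(f"_{t}") and c[:-2].endswith(str(wave)):
                        df.loc[rows, c] = np.nan
    return TwinDataset(df, continuous=ds.continuous)


def discretize(ds: TwinDataset,
               rules: Mapping[str, DiscretizeRule] = DEFAULT_DISCRETIZE_RULES) -> TwinDataset:
    """Coarsen continuous simulated measures to their bounded ordinal scales.

    Each measure is affinely rescaled to the rule's target mean/SD (using
    its pooled observed mean/SD; identity when targets are None), rounded
    half-up (floor(x + 0.5)) and clamped to [lo, hi].
    """
    df = ds.df.copy()
    for var, rule in rules.items():
        cols = [column_name(var, w, t) for w in (1, 2, 3) for t in (1, 2)
                if column_name(var, w, t) in df.columns]
        if not cols:
            continue
        vals = df[cols].to_numpy(dtype=float)
        if rule.target_mean is not None and rule.target_sd is not None:
            m = np.nanmean(vals)
            s = np.nanstd(vals)
            if s > 0:
                vals = (vals - m) / s * rule.target_sd + rule.target_mean
        vals = np.floor(vals + 0.5)
        vals = np.clip(vals, rule.lo, rule.hi)
        df[cols] = vals
    return TwinDataset(df, continuous=False)


# ---------------------------------------------------------------------------
# generating-parameter presets (study conditions)
# ---------------------------------------------------------------------------

def wellbeing_cholesky_params() -> CholeskyParams:
    """AE Cholesky generating truth for three-wave wellbeing.

    Standardised heritabilities (0.48, 0.46, 0.26) with the remainder
    nonshared environment, on a unit-variance scale.  Cross-wave genetic
    correlations are high (stability is mostly genetic) and nonshared
    environmental correlations low, giving phenotypic cross-wave
    stability around 0.4-0.5.
    """
    a2 = np.array([0.48, 0.46, 0.26])
    e2 = 1.0 - a2
    r_a = np.array([[1.0, 0.80, 0.70],
                    [0.80, 1.0, 0.80],
                    [0.70, 0.80, 1.0]])
    r_e = np.array([[1.0, 0.20, 0.15],
                    [0.20, 1.0, 0.20],
                    [0.15, 0.20, 1.0]])
    A = np.sqrt(np.outer(a2, a2)) * r_a
    E = np.sqrt(np.outer(e2, e2)) * r_e
    return CholeskyParams(a=np.linalg.cholesky(A), c=None,
                          e=np.linalg.cholesky(E),
                          mu=np.array([7.7, 7.5, 7.3]), components="AE")


def _component_block(dx: float, dy: float, r: float) -> np.ndarray:
    """Cholesky factor of [[dx, r*sqrt(dx*dy)], [., dy]] with structural zeros."""
    if dx <= 0 and dy <= 0:
        return np.zeros((2, 2))
    if dx <= 0:
        return np.array([[0.0, 0.0], [0.0, math.sqrt(dy)]])
    if dy <= 0:
        return np.array([[math.sqrt(dx), 0.0], [0.0, 0.0]])
    return np.array([[math.sqrt(dx), 0.0],
                     [r * math.sqrt(dy), math.sqrt(dy * (1.0 - r * r))]])


def riclpm_study_params(event: str = "negdep") -> RiclpmParams:
    """Generating truth for the genetic RI-CLPM at the study conditions.

    On a unit-total-variance scale per trait and wave:

    - wellbeing (X): RI variance 0.40 split 81% A / 19% E; within-person
      variance 0.60 per wave, wave-1 split so total wave-1 heritability is
      0.48 (within split 26% A / 74% E);
    - negative dependent events (Y, AE): RI variance 0.35 split 70/30,
      within 0.65 split 39.2% A (total heritability 0.50);
    - negative independent events (Y, ACE): RI variance 0.20 split
      25% A / 50% C / 25% E, within 0.80 split 16% A / 39% C / 45% E
      (heritability ~0.18, shared environment ~0.41);
    - standardized lagged paths: autoregression 0.25 (X) and 0.30 (Y);
      cross-lags from the study's estimates for the chosen event cluster
      (negdep: -0.11 and -0.02 onto wellbeing, -0.08 and -0.10 onto
      events; negind: -0.01/-0.05 and -0.01/-0.01);
    - cross-trait correlations -0.40 (RI level), -0.15 (wave-1),
      -0.10 (innovations).

    Innovation variances are solved from the lag recursion so every
    within-person factor has exactly the target variance, which makes the
    generating standardized paths and RI shares exact.
    """
    if event == "negdep":
        cfg = TraitComponentConfig(("A", "E"), ("A", "E"))
        ri_var = {"x": 0.40, "y": 0.35}
        ri_split = {"x": {"A": 0.81, "E": 0.19}, "y": {"A": 0.70, "E": 0.30}}
        within_var = {"x": 0.60, "y": 0.65}
        within_split = {"x": {"A": 0.26, "E": 0.74}, "y": {"A": 0.392, "E": 0.608}}
        std_t1 = np.array([[0.25, -0.11], [-0.08, 0.30]])
        std_t2 = np.array([[0.25, -0.02], [-0.10, 0.30]])
        mu = np.array([7.7, 2.5, 7.5, 2.4, 7.3, 2.3])
    elif event == "negind":
        cfg = TraitComponentConfig(("A", "E"), ("A", "C", "E"))
        ri_var = {"x": 0.40, "y": 0.20}
        ri_split = {"x": {"A": 0.81, "E": 0.19},
                    "y": {"A": 0.25, "C": 0.50, "E": 0.25}}
        within_var = {"x": 0.60, "y": 0.80}
        within_split = {"x": {"A": 0.26, "E": 0.74},
                        "y": {"A": 0.16, "C": 0.39, "E": 0.45}}
        std_t1 = np.array([[0.25, -0.01], [-0.01, 0.30]])
        std_t2 = np.array([[0.25, -0.05], [-0.01, 0.30]])
        mu = np.array([7.7, 1.5, 7.5, 1.5, 7.3, 1.5])
    else:
        raise ValueError("event must be 'negdep' or 'negind'")
    corr = {"ri": -0.40, "w1": -0.15, "innov": -0.10}

    def split_blocks(total: dict[str, float], split: dict[str, dict[str, float]],
                     r: float) -> dict[str, np.ndarray]:
        out = {}
        for comp in cfg.union:
            dx = total["x"] * split["x"].get(comp, 0.0)
            dy = total["y"] * split["y"].get(comp, 0.0)
            out[comp] = _component_block(dx, dy, r)
        return out

    blocks = {
        "ri": split_blocks(ri_var, ri_split, corr["ri"]),
        "w1": split_blocks(within_var, within_split, corr["w1"]),
    }
    sd = np.sqrt([within_var["x"], within_var["y"]])
    # raw path = standardized * SD(outcome at w+1) / SD(predictor at w)
    t1 = std_t1 * np.outer(sd, 1.0 / sd)
    t2 = std_t2 * np.outer(sd, 1.0 / sd)

    # innovations keep every within-person factor at its target variance
    V_prev = sum(B @ B.T for B in blocks["w1"].values())
    for level, T in (("i2", t1), ("i3", t2)):
        carried = T @ V_prev @ T.T
        psi = {"x": within_var["x"] - carried[0, 0],
               "y": within_var["y"] - carried[1, 1]}
        if min(psi.values()) <= 0:
            raise ValueError("lagged paths too large for the target variances")
        blocks[level] = split_blocks(psi, within_split, corr["innov"])
        V_prev = carried + sum(B @ B.T for B in blocks[level].values())
    return RiclpmParams(blocks=blocks, t1=t1, t2=t2, mu=mu, config=cfg)


def scenario_from_config(source) -> SimulationScenario:
    """Build a study-scale scenario from a YAML/JSON mapping or file path.

    Recognised keys: ``kind`` (cholesky|riclpm), ``event`` (negdep|negind),
    ``n_mz``, ``n_dz``, ``realism`` (bool), ``seed``.
    """
    if isinstance(source, Mapping):
        cfg = dict(source)
    else:
        import yaml
        from pathlib import Path
        cfg = yaml.safe_load(Path(source).read_text())
    known = {"kind", "event", "n_mz", "n_dz", "realism", "seed"}
    unknown = set(cfg) - known
    if unknown:
        raise ValueError(f"unknown scenario keys: {sorted(unknown)}")
    return study_scenario(
        kind=cfg.get("kind", "riclpm"), event=cfg.get("event", "negdep"),
        realism=bool(cfg.get("realism", False)), seed=int(cfg.get("seed", 0)),
        n_mz=cfg.get("n_mz"), n_dz=cfg.get("n_dz"))


def study_scenario(kind: str = "riclpm", event: str = "negdep",
                   realism: bool = False, seed: int = 0,
                   n_mz: int | None = None, n_dz: int | None = None) -> SimulationScenario:
    """Study-scale scenario preset.

    ``realism=True`` switches on the study's participation-pattern
    missingness and discretisation; the default keeps complete continuous
    data so recovery isolates estimator bias.
    """
    if kind == "cholesky":
        params = wellbeing_cholesky_params()
    else:
        params = riclpm_study_params(event)
    return SimulationScenario(
        kind=kind, params=params,
        n_mz=STUDY["n_mz_pairs"] if n_mz is None else n_mz,
        n_dz=STUDY["n_dz_pairs"] if n_dz is None else n_dz,
        pattern_weights=study_pattern_weights() if realism else None,
        discretize=realism, include_age=realism,
        seed=seed, y_var=event,
    )
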