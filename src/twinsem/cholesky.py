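"""Trivariate Cholesky ACE/AE decomposition of a three-wave phenotype.

The biometric Cholesky model writes each variance component's covariance
contribution as the square of a lower-triangular path matrix,

    Sigma_twin = a a' + c c' + e e',

which keeps every component matrix positive semi-definite for any path
values.  Cross-twin covariance is r * a a' + c c' with r = 1 (MZ) or
0.5 (DZ).  Standardised per-wave shares a2/c2/e2 divide each component's
diagonal by the total phenotypic variance; a2 is the heritability.

Sign indeterminacy of the paths is resolved by constraining the diagonal
entries non-negative (off-diagonals stay free), a pure reparameterisation
with identical fit.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data import TwinDataset
from .fiml import (
    FitResult,
    SourceLoadingModel,
    delta_method,
    expected_moments,
    fit_independence,
    fit_saturated,
    fit_indices,
    fit_source_model,
    parameter_covariance,
    profile_ci,
    twin_source_columns,
)

__all__ = [
    "CholeskyParams",
    "build_cholesky_model",
    "standardized_components",
    "CholeskyACE",
    "CholeskyACEResults",
    "compare_ace_ae",
    "AceAeComparison",
]

_COMPONENTS = {"AE": ("a", "e"), "ACE": ("a", "c", "e"), "E": ("e",)}


def _tril_names(prefix: str, k: int) -> list[str]:
    return [f"{prefix}{i + 1}{j + 1}" for i in range(k) for j in range(i + 1)]


@dataclass
class CholeskyParams:
    """Lower-triangular path matrices and means of a Cholesky decomposition."""

    a: np.ndarray | None
    c: np.ndarray | None
    e: np.ndarray
    mu: np.ndarray
    components: str = "AE"

    def __post_init__(self):
        self.components = self.components.upper()
        if self.components not in _COMPONENTS:
            raise ValueError(f"components must be one of {sorted(_COMPONENTS)}")
        for m in self.matrices().values():
            if not np.allclose(m, np.tril(m)):
                raise ValueError("path matrices must be lower triangular")

    @property
    def n_vars(self) -> int:
        return self.e.shape[0]

    def matrices(self) -> dict[str, np.ndarray]:
        out = {}
        for name in _COMPONENTS[self.components]:
            m = getattr(self, name)
            if m is None:
                raise ValueError(f"component matrix '{name}' missing")
            out[name] = np.asarray(m, dtype=float)
        return out

    def component_covariances(self) -> dict[str, np.ndarray]:
        """A = aa', C = cc', E = ee' (only the included components)."""
        return {n.upper(): m @ m.T for n, m in self.matrices().items()}

    def total_covariance(self) -> np.ndarray:
        return sum(self.component_covariances().values())

    def to_theta(self) -> np.ndarray:
        tril = np.tril_indices(self.n_vars)
        parts = [m[tril] for m in self.matrices().values()]
        parts.append(np.asarray(self.mu, dtype=float))
        return np.concatenate(parts)

    @classmethod
    def from_theta(cls, theta: np.ndarray, components: str = "AE",
                   n_vars: int = 3) -> "CholeskyParams":
        theta = np.asarray(theta, dtype=float)
        tril = np.tril_indices(n_vars)
        m = tril[0].size
        mats: dict[str, np.ndarray] = {}
        pos = 0
        for name in _COMPONENTS[components.upper()]:
            M = np.zeros((n_vars, n_vars))
            M[tril] = theta[pos:pos + m]
            mats[name] = M
            pos += m
        mu = theta[pos:pos + n_vars]
        return cls(a=mats.get("a"), c=mats.get("c"), e=mats["e"], mu=mu,
                   components=components.upper())


def build_cholesky_model(components: str = "AE", n_vars: int = 3) -> SourceLoadingModel:
    """Source-loading twin model for an n-variate Cholesky decomposition.

    Free parameters: one lower triangle (n(n+1)/2 paths) per included
    component plus n means equated across co-twins and zygosity groups.
    AE at n=3 has q=15; ACE has q=21.
    """
    components = components.upper()
    comp_names = _COMPONENTS[components]
    tril = np.tril_indices(n_vars)
    m = tril[0].size
    names = []
    bounds: list[tuple] = []
    for cname in comp_names:
        names += _tril_names(cname, n_vars)
        bounds += [(0.0, None) if i == j else (None, None)
                   for i, j in zip(*tril)]
    names += [f"mu{w + 1}" for w in range(n_vars)]
    bounds += [(None, None)] * n_vars

    from .fiml import GENETIC_CORRELATION

    def unpack(theta):
        return CholeskyParams.from_theta(theta, components, n_vars)

    def loadings(theta, group):
        p = unpack(theta)
        rbar = GENETIC_CORRELATION[group]
        cols: list[np.ndarray] = []
        for cname, mat in p.matrices().items():
            cols += twin_source_columns(mat, cname.upper(), rbar)
        return np.hstack(cols)

    def means(theta, group):
        mu = theta[-n_vars:]
        return np.concatenate([mu, mu])

    def start(data):
        stacked = np.vstack([np.asarray(Y, float) for Y in data.values() if len(Y)])
        per_var = np.empty(n_vars)
        mu0 = np.empty(n_vars)
        for j in range(n_vars):
            vals = np.concatenate([stacked[:, j], stacked[:, j + n_vars]])
            vals = vals[~np.isnan(vals)]
            per_var[j] = np.var(vals) if vals.size > 1 else 1.0
            mu0[j] = np.mean(vals) if vals.size else 0.0
        k = len(comp_names)
        theta0 = []
        for cname in comp_names:
            M = np.zeros((n_vars, n_vars))
            np.fill_diagonal(M, np.sqrt(np.maximum(per_var, 1e-6) / k))
            theta0.append(M[tril])
        theta0.append(mu0)
        return np.concatenate(theta0)

    def source_labels(group):
        labels = []
        for cname in comp_names:
            kind = cname.upper()
            if kind == "C":
                labels += [f"C{j+1}:both" for j in range(n_vars)]
            elif kind == "E":
                labels += [f"E{j+1}:t1" for j in range(n_vars)]
                labels += [f"E{j+1}:t2" for j in range(n_vars)]
            else:
                labels += [f"A{j+1}:common" for j in range(n_vars)]
                if GENETIC_CORRELATION[group] < 1:
                    labels += [f"A{j+1}:t1" for j in range(n_vars)]
                    labels += [f"A{j+1}:t2" for j in range(n_vars)]
        return labels

    return SourceLoadingModel(
        name=f"cholesky_{components}", param_names=names, bounds=bounds,
        n_observed=2 * n_vars, loadings=loadings, means=means, start=start,
        source_labels=source_labels,
    )


def standardized_components(params: CholeskyParams) -> pd.DataFrame:
    """Per-wave standardised variance shares (a2, c2, e2 sum to 1)."""
    comps = params.component_covariances()
    total = sum(comps.values())
    tv = np.diag(total)
    if np.any(tv <= 0):
        raise ValueError("total variance must be positive at every wave")
    rows = {}
    for name, mat in comps.items():
        rows[f"{name.lower()}2"] = np.diag(mat) / tv
    return pd.DataFrame(rows, index=[f"wave{w + 1}" for w in range(params.n_vars)])


def implied_twin_correlations(params: CholeskyParams) -> pd.DataFrame:
    """Model-implied cross-twin correlations per wave (for AE: rMZ=a2, rDZ=a2/2)."""
    comps = params.component_covariances()
    total_d = np.diag(sum(comps.values()))
    a_d = np.diag(comps.get("A", np.zeros_like(sum(comps.values()))))
    c_d = np.diag(comps.get("C", np.zeros((params.n_vars, params.n_vars))))
    return pd.DataFrame({
        "rMZ": (a_d + c_d) / total_d,
        "rDZ": (0.5 * a_d + c_d) / total_d,
    }, index=[f"wave{w + 1}" for w in range(params.n_vars)])


# ---------------------------------------------------------------------------
# Model / Results
# ---------------------------------------------------------------------------

class CholeskyACE:
    """Cholesky twin model for one phenotype over several waves.

    Parameters
    ----------
    data : TwinDataset or mapping
        Either a dataset (the wide twin table) or a prebuilt mapping
        ``{"MZ": array, "DZ": array}`` of stacked pair observations.
    variable : str
        Base measure name in the dataset (default "wb").
    components : {"AE", "ACE", "E"}
    waves : tuple of int

    Examples
    --------
    >>> res = CholeskyACE(ds, components="AE").fit(seed=0)
    >>> res.standardized_components()  # doctest: +SKIP
    """

    def __init__(self, data, variable: str = "wb", components: str = "AE",
                 waves: Sequence[int] = (1, 2, 3)):
        self.variable = variable
        self.components = components.upper()
        self.waves = tuple(waves)
        if isinstance(data, TwinDataset):
            self.data = data.pair_matrix([(variable, w) for w in self.waves])
        else:
            self.data = {g: np.asarray(Y, float) for g, Y in data.items()}
        self.slm = build_cholesky_model(self.components, len(self.waves))

    def fit(self, n_starts: int = 5, seed: int | None = 0, compute_se: bool = True,
            ci_method: str = "delta", ci_level: float = 0.95,
            **fit_kwargs) -> "CholeskyACEResults":
        fr = fit_source_model(self.slm, self.data, n_starts=n_starts, seed=seed,
                              **fit_kwargs)
        cov = None
        if compute_se:
            cov = parameter_covariance(self.slm, fr, self.data)
            fr.bse = np.sqrt(np.where(np.diag(cov) > 0, np.diag(cov), np.nan))
            fr.bse_reliable = bool(np.isfinite(fr.bse).all())
        return CholeskyACEResults(self, fr, cov=cov, ci_method=ci_method,
                                  ci_level=ci_level)


class CholeskyACEResults:
    """Fitted Cholesky decomposition: estimates, shares, CIs, fit statistics."""

    def __init__(self, model: CholeskyACE, fitresult: FitResult,
                 cov: np.ndarray | None = None, ci_method: str = "delta",
                 ci_level: float = 0.95):
        self.model = model
        self.fitresult = fitresult
        self.cov = cov
        self.ci_method = ci_method
        self.ci_level = ci_level

    @property
    def params(self) -> CholeskyParams:
        return CholeskyParams.from_theta(
            self.fitresult.params, self.model.components, len(self.model.waves))

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

    def standardized_components(self, ci: bool = True) -> pd.DataFrame:
        """Standardised shares per wave, with delta-method CIs when available."""
        comps = self.model.components
        n_vars = len(self.model.waves)
        table = standardized_components(self.params)
        if not ci or self.cov is None:
            return table

        def shares_fun(theta):
            p = CholeskyParams.from_theta(theta, comps, n_vars)
            return standardized_components(p).to_numpy().ravel(order="F")

        vals, ses = delta_method(shares_fun, self.fitresult.params, self.cov)
        z = stats.norm.ppf(0.5 + self.ci_level / 2)
        k = 0
        for col in list(table.columns):
            table[f"{col}_se"] = ses[k:k + n_vars]
            table[f"{col}_lo"] = np.clip(vals[k:k + n_vars] - z * ses[k:k + n_vars], 0, 1)
            table[f"{col}_hi"] = np.clip(vals[k:k + n_vars] + z * ses[k:k + n_vars], 0, 1)
            k += n_vars
        return table

    def profile_ci(self, name: str, level: float = 0.95) -> tuple[float, float]:
        """Profile-likelihood CI for one raw path or mean parameter."""
        se = None
        if self.fitresult.bse is not None:
            se = float(self.fitresult.bse[self.model.slm.index(name)])
        return profile_ci(self.model.slm, self.model.data, self.fitresult, name,
                          level=level, se_hint=se)

    def fit_statistics(self):
        sat = fit_saturated(self.model.data)
        ind = fit_independence(self.model.data)
        return fit_indices(self.fitresult, sat, ind)

    def decomposition_table(self, dataset: TwinDataset | None = None) -> pd.DataFrame:
        """Twin correlations plus standardised shares, one row per wave."""
        out = self.standardized_components(ci=True)
        if dataset is not None:
            from .data import twin_correlations
            for i, w in enumerate(self.model.waves):
                tc = twin_correlations(dataset, f"{self.model.variable}{w}")
                out.loc[f"wave{i + 1}", "rMZ"] = tc["MZ"]["r"]
                out.loc[f"wave{i + 1}", "rDZ"] = tc["DZ"]["r"]
        return out

    def summary(self) -> str:
        p = self.params
        lines = [
            f"Cholesky {self.model.components} decomposition of "
            f"'{self.model.variable}' over waves {self.model.waves}",
            f"  -2lnL = {self.minus2ll:.3f}   AIC = {self.aic:.3f}   "
            f"q = {self.fitresult.n_free}   converged = {self.converged}",
            f"  pairs: " + ", ".join(f"{g}={n}" for g, n in self.fitresult.n_rows.items()),
            "", "Standardised variance components:",
        ]
        tab = self.standardized_components(ci=self.cov is not None)
        share_cols = [c for c in tab.columns if len(c) == 2]
        for w in tab.index:
            parts = []
            for cname in share_cols:
                v = tab.loc[w, cname]
                if f"{cname}_lo" in tab.columns:
                    parts.append(f"{cname}={v:.2f} [{tab.loc[w, cname + '_lo']:.2f}, "
                                 f"{tab.loc[w, cname + '_hi']:.2f}]")
                else:
                    parts.append(f"{cname}={v:.2f}")
            lines.append(f"  {w}: " + "  ".join(parts))
        lines += ["", "Means: " + np.array2string(p.mu, precision=3)]
        return "\n".join(lines)

    def to_json(self) -> str:
        d = self.fitresult.to_dict()
        d["standardized"] = json.loads(
            self.standardized_components(ci=self.cov is not None).to_json())
        return json.dumps(d, indent=2)


@dataclass
class AceAeComparison:
    """AE-vs-ACE model selection by AIC."""

    selected: str
    results: dict
    delta_aic: float  # AIC(ACE) - AIC(AE); positive favours AE

    @property
    def best(self) -> CholeskyACEResults:
        return self.results[self.selected]


def compare_ace_ae(data, variable: str = "wb", waves: Sequence[int] = (1, 2, 3),
                   compute_se: bool = False, **fit_kwargs) -> AceAeComparison:
    """Fit both ACE and AE configurations and select the lower AIC.

    Ties within 1e-6 go to the simpler AE model.  Raises if either fit
    fails to converge.
    """
    results = {}
    for comp in ("ACE", "AE"):
        res = CholeskyACE(data, variable=variable, components=comp,
                          waves=waves).fit(compute_se=compute_se, **fit_kwargs)
        if not res.converged:
            raise RuntimeError(
                f"{comp} fit did not converge; selection aborted "
                f"(diagnostics: {res.fitresult.start_diagnostics})")
        results[comp] = res
    delta = results["ACE"].aic - results["AE"].aic
    selected = "AE" if delta >= -1e-6 else "ACE"
    return AceAeComparison(selected=selected, results=results, delta_aic=float(delta))
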