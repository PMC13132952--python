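"""Multi-group Gaussian structural-model core with raw-data FIML.

A twin structural model is expressed as a :class:`SourceLoadingModel`: a map
from a parameter vector to a loading matrix L and mean vector mu per
zygosity group, where the observed vector of a twin pair is modelled as

    x = mu(theta) + L(theta) z,      z ~ N(0, I),

so the implied covariance Sigma = L L' is positive semi-definite by
construction.  Independent standard-normal sources are tagged A (additive
genetic), C (shared environment) or E (nonshared environment).  Genetic
sources correlate r = 1 across MZ co-twins and r = 0.5 across DZ co-twins;
this is realised by source splitting

    A_twin = sqrt(r) A_common + sqrt(1 - r) A_unique,

which reproduces the cross-twin genetic covariance r * a a' exactly while
keeping every source independent standard normal.  C sources load both
twins identically, E sources load one twin only.

The raw-data likelihood handles arbitrary missingness: each pair
contributes a multivariate-normal density over its observed entries only.
Rows are grouped by missingness pattern, which reduces the cost per
likelihood evaluation to one Cholesky factorisation per pattern.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy import linalg, optimize, stats
from statsmodels.tools.numdiff import approx_fprime, approx_hess

__all__ = [
    "GENETIC_CORRELATION",
    "SourceLoadingModel",
    "FitResult",
    "FitIndices",
    "LRTResult",
    "twin_source_columns",
    "expected_moments",
    "pattern_statistics",
    "fiml_neg2loglik",
    "fiml_neg2loglik_rowwise",
    "fit_source_model",
    "standard_errors",
    "fix_params",
    "fit_saturated",
    "fit_independence",
    "fit_indices",
    "likelihood_ratio_test",
    "delta_method",
    "profile_ci",
]

LN_2PI = math.log(2.0 * math.pi)

#: cross-twin correlation of additive-genetic sources by zygosity
GENETIC_CORRELATION: dict[str, float] = {"MZ": 1.0, "DZ": 0.5}

#: value returned to the optimizer when the implied covariance is singular
SINGULAR_PENALTY = 1e12


class SourceLoadingModel:
    """A structural model as loadings of observed variables on N(0,1) sources.

    Parameters
    ----------
    name : str
    param_names : list of str
    bounds : list of (lo, hi)
        Box bounds per parameter (None = unbounded).
    n_observed : int
        Length of the stacked observed vector of one twin pair.
    loadings : callable(theta, group) -> (n_observed, n_sources) array
    means : callable(theta, group) -> (n_observed,) array
    start : callable(data) -> theta
        Default starting values from the per-group data arrays.
    source_labels : callable(group) -> list of str, optional
        Tags each source column (A-common / A-unique / C / E and carrier).
    """

    def __init__(
        self,
        name: str,
        param_names: Sequence[str],
        bounds: Sequence[tuple],
        n_observed: int,
        loadings: Callable[[np.ndarray, str], np.ndarray],
        means: Callable[[np.ndarray, str], np.ndarray],
        start: Callable[[Mapping[str, np.ndarray]], np.ndarray],
        source_labels: Callable[[str], list] | None = None,
    ):
        self.name = name
        self.param_names = list(param_names)
        self.bounds = list(bounds)
        self.n_observed = n_observed
        self.loadings = loadings
        self.means = means
        self.start = start
        self.source_labels = source_labels

    @property
    def n_params(self) -> int:
        return len(self.param_names)

    def index(self, name: str) -> int:
        return self.param_names.index(name)


def twin_source_columns(M: np.ndarray, kind: str, rbar: float) -> list[np.ndarray]:
    """Stack a per-twin loading block into pair-level source columns.

    ``M`` (k x s) maps a twin's own sources to that twin's observed block.
    Returns the pair-level (2k x ·) column blocks implementing the twin
    covariance structure of component ``kind``:

    - ``"C"``: one shared block loading both twins,
    - ``"E"``: two independent per-twin blocks,
    - ``"A"``: a common block weighted sqrt(rbar) plus, when rbar < 1,
      per-twin unique blocks weighted sqrt(1 - rbar).
    """
    k, s = M.shape
    Z = np.zeros_like(M)
    if kind == "C":
        return [np.vstack([M, M])]
    if kind == "E":
        return [np.vstack([M, Z]), np.vstack([Z, M])]
    if kind == "A":
        cols = [math.sqrt(rbar) * np.vstack([M, M])]
        if rbar < 1.0:
            w = math.sqrt(1.0 - rbar)
            cols.append(np.vstack([w * M, Z]))
            cols.append(np.vstack([Z, w * M]))
        return cols
    raise ValueError(f"unknown component kind {kind!r}")


def expected_moments(model: SourceLoadingModel, theta: np.ndarray, group: str):
    """Model-implied mean vector and covariance matrix for one group."""
    theta = np.asarray(theta, dtype=float)
    if not np.all(np.isfinite(theta)):
        raise ValueError("non-finite parameter vector")
    L = model.loadings(theta, group)
    mu = model.means(theta, group)
    return mu, L @ L.T


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------

@dataclass
class _Pattern:
    idx: np.ndarray      # observed-variable indices
    n: int
    mean: np.ndarray
    scatter: np.ndarray  # mean-centred second moment, divisor n


def pattern_statistics(Y: np.ndarray) -> list[_Pattern]:
    """Sufficient statistics per missingness pattern (all-missing rows dropped)."""
    Y = np.asarray(Y, dtype=float)
    if Y.ndim != 2:
        raise ValueError("data must be 2-D (rows are pairs)")
    obs = ~np.isnan(Y)
    Y = Y[obs.any(axis=1)]
    obs = obs[obs.any(axis=1)] if len(Y) else obs[:0]
    out: list[_Pattern] = []
    if not len(Y):
        return out
    uniq, inv = np.unique(obs, axis=0, return_inverse=True)
    for i, m in enumerate(uniq):
        rows = Y[inv == i][:, m]
        n = rows.shape[0]
        xbar = rows.mean(axis=0)
        d = rows - xbar
        out.append(_Pattern(np.flatnonzero(m), n, xbar, d.T @ d / n))
    return out


def _neg2ll_patterns(mu: np.ndarray, Sigma: np.ndarray, patterns: Sequence[_Pattern]) -> float:
    total = 0.0
    for p in patterns:
        k = p.idx.size
        sub = Sigma[np.ix_(p.idx, p.idx)]
        try:
            c, low = linalg.cho_factor(sub, lower=True, check_finite=False)
        except linalg.LinAlgError:
            return SINGULAR_PENALTY
        logdet = 2.0 * np.sum(np.log(np.diag(c)))
        if not np.isfinite(logdet):
            return SINGULAR_PENALTY
        inv_scatter = linalg.cho_solve((c, low), p.scatter, check_finite=False)
        d = p.mean - mu[p.idx]
        quad = d @ linalg.cho_solve((c, low), d, check_finite=False)
        total += p.n * (k * LN_2PI + logdet + np.trace(inv_scatter) + quad)
    return float(total)


def fiml_neg2loglik(
    model: SourceLoadingModel,
    theta: np.ndarray,
    data: Mapping[str, np.ndarray],
    patterns: Mapping[str, Sequence[_Pattern]] | None = None,
) -> float:
    """-2 log-likelihood of the raw data under the model, all groups summed."""
    if patterns is None:
        patterns = {g: pattern_statistics(Y) for g, Y in data.items()}
    total = 0.0
    for g, pats in patterns.items():
        if not pats:
            continue
        mu, Sigma = expected_moments(model, theta, g)
        total += _neg2ll_patterns(mu, Sigma, pats)
    return total


def fiml_neg2loglik_rowwise(
    model: SourceLoadingModel, theta: np.ndarray, data: Mapping[str, np.ndarray]
) -> float:
    """Reference row-by-row evaluation (same value as the pattern-grouped path)."""
    total = 0.0
    for g, Y in data.items():
        if not len(Y):
            continue
        mu, Sigma = expected_moments(model, theta, g)
        for row in np.asarray(Y, dtype=float):
            m = ~np.isnan(row)
            if not m.any():
                continue
            k = int(m.sum())
            sub = Sigma[np.ix_(m, m)]
            sign, logdet = np.linalg.slogdet(sub)
            if sign <= 0:
                return SINGULAR_PENALTY
            d = row[m] - mu[m]
            total += k * LN_2PI + logdet + d @ np.linalg.solve(sub, d)
    return float(total)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    """Outcome of a FIML optimisation."""

    model_name: str
    param_names: list[str]
    params: np.ndarray
    minus2ll: float
    n_free: int
    converged: bool
    grad_norm: float
    n_rows: dict[str, int]
    message: str = ""
    bse: np.ndarray | None = None
    bse_reliable: bool | None = None
    start_diagnostics: list[dict] = field(default_factory=list)

    @property
    def aic(self) -> float:
        """Akaike information criterion, -2lnL + 2q."""
        return self.minus2ll + 2.0 * self.n_free

    @property
    def n_total(self) -> int:
        return sum(self.n_rows.values())

    def params_dict(self) -> dict[str, float]:
        return dict(zip(self.param_names, np.asarray(self.params, float)))

    def to_dict(self) -> dict:
        return {
            "model": self.model_name,
            "minus2ll": self.minus2ll,
            "aic": self.aic,
            "n_free": self.n_free,
            "converged": self.converged,
            "grad_norm": self.grad_norm,
            "n_rows": self.n_rows,
            "params": self.params_dict(),
            "bse": None if self.bse is None else dict(zip(self.param_names, self.bse)),
            "bse_reliable": self.bse_reliable,
        }


def _count_rows(data: Mapping[str, np.ndarray]) -> dict[str, int]:
    out = {}
    for g, Y in data.items():
        Y = np.asarray(Y, dtype=float)
        out[g] = int((~np.isnan(Y)).any(axis=1).sum()) if len(Y) else 0
    return out


def fit_source_model(
    model: SourceLoadingModel,
    data: Mapping[str, np.ndarray],
    n_starts: int = 5,
    jitter: float = 0.2,
    seed: int | None = None,
    start: np.ndarray | None = None,
    maxiter: int = 2000,
    gtol: float = 1e-6,
    compute_se: bool = False,
) -> FitResult:
    """Minimise the FIML -2lnL with multi-start bounded quasi-Newton.

    The first start is the model's data-driven heuristic (or ``start``);
    the remaining ``n_starts - 1`` are multiplicative/additive jitters of
    it, clipped into the box bounds.  The best converged solution wins.
    """
    patterns = {g: pattern_statistics(Y) for g, Y in data.items()}
    patterns = {g: p for g, p in patterns.items() if p}
    if not patterns:
        raise ValueError("no usable rows in any group")

    def objective(theta):
        return fiml_neg2loglik(model, theta, data, patterns)

    theta0 = np.asarray(model.start(data) if start is None else start, dtype=float)
    if theta0.shape != (model.n_params,):
        raise ValueError("starting vector has wrong length")
    rng = np.random.default_rng(seed)
    starts = [theta0]
    lo = np.array([b[0] if b[0] is not None else -np.inf for b in model.bounds])
    hi = np.array([b[1] if b[1] is not None else np.inf for b in model.bounds])
    for _ in range(max(0, n_starts - 1)):
        s = theta0 + jitter * (1.0 + np.abs(theta0)) * rng.standard_normal(theta0.size)
        starts.append(np.clip(s, lo + 1e-6 * (lo > -np.inf), hi))

    best = None
    diagnostics = []
    for i, s in enumerate(starts):
        res = optimize.minimize(
            objective, s, method="L-BFGS-B", bounds=model.bounds,
            options={"maxiter": maxiter, "maxfun": 20 * maxiter,
                     "ftol": 1e-11, "gtol": gtol},
        )
        diagnostics.append({"start": i, "fun": float(res.fun), "success": bool(res.success),
                            "message": str(res.message)})
        if best is None or (res.fun < best.fun - 1e-9 and res.success) or \
           (not best.success and res.success and res.fun < best.fun + 1e-6):
            best = res
    assert best is not None
    grad_norm = float(np.max(np.abs(best.jac))) if best.jac is not None else math.nan
    converged = bool(best.success) and best.fun < SINGULAR_PENALTY / 2
    if converged and grad_norm > 1e-4 * max(1.0, abs(best.fun)):
        warnings.warn(f"{model.name}: gradient norm {grad_norm:.3g} above tolerance")
    result = FitResult(
        model_name=model.name,
        param_names=model.param_names,
        params=np.asarray(best.x, dtype=float),
        minus2ll=float(best.fun),
        n_free=model.n_params,
        converged=converged,
        grad_norm=grad_norm,
        n_rows=_count_rows(data),
        message=str(best.message),
        start_diagnostics=diagnostics,
    )
    if compute_se:
        bse, ok = standard_errors(model, result, data)
        result.bse, result.bse_reliable = bse, ok
    return result


def standard_errors(
    model: SourceLoadingModel, result: FitResult, data: Mapping[str, np.ndarray]
) -> tuple[np.ndarray, bool]:
    """Observed-information SEs from the numerical Hessian of -lnL.

    Returns (se_vector, reliable).  ``reliable`` is False when the Hessian
    is not positive definite or the estimate sits on a box bound (where the
    quadratic approximation breaks down); unusable entries are NaN.
    """
    patterns = {g: pattern_statistics(Y) for g, Y in data.items()}

    def half_obj(theta):
        return 0.5 * fiml_neg2loglik(model, theta, data, patterns)

    at_bound = False
    for v, (lo, hi) in zip(result.params, model.bounds):
        if lo is not None and v - lo < 1e-6:
            at_bound = True
        if hi is not None and hi - v < 1e-6:
            at_bound = True
    try:
        H = approx_hess(result.params, half_obj)
        H = 0.5 * (H + H.T)
        evals = np.linalg.eigvalsh(H)
        if np.min(evals) <= 0:
            cov = np.linalg.pinv(H)
            se = np.sqrt(np.where(np.diag(cov) > 0, np.diag(cov), np.nan))
            return se, False
        cov = np.linalg.inv(H)
        se = np.sqrt(np.diag(cov))
        return se, not at_bound
    except Exception:
        return np.full(model.n_params, np.nan), False


def parameter_covariance(
    model: SourceLoadingModel, result: FitResult, data: Mapping[str, np.ndarray]
) -> np.ndarray:
    """Full parameter covariance matrix (inverse observed information)."""
    patterns = {g: pattern_statistics(Y) for g, Y in data.items()}

    def half_obj(theta):
        return 0.5 * fiml_neg2loglik(model, theta, data, patterns)

    H = approx_hess(result.params, half_obj)
    H = 0.5 * (H + H.T)
    evals = np.linalg.eigvalsh(H)
    if np.min(evals) <= 0:
        return np.linalg.pinv(H)
    return np.linalg.inv(H)


def fix_params(model: SourceLoadingModel, fixed: Mapping[str, float]) -> SourceLoadingModel:
    """Constrained submodel with named parameters pinned at given values."""
    unknown = set(fixed) - set(model.param_names)
    if unknown:
        raise KeyError(f"unknown parameters: {sorted(unknown)}")
    fixed_idx = {model.param_names.index(k): float(v) for k, v in fixed.items()}
    free_idx = [i for i in range(model.n_params) if i not in fixed_idx]

    def expand(theta_free):
        full = np.empty(model.n_params)
        full[free_idx] = theta_free
        for i, v in fixed_idx.items():
            full[i] = v
        return full

    def start(data):
        return np.asarray(model.start(data), dtype=float)[free_idx]

    sub = SourceLoadingModel(
        name=f"{model.name}|fixed({','.join(sorted(fixed))})",
        param_names=[model.param_names[i] for i in free_idx],
        bounds=[model.bounds[i] for i in free_idx],
        n_observed=model.n_observed,
        loadings=lambda th, g: model.loadings(expand(th), g),
        means=lambda th, g: model.means(expand(th), g),
        start=start,
        source_labels=model.source_labels,
    )
    sub.expand = expand  # type: ignore[attr-defined]
    sub.parent = model   # type: ignore[attr-defined]
    return sub


# ---------------------------------------------------------------------------
# saturated / independence reference models
# ---------------------------------------------------------------------------

def _complete_group_saturated(Y: np.ndarray) -> float:
    """Closed-form saturated -2lnL for a complete-data group (MLE divisor n)."""
    n, k = Y.shape
    S = np.cov(Y, rowvar=False, bias=True) if k > 1 else np.array([[Y.var()]])
    S = np.atleast_2d(S)
    sign, logdet = np.linalg.slogdet(S)
    if sign <= 0:
        raise np.linalg.LinAlgError("singular sample covariance")
    return n * (k * LN_2PI + logdet + k)


def fit_saturated(data: Mapping[str, np.ndarray], maxiter: int = 5000) -> FitResult:
    """Saturated model: free mean vector and free covariance per group.

    Complete-data groups use the closed-form MLE (sample moments, divisor
    n); groups with missingness optimise a mean + Cholesky(covariance)
    parameterisation under FIML.
    """
    total = 0.0
    q = 0
    n_rows = {}
    converged = True
    for g, Y in data.items():
        Y = np.asarray(Y, dtype=float)
        obs = ~np.isnan(Y)
        Y = Y[obs.any(axis=1)]
        if not len(Y):
            n_rows[g] = 0
            continue
        n, k = Y.shape
        n_rows[g] = n
        q += k + k * (k + 1) // 2
        if not np.isnan(Y).any():
            total += _complete_group_saturated(Y)
            continue
        total_g, ok = _fit_saturated_group(Y, maxiter)
        total += total_g
        converged = converged and ok
    return FitResult("saturated", [], np.array([]), float(total), q,
                     converged, math.nan, n_rows)


def _fit_saturated_group(Y: np.ndarray, maxiter: int) -> tuple[float, bool]:
    n, k = Y.shape
    patterns = pattern_statistics(Y)
    tril = np.tril_indices(k)

    def unpack(theta):
        mu = theta[:k]
        Lc = np.zeros((k, k))
        Lc[tril] = theta[k:]
        return mu, Lc

    def objective(theta):
        mu, Lc = unpack(theta)
        return _neg2ll_patterns(mu, Lc @ Lc.T, patterns)

    # start from pairwise-complete moments, ridged to PD
    mu0 = np.nanmean(Y, axis=0)
    df = np.where(np.isnan(Y), np.nan, Y)
    S0 = np.atleast_2d(np.array(
        [[np.nanmean((df[:, i] - mu0[i]) * (df[:, j] - mu0[j])) for j in range(k)]
         for i in range(k)]))
    S0 = np.nan_to_num(S0, nan=0.0)
    ridge = 1e-6 * max(1.0, np.trace(S0) / k)
    while np.min(np.linalg.eigvalsh(S0)) <= ridge:
        S0[np.diag_indices(k)] += ridge * 10
        ridge *= 10
    L0 = np.linalg.cholesky(S0)
    theta0 = np.concatenate([mu0, L0[tril]])
    bounds = [(None, None)] * k + [
        (1e-8, None) if i == j else (None, None) for i, j in zip(*tril)
    ]
    res = optimize.minimize(objective, theta0, method="L-BFGS-B", bounds=bounds,
                            options={"maxiter": maxiter, "maxfun": 20 * maxiter,
                                     "ftol": 1e-11})
    return float(res.fun), bool(res.success)


def fit_independence(data: Mapping[str, np.ndarray]) -> FitResult:
    """Independence model: free means, diagonal covariance per group.

    Under a diagonal covariance the FIML likelihood factorises across
    variables, so each variable's MLE is the mean/variance of its observed
    values — closed form even with missing data.
    """
    total = 0.0
    q = 0
    n_rows = {}
    for g, Y in data.items():
        Y = np.asarray(Y, dtype=float)
        obs = ~np.isnan(Y)
        Y = Y[obs.any(axis=1)]
        if not len(Y):
            n_rows[g] = 0
            continue
        n, k = Y.shape
        n_rows[g] = n
        q += 2 * k
        for j in range(k):
            col = Y[:, j]
            col = col[~np.isnan(col)]
            if col.size == 0:
                continue
            v = max(float(np.var(col)), 1e-12)
            total += col.size * (LN_2PI + math.log(v) + 1.0)
    return FitResult("independence", [], np.array([]), float(total), q,
                     True, math.nan, n_rows)


# ---------------------------------------------------------------------------
# fit indices and tests
# ---------------------------------------------------------------------------

@dataclass
class FitIndices:
    """Likelihood-based fit statistics relative to saturated/independence models."""

    chisq: float
    df: int
    p: float
    cfi: float
    tli: float
    rmsea: float
    aic: float
    n_groups: int = 2
    note: str = ("RMSEA uses the multi-group convention sqrt(G*max(T-df,0)/"
                 "(df*(N-G))); conventions without the factor G differ by sqrt(G).")

    def to_dict(self) -> dict:
        return {"chisq": self.chisq, "df": self.df, "p": self.p, "cfi": self.cfi,
                "tli": self.tli, "rmsea": self.rmsea, "aic": self.aic,
                "n_groups": self.n_groups, "note": self.note}


def fit_indices(
    target: FitResult,
    saturated: FitResult,
    independence: FitResult,
    n_total: int | None = None,
    n_groups: int = 2,
) -> FitIndices:
    """CFI, TLI, RMSEA and AIC from target vs saturated/independence fits."""
    T = max(target.minus2ll - saturated.minus2ll, 0.0)
    df = saturated.n_free - target.n_free
    T0 = max(independence.minus2ll - saturated.minus2ll, 0.0)
    df0 = saturated.n_free - independence.n_free
    if df < 0:
        raise ValueError("target has more free parameters than the saturated model")
    p = float(stats.chi2.sf(T, df)) if df > 0 else math.nan
    denom = max(T0 - df0, T - df, 0.0)
    cfi = 1.0 if denom == 0 else 1.0 - max(T - df, 0.0) / denom
    cfi = min(max(cfi, 0.0), 1.0)
    if df == 0 or df0 == 0 or T0 / df0 == 1.0:
        tli = math.nan
        rmsea = math.nan if df == 0 else 0.0
    else:
        tli = ((T0 / df0) - (T / df)) / ((T0 / df0) - 1.0)
        tli = min(max(tli, 0.0), 1.0)
        rmsea = 0.0
    if df > 0:
        N = target.n_total if n_total is None else n_total
        rmsea = math.sqrt(n_groups * max(T - df, 0.0) / (df * max(N - n_groups, 1)))
    return FitIndices(chisq=float(T), df=int(df), p=p, cfi=float(cfi),
                      tli=float(tli), rmsea=float(rmsea), aic=target.aic,
                      n_groups=n_groups)


@dataclass
class LRTResult:
    """Likelihood-ratio test of a nested against a full model."""

    delta_chisq: float
    delta_df: int
    p: float
    warning: str = ""

    def to_dict(self) -> dict:
        return {"delta_chisq": self.delta_chisq, "delta_df": self.delta_df,
                "p": self.p, "warning": self.warning}


def likelihood_ratio_test(full: FitResult, nested: FitResult, tol: float = 1e-6) -> LRTResult:
    if nested.n_free >= full.n_free:
        raise ValueError("nested model must have fewer free parameters")
    raw = nested.minus2ll - full.minus2ll
    warning = ""
    if raw < -tol:
        warning = (f"nested model fits better by {-raw:.3g}; "
                   "optimizer failure on the full model suspected")
        warnings.warn(warning)
    d = max(raw, 0.0)
    ddf = full.n_free - nested.n_free
    return LRTResult(float(d), int(ddf), float(stats.chi2.sf(d, ddf)), warning)


# ---------------------------------------------------------------------------
# uncertainty for derived quantities
# ---------------------------------------------------------------------------

def delta_method(
    fun: Callable[[np.ndarray], np.ndarray],
    theta: np.ndarray,
    cov: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """First-order (delta-method) values and SEs of fun(theta).

    ``fun`` maps the parameter vector to a vector of derived quantities.
    """
    theta = np.asarray(theta, dtype=float)
    vals = np.atleast_1d(np.asarray(fun(theta), dtype=float))
    G = approx_fprime(theta, lambda t: np.atleast_1d(np.asarray(fun(t), float)))
    G = np.atleast_2d(G)
    if G.shape[0] != vals.size:
        G = G.T
    var = np.einsum("ij,jk,ik->i", G, cov, G)
    return vals, np.sqrt(np.maximum(var, 0.0))


def profile_ci(
    model: SourceLoadingModel,
    data: Mapping[str, np.ndarray],
    result: FitResult,
    name: str,
    level: float = 0.95,
    se_hint: float | None = None,
    maxiter: int = 500,
) -> tuple[float, float]:
    """Profile-likelihood CI for a raw parameter by bisection on the LRT boundary.

    Finds the parameter values where the profiled -2lnL rises by the
    chi-square(1) critical value above the optimum (3.84 at 95%).
    """
    crit = stats.chi2.ppf(level, 1)
    i = model.index(name)
    mle = float(result.params[i])
    target = result.minus2ll + crit

    def profiled(v: float) -> float:
        sub = fix_params(model, {name: v})
        start = np.delete(result.params, i)
        res = fit_source_model(sub, data, n_starts=1, start=start, maxiter=maxiter)
        return res.minus2ll

    step = se_hint if se_hint and math.isfinite(se_hint) else 0.25 * (1.0 + abs(mle))
    lo_b, hi_b = model.bounds[i]
    out = []
    for direction in (-1.0, 1.0):
        a, fa = mle, result.minus2ll
        b = mle
        found = False
        for _ in range(40):
            b = b + direction * step
            if lo_b is not None and b < lo_b:
                b = lo_b
            if hi_b is not None and b > hi_b:
                b = hi_b
            fb = profiled(b)
            if fb >= target:
                found = True
                break
            if (lo_b is not None and b <= lo_b) or (hi_b is not None and b >= hi_b):
                break
            a, fa = b, fb
        if not found:
            out.append(b)  # boundary-limited
            continue
        root = optimize.brentq(lambda v: profiled(v) - target, min(a, b), max(a, b),
                               xtol=1e-4 * (1 + abs(mle)))
        out.append(float(root))
    lo, hi = sorted(out)
    return lo, hi
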