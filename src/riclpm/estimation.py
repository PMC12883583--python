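"""Full-information maximum likelihood estimation of panel SEMs.

Rows are grouped by missingness pattern; each group contributes the Gaussian
log-density of its observed sub-vector under the corresponding sub-mean and
sub-covariance of the model-implied moments.  Grouping makes the likelihood
(and its analytic gradient, obtained by reverse-mode accumulation through
the implied-moment construction) a function of per-pattern sufficient
statistics only, so the cost per evaluation is independent of n.

Inference follows the common "MLR-style" practice for panel SEM: coefficients
are standardized using model-implied within-component standard deviations,
and standard errors default to the Huber-White sandwich (observed-information
SEs are available by flag).  Standard errors of standardized quantities use
the delta method with central finite differences on the packed parameter
vector.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize

from .model import (
    ALTSRParams,
    InvalidParameterError,
    ParameterIndex,
    RICLPMParams,
    implied_moments,
    within_covariance,
)
from .preprocess import ModelPanel

__all__ = [
    "PatternStats",
    "FitOptions",
    "FitResult",
    "fiml_loglik",
    "fit",
    "fit_to_moments",
    "standardize",
    "robust_se",
    "saturated_loglik",
    "baseline_loglik",
    "saturated_and_baseline_loglik",
]

_BIG = 1e15  # optimizer-safe sentinel for non-PD implied sub-covariances
_LOG2PI = np.log(2.0 * np.pi)


# ---------------------------------------------------------------------------
# pattern grouping

@dataclass
class PatternGroup:
    mask: np.ndarray          # (p,) bool, observed variables
    idx: np.ndarray           # observed variable indices
    n: int
    mean: np.ndarray          # (k,) group mean of observed values
    scatter: np.ndarray       # (k,k) sum of (x - mean)(x - mean)^T
    rows: np.ndarray | None   # (n, k) observed values, kept for row scores


@dataclass
class PatternStats:
    """Sufficient statistics of a panel, grouped by missingness pattern."""

    p: int
    n: int                    # rows contributing (>= 1 observed variable)
    n_empty: int              # rows with no observed variable (excluded)
    groups: list[PatternGroup]
    _buckets: dict = field(default=None, repr=False, compare=False)

    def buckets(self) -> dict:
        """Groups stacked by observed-variable count for batched linalg.

        Per count k: idx (m, k) int, n (m,), mean (m, k), scatter (m, k, k).
        """
        if self._buckets is None:
            by_k: dict[int, list[PatternGroup]] = {}
            for g in self.groups:
                by_k.setdefault(g.idx.size, []).append(g)
            self._buckets = {
                k: {
                    "idx": np.stack([g.idx for g in gs]),
                    "n": np.array([g.n for g in gs], float),
                    "mean": np.stack([g.mean for g in gs]),
                    "scatter": np.stack([g.scatter for g in gs]),
                }
                for k, gs in by_k.items()
            }
        return self._buckets

    @classmethod
    def from_matrix(cls, X: np.ndarray, keep_rows: bool = True) -> "PatternStats":
        X = np.asarray(X, float)
        p = X.shape[1]
        obs = ~np.isnan(X)
        nonempty = obs.any(axis=1)
        n_empty = int((~nonempty).sum())
        X, obs = X[nonempty], obs[nonempty]
        groups: list[PatternGroup] = []
        # lexicographic grouping of boolean masks
        keys = np.packbits(obs, axis=1)
        order = np.lexsort(keys.T[::-1])
        keys_sorted = keys[order]
        boundaries = np.flatnonzero(np.any(np.diff(keys_sorted, axis=0) != 0, axis=1)) + 1
        starts = np.concatenate([[0], boundaries, [len(order)]])
        for a, b in zip(starts[:-1], starts[1:]):
            rows_idx = order[a:b]
            mask = obs[rows_idx[0]]
            idx = np.flatnonzero(mask)
            R = X[np.ix_(rows_idx, idx)]
            mean = R.mean(axis=0)
            d = R - mean
            groups.append(PatternGroup(mask=mask, idx=idx, n=len(rows_idx), mean=mean,
                                       scatter=d.T @ d, rows=R if keep_rows else None))
        return cls(p=p, n=int(nonempty.sum()), n_empty=n_empty, groups=groups)

    @classmethod
    def from_moments(cls, mu: np.ndarray, Sigma: np.ndarray, n: int) -> "PatternStats":
        """A pseudo-sample whose mean/covariance equal the given moments.

        Feeding these statistics to the FIML objective turns it into the ML
        moment discrepancy, i.e. the large-sample limit of fitting data
        generated from (mu, Sigma).
        """
        mu = np.asarray(mu, float)
        Sigma = np.asarray(Sigma, float)
        p = mu.shape[0]
        g = PatternGroup(mask=np.ones(p, bool), idx=np.arange(p), n=int(n),
                         mean=mu.copy(), scatter=n * Sigma.copy(), rows=None)
        return cls(p=p, n=int(n), n_empty=0, groups=[g])

    @property
    def n_patterns(self) -> int:
        return len(self.groups)

    def has_rows(self) -> bool:
        return all(g.rows is not None for g in self.groups)

    def is_complete(self) -> bool:
        return self.n_patterns == 1 and self.groups[0].idx.size == self.p

    def pairwise_moments(self) -> tuple[np.ndarray, np.ndarray]:
        """Pairwise-complete mean vector and covariance (for starting values)."""
        p = self.p
        s1 = np.zeros(p)
        n1 = np.zeros(p)
        s2 = np.zeros((p, p))
        n2 = np.zeros((p, p))
        for g in self.groups:
            ix = g.idx
            s1[ix] += g.n * g.mean
            n1[ix] += g.n
            cross = g.scatter + g.n * np.outer(g.mean, g.mean)
            s2[np.ix_(ix, ix)] += cross
            n2[np.ix_(ix, ix)] += g.n
        with np.errstate(invalid="ignore", divide="ignore"):
            mean = s1 / n1
            cov = s2 / np.maximum(n2, 1) - np.outer(mean, mean)
        mean = np.nan_to_num(mean)
        cov = np.nan_to_num(cov)
        return mean, (cov + cov.T) / 2.0


def _as_stats(panel) -> PatternStats:
    if isinstance(panel, PatternStats):
        return panel
    if isinstance(panel, ModelPanel):
        return PatternStats.from_matrix(panel.to_matrix())
    if hasattr(panel, "values"):
        return PatternStats.from_matrix(np.asarray(panel.values, float))
    return PatternStats.from_matrix(np.asarray(panel, float))


# ---------------------------------------------------------------------------
# likelihood

def _group_loglik(mu: np.ndarray, Sigma: np.ndarray, stats: PatternStats,
                  accumulate: bool = False):
    """Total FIML log-likelihood; optionally gradients w.r.t. (mu, Sigma).

    Patterns are processed in stacks of equal observed-variable count so the
    Cholesky factorizations and solves run through numpy's batched LAPACK
    paths.  Returns None when any implied sub-covariance is not PD.
    """
    ll = 0.0
    G = np.zeros_like(Sigma) if accumulate else None
    gmu = np.zeros_like(mu) if accumulate else None
    for k, b in stats.buckets().items():
        idx = b["idx"]                                   # (m, k)
        Sub = Sigma[idx[:, :, None], idx[:, None, :]]    # (m, k, k)
        try:
            L = np.linalg.cholesky(Sub)
        except np.linalg.LinAlgError:
            return None
        logdet = 2.0 * np.log(np.diagonal(L, axis1=1, axis2=2)).sum(axis=1)
        Linv = np.linalg.inv(L)
        Sinv = np.einsum("mba,mbc->mac", Linv, Linv)     # L^-T L^-1
        d = b["mean"] - mu[idx]                          # (m, k)
        n_g = b["n"]
        Sd = np.einsum("mab,mb->ma", Sinv, d)
        ll += -0.5 * (np.sum(n_g * (k * _LOG2PI + logdet))
                      + np.einsum("mab,mab->", Sinv, b["scatter"])
                      + np.sum(n_g * np.einsum("ma,ma->m", d, Sd)))
        if accumulate:
            M = b["scatter"] + n_g[:, None, None] * np.einsum("ma,mb->mab", d, d)
            Gblk = 0.5 * (np.einsum("mab,mbc,mcd->mad", Sinv, M, Sinv)
                          - n_g[:, None, None] * Sinv)
            np.add.at(G, (idx[:, :, None], idx[:, None, :]), Gblk)
            np.add.at(gmu, idx, n_g[:, None] * Sd)
    if accumulate:
        return ll, G, gmu
    return ll


def fiml_loglik(params: RICLPMParams | ALTSRParams, panel) -> float:
    """FIML log-likelihood of a structured parameter set on a panel.

    Sums, over missingness-pattern groups, the multivariate-normal
    log-density of the observed sub-vectors under the implied moments.  Rows
    with no observed variable contribute nothing.  A singular implied
    sub-covariance yields ``-inf``.
    """
    stats = _as_stats(panel)
    mu, Sigma = implied_moments(params)
    if mu.shape[0] != stats.p:
        raise ValueError(f"model has {mu.shape[0]} variables but panel has {stats.p}")
    out = _group_loglik(mu, Sigma, stats)
    return -np.inf if out is None else float(out)


def _neg_mean_loglik_grad(x: np.ndarray, index: ParameterIndex, stats: PatternStats):
    mu, Sigma, backward = index.moments_and_adjoint(x)
    out = _group_loglik(mu, Sigma, stats, accumulate=True)
    if out is None:
        return _BIG, np.zeros_like(x)
    ll, G, gmu = out
    grad = backward(G, gmu)
    n = stats.n
    return -ll / n, -grad / n


# ---------------------------------------------------------------------------
# starting values

def _nearest_pd(S: np.ndarray, floor_frac: float = 1e-4) -> np.ndarray:
    S = (S + S.T) / 2.0
    w, V = np.linalg.eigh(S)
    floor = max(w.max(), 1e-8) * floor_frac
    w = np.clip(w, floor, None)
    return (V * w) @ V.T


def _start_values(index: ParameterIndex, stats: PatternStats) -> np.ndarray:
    """Moment-based starting values from pairwise-complete statistics."""
    T = index.T
    mean, cov = stats.pairwise_moments()
    var = np.clip(np.diag(cov), 1e-8, None)

    # between-person covariance from distant same/cross-construct wave pairs
    psi0 = np.zeros((2, 2))
    for a in range(2):
        for b in range(2):
            vals = [cov[2 * t + a, 2 * s + b]
                    for t in range(T) for s in range(T) if abs(t - s) >= 2]
            psi0[a, b] = np.mean(vals) if vals else 0.0
    psi0 = (psi0 + psi0.T) / 2.0
    for c in range(2):
        cap = 0.8 * np.mean(var[c::2])
        psi0[c, c] = np.clip(psi0[c, c], 0.05 * np.mean(var[c::2]), cap)
    rho = psi0[0, 1] / np.sqrt(psi0[0, 0] * psi0[1, 1])
    psi0[0, 1] = psi0[1, 0] = np.clip(rho, -0.9, 0.9) * np.sqrt(psi0[0, 0] * psi0[1, 1])

    def w_block(t: int, s: int) -> np.ndarray:
        blk = cov[2 * t:2 * t + 2, 2 * s:2 * s + 2] - psi0
        return blk

    theta1 = _nearest_pd(w_block(0, 0), 1e-2)
    B0 = np.zeros((T - 1, 2, 2))
    theta0 = np.zeros((T - 1, 2, 2))
    for t in range(T - 1):
        Ct = _nearest_pd(w_block(t, t), 1e-2)
        Cross = w_block(t + 1, t)
        Bt = Cross @ np.linalg.inv(Ct)
        B0[t] = np.clip(Bt, -0.95, 0.95)
        resid = w_block(t + 1, t + 1) - B0[t] @ Ct @ B0[t].T
        theta0[t] = _nearest_pd(resid, 1e-1)

    if index.kind == "riclpm":
        params = RICLPMParams(psi=_nearest_pd(psi0, 1e-3), theta1=theta1, B=B0,
                              theta=theta0, mu=mean.copy())
        return index.pack(params)

    lam = index.slope_loadings
    phi0 = np.zeros((4, 4))
    phi0[:2, :2] = _nearest_pd(psi0, 1e-3)
    for c in range(2):
        phi0[2 + c, 2 + c] = 0.1 * phi0[c, c] / max(lam[c, -1] ** 2, 1.0)
    phi0 = _nearest_pd(phi0, 1e-5)
    if index.means_mode == "saturated":
        params = ALTSRParams(phi=phi0, theta1=theta1, B=B0, theta=theta0,
                             slope_loadings=lam, mu=mean.copy(), means_mode="saturated")
    else:
        fm = np.zeros(4)
        for c in range(2):
            fm[c] = mean[c]
            fm[2 + c] = (mean[2 * (T - 1) + c] - mean[c]) / max(lam[c, -1], 1.0)
        params = ALTSRParams(phi=phi0, theta1=theta1, B=B0, theta=theta0,
                             slope_loadings=lam, factor_means=fm, means_mode="structured")
    return index.pack(params)


# ---------------------------------------------------------------------------
# standardization

def standardized_names(index: ParameterIndex, labels: tuple[str, str] = ("a", "b")) -> list[str]:
    la, lb = labels
    names = []
    for t in range(1, index.T):
        names += [f"ar_{la}[{t}]", f"ar_{lb}[{t}]",
                  f"cl_{lb}_to_{la}[{t}]", f"cl_{la}_to_{lb}[{t}]"]
    names += [f"resid_cor[{t}]" for t in range(1, index.T + 1)]
    names += ["ri_cor"]
    return names


def standardized_vector(index: ParameterIndex, x: np.ndarray) -> np.ndarray:
    """Standardized paths, residual correlations and intercept correlation.

    Lagged coefficients b (predictor at wave t -> outcome at wave t+1) are
    rescaled to beta = b * sd(predictor) / sd(outcome) using model-implied
    within-component standard deviations; covariances become correlations.
    Order per lag: AR of construct 0, AR of construct 1, CL 1->0, CL 0->1;
    then residual correlations for waves 1..T; then the intercept
    correlation.
    """
    params = index.unpack(x)
    T = index.T
    W = within_covariance(params)
    v = np.diag(W).reshape(T, 2)
    sd = np.sqrt(np.clip(v, 0.0, None))
    out = []
    for t in range(T - 1):
        B = params.B[t]
        pairs = [(0, 0), (1, 1), (0, 1), (1, 0)]  # (outcome, predictor)
        for i, j in pairs:
            denom = sd[t + 1, i]
            if B[i, j] == 0.0:
                out.append(0.0)
            elif denom == 0.0 or sd[t, j] == 0.0:
                out.append(np.nan)
            else:
                out.append(B[i, j] * sd[t, j] / denom)
    def corr(S):
        den = np.sqrt(S[0, 0] * S[1, 1])
        return S[0, 1] / den if den > 0 else np.nan
    out.append(corr(params.theta1))
    for t in range(T - 1):
        out.append(corr(params.theta[t]))
    if isinstance(params, ALTSRParams):
        out.append(corr(params.phi[:2, :2]))
    else:
        out.append(corr(params.psi))
    return np.asarray(out)


# ---------------------------------------------------------------------------
# results container

@dataclass
class FitOptions:
    """Estimation settings.

    ``rel_ll_tol`` and ``grad_tol`` define convergence (relative change of
    the log-likelihood and infinity-norm of the per-row mean gradient);
    ``retries`` perturbed restarts are attempted when the first optimization
    fails to converge, and ``n_starts`` > 1 forces multi-start from the
    outset.  ``se``: "robust" (Huber-White sandwich), "observed"
    (observed-information), or "none".
    """

    rel_ll_tol: float = 1e-9
    grad_tol: float = 1e-5
    maxiter: int = 2000
    n_starts: int = 1
    retries: int = 3
    perturb_scale: float = 0.05
    seed: int = 0
    se: Literal["robust", "observed", "none"] = "robust"
    fd_step: float = 1e-6
    hess_step: float = 1e-5


@dataclass
class FitResult:
    """Estimates, inference and convergence metadata for one model fit."""

    index: ParameterIndex
    labels: tuple[str, str]
    x: np.ndarray
    params: RICLPMParams | ALTSRParams
    loglik: float
    n: int
    n_patterns: int
    converged: bool
    n_iter: int
    grad_norm: float
    boundary: bool
    se_mode: str = "none"
    vcov: np.ndarray | None = None          # packed-parameter covariance
    std_values: np.ndarray | None = None
    std_se: np.ndarray | None = None

    @property
    def T(self) -> int:
        return self.index.T

    @property
    def std_names(self) -> list[str]:
        return standardized_names(self.index, self.labels)

    def _std(self, name: str) -> tuple[float, float]:
        i = self.std_names.index(name)
        se = float(self.std_se[i]) if self.std_se is not None else np.nan
        return float(self.std_values[i]), se

    def paths(self) -> pd.DataFrame:
        """One row per lagged path: unstandardized and standardized estimates."""
        la, lb = self.labels
        rows = []
        kinds = [(f"ar_{la}", 0, 0), (f"ar_{lb}", 1, 1),
                 (f"cl_{lb}_to_{la}", 0, 1), (f"cl_{la}_to_{lb}", 1, 0)]
        for kind, i, j in kinds:
            for t in range(1, self.T):
                beta, se = self._std(f"{kind}[{t}]")
                rows.append({
                    "path": kind, "lag": t,
                    "estimate": float(self.params.B[t - 1, i, j]),
                    "beta": beta, "se": se,
                    "ci_low": beta - 1.96 * se, "ci_high": beta + 1.96 * se,
                })
        return pd.DataFrame(rows)

    def residual_correlations(self) -> pd.DataFrame:
        rows = []
        for t in range(1, self.T + 1):
            r, se = self._std(f"resid_cor[{t}]")
            rows.append({"wave": t, "r": r, "se": se,
                         "ci_low": r - 1.96 * se, "ci_high": r + 1.96 * se})
        return pd.DataFrame(rows)

    def intercept_correlation(self) -> dict:
        r, se = self._std("ri_cor")
        return {"r": r, "se": se, "ci_low": r - 1.96 * se, "ci_high": r + 1.96 * se}

    def to_dict(self) -> dict:
        return {
            "model": self.index.kind,
            "T": self.T,
            "n": self.n,
            "n_free": self.index.n_free,
            "df": self.index.df,
            "loglik": self.loglik,
            "converged": bool(self.converged),
            "boundary": bool(self.boundary),
            "n_iter": self.n_iter,
            "grad_norm": self.grad_norm,
            "n_patterns": self.n_patterns,
            "se_mode": self.se_mode,
            "paths": self.paths().to_dict(orient="records"),
            "residual_correlations": self.residual_correlations().to_dict(orient="records"),
            "intercept_correlation": self.intercept_correlation(),
        }


# ---------------------------------------------------------------------------
# fitting

@dataclass
class _OptOut:
    x: np.ndarray
    fun: float
    nit: int


def _run_opt(x0: np.ndarray, index: ParameterIndex, stats: PatternStats,
             options: FitOptions):
    res = minimize(
        _neg_mean_loglik_grad, x0, args=(index, stats), jac=True,
        method="L-BFGS-B",
        options={"maxiter": options.maxiter, "maxcor": 30,
                 "ftol": options.rel_ll_tol * 1e-2, "gtol": options.grad_tol * 1e-2},
    )
    x, fval = res.x, res.fun
    nit = int(res.nit)
    _, g = _neg_mean_loglik_grad(x, index, stats)
    gnorm = float(np.max(np.abs(g)))
    # Newton refinement: quasi-Newton stalls in flat directions (e.g. variance
    # components at the boundary); damped Newton steps with an eigenvalue-
    # regularized FD Hessian drive the gradient norm to tolerance
    for _ in range(25):
        if gnorm < options.grad_tol / 10 or fval > _BIG / 2:
            break
        H = _mean_hessian(index, x, stats, options.hess_step)
        w, V = np.linalg.eigh(H)
        wmax = max(np.abs(w).max(), 1e-12)
        improved = False
        for floor_frac in (1e-9, 1e-6, 1e-4, 1e-2):
            w_reg = np.maximum(np.abs(w), wmax * floor_frac)
            step = V @ ((V.T @ g) / w_reg)
            norm = np.linalg.norm(step)
            if norm > 1.0:  # trust region: flat directions give wild steps
                step *= 1.0 / norm
            for damp in (1.0, 0.5, 0.25, 0.1, 0.01):
                x_new = x - damp * step
                f_new, g_new = _neg_mean_loglik_grad(x_new, index, stats)
                if f_new <= fval + 1e-12 and np.max(np.abs(g_new)) < gnorm:
                    x, fval, g = x_new, f_new, g_new
                    gnorm = float(np.max(np.abs(g)))
                    nit += 1
                    improved = True
                    break
            if improved:
                break
        if not improved:
            break
    converged = gnorm < options.grad_tol and fval < _BIG / 2
    return _OptOut(x=x, fun=fval, nit=nit), gnorm, converged


def fit(index: ParameterIndex, panel, options: FitOptions | None = None) -> FitResult:
    """Maximize the FIML likelihood and assemble standardized inference.

    ``panel`` may be a :class:`~riclpm.preprocess.ModelPanel`, a
    :class:`PatternStats`, or a plain (n, 2T) array with NaN for missing.
    Non-convergence is flagged on the result, never raised.
    """
    if options is None:
        options = FitOptions()
    stats = _as_stats(panel)
    if stats.p != 2 * index.T:
        raise ValueError(f"panel has {stats.p} variables, model expects {2 * index.T}")
    if index.df < 0:  # pragma: no cover - build_* already guards
        raise InvalidParameterError("model is not identified")
    labels = panel.schedule.labels if hasattr(panel, "schedule") else ("a", "b")

    rng = np.random.default_rng(options.seed)
    x0 = _start_values(index, stats)
    starts = [x0]
    for _ in range(options.n_starts - 1):
        starts.append(x0 + options.perturb_scale * rng.standard_normal(x0.size))

    best = None
    for s in starts:
        res, gnorm, conv = _run_opt(s, index, stats, options)
        if best is None or res.fun < best[0].fun:
            best = (res, gnorm, conv)
    attempts = 0
    while not best[2] and attempts < options.retries:
        attempts += 1
        s = best[0].x + options.perturb_scale * rng.standard_normal(x0.size)
        res, gnorm, conv = _run_opt(s, index, stats, options)
        if res.fun < best[0].fun or (conv and not best[2]):
            best = (res, gnorm, conv)
    res, gnorm, converged = best

    x_hat = res.x
    params = index.unpack(x_hat)
    loglik = -res.fun * stats.n
    # variance floor active? inspect log-diagonal entries of the between block
    off = index._offsets()
    diag_positions = np.cumsum(np.arange(1, (2 if index.kind == "riclpm" else 4) + 1)) - 1
    boundary = bool(np.any(x_hat[off["between"]][diag_positions] < -12.0))

    result = FitResult(
        index=index, labels=labels, x=x_hat, params=params, loglik=float(loglik),
        n=stats.n, n_patterns=stats.n_patterns, converged=bool(converged),
        n_iter=int(res.nit), grad_norm=gnorm, boundary=boundary,
    )
    result = standardize(result)
    if options.se != "none":
        result = robust_se(result, stats, mode=options.se,
                           fd_step=options.fd_step, hess_step=options.hess_step)
    return result


def fit_to_moments(index: ParameterIndex, mu: np.ndarray, Sigma: np.ndarray,
                   n: int = 100000, options: FitOptions | None = None) -> FitResult:
    """Fit to target moments (the large-sample limit of a data fit)."""
    if options is None:
        options = FitOptions(se="none")
    stats = PatternStats.from_moments(mu, Sigma, n)
    return fit(index, stats, options)


def standardize(result: FitResult) -> FitResult:
    """Attach standardized path coefficients and correlations to a fit."""
    vals = standardized_vector(result.index, result.x)
    if np.any(np.isnan(vals)):
        warnings.warn("zero within-component variance: some standardized values undefined")
    result.std_values = vals
    return result


# ---------------------------------------------------------------------------
# robust / observed-information standard errors

def _moment_jacobians(index: ParameterIndex, x: np.ndarray, step: float):
    q = x.size
    p = 2 * index.T
    dmu = np.empty((p, q))
    dSig = np.empty((p, p, q))
    for j in range(q):
        h = step * max(1.0, abs(x[j]))
        xp, xm = x.copy(), x.copy()
        xp[j] += h
        xm[j] -= h
        mup, Sp = index.moments(xp)
        mum, Sm = index.moments(xm)
        dmu[:, j] = (mup - mum) / (2 * h)
        dSig[:, :, j] = (Sp - Sm) / (2 * h)
    return dmu, dSig


def _mean_hessian(index: ParameterIndex, x: np.ndarray, stats: PatternStats,
                  step: float) -> np.ndarray:
    q = x.size
    H = np.empty((q, q))
    for j in range(q):
        h = step * max(1.0, abs(x[j]))
        xp, xm = x.copy(), x.copy()
        xp[j] += h
        xm[j] -= h
        _, gp = _neg_mean_loglik_grad(xp, index, stats)
        _, gm = _neg_mean_loglik_grad(xm, index, stats)
        H[:, j] = (gp - gm) / (2 * h)
    return (H + H.T) / 2.0


def _row_scores(index: ParameterIndex, x: np.ndarray, stats: PatternStats,
                step: float) -> np.ndarray:
    """Per-row score vectors (n, q) of the log-likelihood."""
    dmu, dSig = _moment_jacobians(index, x, step)
    mu, Sigma = index.moments(x)
    q = x.size
    scores = np.empty((stats.n, q))
    pos = 0
    for g in stats.groups:
        ix = g.idx
        k = ix.size
        So = Sigma[np.ix_(ix, ix)]
        c, low = cho_factor(So, lower=True)
        Sinv = cho_solve((c, low), np.eye(k))
        D = g.rows - mu[ix]
        dmu_o = dmu[ix, :]
        dS_o = dSig[np.ix_(ix, ix)][:, :, :]
        # mean part: d^T Sinv dmu
        T1 = D @ Sinv
        s = T1 @ dmu_o
        # covariance part: 0.5 (d^T K d - tr(Sinv dS)) with K = Sinv dS Sinv
        K = np.einsum("ab,bcq,cd->adq", Sinv, dS_o, Sinv, optimize=True)
        s += 0.5 * (np.einsum("na,abq,nb->nq", D, K, D, optimize=True)
                    - np.einsum("ab,baq->q", Sinv, dS_o)[None, :])
        scores[pos:pos + g.n] = s
        pos += g.n
    return scores


def robust_se(result: FitResult, panel, mode: Literal["robust", "observed"] = "robust",
              fd_step: float = 1e-6, hess_step: float = 1e-5) -> FitResult:
    """Attach a parameter covariance and delta-method SEs to a fit.

    ``robust``: Huber-White sandwich A^-1 B A^-1 / n with A the mean per-row
    negative Hessian and B the mean outer product of per-row scores.
    ``observed``: inverse observed information A^-1 / n.  Falls back to the
    pseudo-inverse (with a warning) when A is singular, and to observed-
    information SEs when row-level data are unavailable.
    """
    stats = _as_stats(panel)
    index, x, n = result.index, result.x, stats.n
    A = _mean_hessian(index, x, stats, hess_step)
    try:
        Ainv = np.linalg.inv(A)
    except np.linalg.LinAlgError:
        warnings.warn("singular Hessian; using pseudo-inverse for standard errors")
        Ainv = np.linalg.pinv(A)
    if mode == "robust" and not stats.has_rows():
        warnings.warn("no row-level data available; falling back to observed-information SEs")
        mode = "observed"
    if mode == "robust":
        S = _row_scores(index, x, stats, fd_step)
        Bmat = S.T @ S / n
        V = Ainv @ Bmat @ Ainv / n
    else:
        V = Ainv / n
    V = (V + V.T) / 2.0
    result.vcov = V
    result.se_mode = mode

    # delta method for standardized quantities
    vals = standardized_vector(index, x)
    m = vals.size
    J = np.empty((m, x.size))
    for j in range(x.size):
        h = fd_step * max(1.0, abs(x[j]))
        xp, xm = x.copy(), x.copy()
        xp[j] += h
        xm[j] -= h
        J[:, j] = (standardized_vector(index, xp) - standardized_vector(index, xm)) / (2 * h)
    cov_std = J @ V @ J.T
    result.std_se = np.sqrt(np.clip(np.diag(cov_std), 0.0, None))
    result.std_values = vals
    return result


# ---------------------------------------------------------------------------
# saturated and baseline models

def _saturated_em(stats: PatternStats, max_iter: int = 500, tol: float = 1e-9):
    """EM for the unstructured Gaussian model under arbitrary missingness.

    E-step sufficient statistics are accumulated per pattern bucket with
    batched linear algebra; the per-group algebra works on group means d and
    scatters S: sum_i x_o c_i^T = S + n xbar d^T etc.
    """
    p = stats.p
    mu, Sigma = stats.pairwise_moments()
    Sigma = _nearest_pd(Sigma, 1e-6)
    allv = np.arange(p)
    buckets = stats.buckets()
    midx_cache = {
        k: np.stack([np.setdiff1d(allv, row, assume_unique=True) for row in b["idx"]])
        for k, b in buckets.items() if k < p
    }
    ll = -np.inf
    for _ in range(max_iter):
        ll_old = ll
        T1 = np.zeros(p)
        T2 = np.zeros((p, p))
        ll = 0.0
        for k, b in buckets.items():
            idx = b["idx"]
            n_g = b["n"]
            Sub = Sigma[idx[:, :, None], idx[:, None, :]]
            L = np.linalg.cholesky(Sub)
            Linv = np.linalg.inv(L)
            Sinv = np.einsum("mba,mbc->mac", Linv, Linv)
            xbar = b["mean"]
            d = xbar - mu[idx]
            Sd = np.einsum("mab,mb->ma", Sinv, d)
            logdet = 2.0 * np.log(np.diagonal(L, axis1=1, axis2=2)).sum(axis=1)
            ll += -0.5 * (np.sum(n_g * (k * _LOG2PI + logdet))
                          + np.einsum("mab,mab->", Sinv, b["scatter"])
                          + np.sum(n_g * np.einsum("ma,ma->m", d, Sd)))
            cross_oo = b["scatter"] + n_g[:, None, None] * np.einsum("ma,mb->mab", xbar, xbar)
            np.add.at(T1, idx, n_g[:, None] * xbar)
            np.add.at(T2, (idx[:, :, None], idx[:, None, :]), cross_oo)
            if k == p:
                continue
            midx = midx_cache[k]
            Smo = Sigma[midx[:, :, None], idx[:, None, :]]       # (m, p-k, k)
            A = np.einsum("mab,mbc->mac", Smo, Sinv)
            e_m = mu[midx] + np.einsum("mab,mb->ma", A, d)
            Cm = (Sigma[midx[:, :, None], midx[:, None, :]]
                  - np.einsum("mab,mcb->mac", A, Smo))
            np.add.at(T1, midx, n_g[:, None] * e_m)
            sum_xo_cT = b["scatter"] + n_g[:, None, None] * np.einsum("ma,mb->mab", xbar, d)
            sum_xo_em = (n_g[:, None, None] * np.einsum("ma,mb->mab", xbar, mu[midx])
                         + np.einsum("mab,mcb->mac", sum_xo_cT, A))
            np.add.at(T2, (idx[:, :, None], midx[:, None, :]), sum_xo_em)
            np.add.at(T2, (midx[:, :, None], idx[:, None, :]), sum_xo_em.transpose(0, 2, 1))
            cc = b["scatter"] + n_g[:, None, None] * np.einsum("ma,mb->mab", d, d)
            Asum_c = n_g[:, None] * np.einsum("mab,mb->ma", A, d)
            sum_em_em = (n_g[:, None, None] * np.einsum("ma,mb->mab", mu[midx], mu[midx])
                         + np.einsum("ma,mb->mab", mu[midx], Asum_c)
                         + np.einsum("ma,mb->mab", Asum_c, mu[midx])
                         + np.einsum("mab,mbc,mdc->mad", A, cc, A)
                         + n_g[:, None, None] * Cm)
            np.add.at(T2, (midx[:, :, None], midx[:, None, :]), sum_em_em)
        mu_new = T1 / stats.n
        Sigma_new = T2 / stats.n - np.outer(mu_new, mu_new)
        mu, Sigma = mu_new, _nearest_pd((Sigma_new + Sigma_new.T) / 2.0, 1e-12)
        if abs(ll - ll_old) < tol * (1 + abs(ll)):
            break
    return mu, Sigma, ll


def _saturated_polish(stats: PatternStats, mu0, Sigma0):
    """Quasi-Newton refinement of the saturated FIML solution."""
    p = stats.p
    L0 = np.linalg.cholesky(_nearest_pd(Sigma0, 1e-10))

    def pack(mu, L):
        v = []
        for i in range(p):
            for j in range(i + 1):
                v.append(np.log(max(L[i, i], 1e-12)) if i == j else L[i, j])
        return np.concatenate([mu, np.asarray(v)])

    def unpack(z):
        mu = z[:p]
        L = np.zeros((p, p))
        k = 0
        for i in range(p):
            for j in range(i + 1):
                L[i, j] = np.exp(z[p + k]) if i == j else z[p + k]
                k += 1
        return mu, L

    def obj(z):
        mu, L = unpack(z)
        Sigma = L @ L.T
        out = _group_loglik(mu, Sigma, stats, accumulate=True)
        if out is None:
            return _BIG, np.zeros_like(z)
        ll, G, gmu = out
        Abar = (G + G.T) @ L
        gL = []
        for i in range(p):
            for j in range(i + 1):
                gL.append(Abar[i, i] * L[i, i] if i == j else Abar[i, j])
        grad = np.concatenate([gmu, np.asarray(gL)])
        return -ll / stats.n, -grad / stats.n

    z0 = pack(np.asarray(mu0, float), L0)
    res = minimize(obj, z0, jac=True, method="L-BFGS-B",
                   options={"maxiter": 1000, "maxcor": 40, "ftol": 1e-13, "gtol": 1e-8})
    mu, L = unpack(res.x)
    return mu, L @ L.T, -res.fun * stats.n


def saturated_loglik(panel) -> tuple[float, np.ndarray, np.ndarray]:
    """Maximized FIML log-likelihood of the unstructured-moments model.

    Returns (loglik, mu_hat, Sigma_hat).  With complete data this is the
    closed-form sample mean and ML covariance; under missingness an EM pass
    warm-starts a quasi-Newton refinement.
    """
    stats = _as_stats(panel)
    if stats.is_complete():
        g = stats.groups[0]
        mu = g.mean.copy()
        Sigma = g.scatter / g.n
        c, low = cho_factor(Sigma, lower=True)
        logdet = 2.0 * np.log(np.diag(c)).sum()
        ll = -0.5 * g.n * (stats.p * _LOG2PI + logdet + stats.p)
        return float(ll), mu, Sigma
    mu, Sigma, _ = _saturated_em(stats)
    mu, Sigma, ll = _saturated_polish(stats, mu, Sigma)
    return float(ll), mu, Sigma


def baseline_loglik(panel) -> tuple[float, int]:
    """Independence baseline: free means and variances, zero covariances.

    The likelihood factorizes over variables, so each variable's ML solution
    is the mean and (ML) variance of its observed values.  Returns the
    maximized log-likelihood and the baseline degrees of freedom
    p(p+3)/2 - 2p.
    """
    stats = _as_stats(panel)
    p = stats.p
    s1 = np.zeros(p)
    s2 = np.zeros(p)
    cnt = np.zeros(p)
    for g in stats.groups:
        ix = g.idx
        s1[ix] += g.n * g.mean
        s2[ix] += np.diag(g.scatter) + g.n * g.mean ** 2
        cnt[ix] += g.n
    ll = 0.0
    for j in range(p):
        nj = cnt[j]
        if nj == 0:
            continue
        mean = s1[j] / nj
        var = s2[j] / nj - mean ** 2
        ll += -0.5 * nj * (_LOG2PI + np.log(var) + 1.0)
    df_base = p * (p + 3) // 2 - 2 * p
    return float(ll), df_base


def saturated_and_baseline_loglik(panel) -> tuple[float, float, int]:
    """(saturated loglik, baseline loglik, baseline df) for fit indices."""
    ll_sat, _, _ = saturated_loglik(panel)
    ll_base, df_base = baseline_loglik(panel)
    return ll_sat, ll_base, df_base
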