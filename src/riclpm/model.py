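"""Model core: RI-CLPM and ALT-SR parameterizations and implied moments.

The random-intercept cross-lagged panel model (RI-CLPM) decomposes two
repeatedly measured constructs into

* a between-person part: two random intercepts (one per construct) loading 1
  on every wave of their construct, with a freely estimated 2x2 covariance
  ``psi``;
* a within-person part: wave-specific latent fluctuations with loading 1 and
  zero measurement-error variance, so the observed score is
  ``mu + intercept + within``;
* lag-1 regressions among the within-components: per lag a 2x2 matrix ``B_t``
  whose diagonal entries are auto-regressive (AR) coefficients and whose
  off-diagonal entries are cross-lagged (CL) coefficients;
* covariances: ``theta1`` for the wave-1 within-components and innovation
  covariances ``theta_t`` (waves 2..T), whose off-diagonals carry the
  wave-specific residual ("cross-sectional") association.

All blocks are wave-specific (no equality constraints by default) and the
mean structure is saturated: one free mean per observed variable.  With
``p = 2T`` observed variables the model therefore has
``3 + 3 + 4(T-1) + 3(T-1) + 2T`` free parameters against ``p(p+3)/2``
observed moments.

The ALT-SR variant adds linear latent growth: per construct a random slope
whose loadings are fixed to years since that construct's first wave, and a
joint 4x4 covariance of intercepts and slopes.  See :func:`build_altsr` for
the identification conventions.

Covariance blocks are parameterized for unconstrained optimization via
Cholesky factors with log-transformed diagonals (floored at exp(-30), which
lets ``psi`` reach the positive-semidefinite boundary in practice).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Literal

import numpy as np

from .panel import WaveSchedule

__all__ = [
    "NotIdentifiedError",
    "InvalidParameterError",
    "RICLPMParams",
    "ALTSRParams",
    "ParameterIndex",
    "build_riclpm",
    "build_altsr",
    "model_df",
    "altsr_df",
    "implied_moments",
    "within_covariance",
]

_LOG_FLOOR = -30.0  # floor for log-diagonal Cholesky entries


class NotIdentifiedError(ValueError):
    """Raised when a model has more free parameters than observed moments."""


class InvalidParameterError(ValueError):
    """Raised when a structured parameter set violates its invariants."""


def _check_sym_psd(name: str, S: np.ndarray, strict: bool) -> None:
    S = np.asarray(S, float)
    if S.shape != (S.shape[0], S.shape[0]) or not np.allclose(S, S.T, atol=1e-10):
        raise InvalidParameterError(f"{name} must be symmetric, got\n{S}")
    eig = np.linalg.eigvalsh(S)
    if strict and eig.min() <= 0:
        raise InvalidParameterError(f"{name} must be positive definite (eigenvalues {eig})")
    if not strict and eig.min() < -1e-10:
        raise InvalidParameterError(f"{name} must be positive semidefinite (eigenvalues {eig})")


@dataclass
class RICLPMParams:
    """Structured RI-CLPM parameters for T waves of two constructs.

    Variable order everywhere is interleaved: (a_1, b_1, a_2, b_2, ...).
    ``B[t]`` maps within-components at wave t+1 to wave t+2 (0-based list over
    lags); rows index the outcome construct, columns the predictor, so
    ``B[t][0, 1]`` is the cross-lagged effect of construct 1 on construct 0.
    """

    psi: np.ndarray      # (2,2) random-intercept covariance
    theta1: np.ndarray   # (2,2) wave-1 within-component covariance
    B: np.ndarray        # (T-1,2,2) lagged coefficient matrices
    theta: np.ndarray    # (T-1,2,2) innovation covariances, waves 2..T
    mu: np.ndarray       # (2T,) observed-variable means

    def __post_init__(self):
        self.psi = np.asarray(self.psi, float)
        self.theta1 = np.asarray(self.theta1, float)
        self.B = np.asarray(self.B, float)
        self.theta = np.asarray(self.theta, float)
        self.mu = np.asarray(self.mu, float)
        T = self.T
        if self.B.shape != (T - 1, 2, 2) or self.theta.shape != (T - 1, 2, 2):
            raise InvalidParameterError("B and theta must have shape (T-1, 2, 2)")
        if self.mu.shape != (2 * T,):
            raise InvalidParameterError(f"mu must have length {2 * T}")

    @property
    def T(self) -> int:
        return self.mu.shape[0] // 2 if self.mu.ndim == 1 else 0

    def validate(self) -> None:
        _check_sym_psd("psi", self.psi, strict=False)
        _check_sym_psd("theta1", self.theta1, strict=False)
        for t in range(self.theta.shape[0]):
            _check_sym_psd(f"theta[{t + 2}]", self.theta[t], strict=True)


@dataclass
class ALTSRParams:
    """ALT-SR parameters: RI-CLPM dynamics plus linear latent growth.

    ``phi`` is the joint covariance of (intercept_a, intercept_b, slope_a,
    slope_b); ``slope_loadings[c, t]`` is fixed to years since construct c's
    first wave.  With ``means_mode == "saturated"`` the observed means ``mu``
    are free and the slope means are fixed at 0 (only between-person variance
    in trends is modelled); with ``"structured"`` the observed means equal
    ``Lambda @ factor_means`` with 4 free factor means.
    """

    phi: np.ndarray              # (4,4) intercept/slope covariance
    theta1: np.ndarray
    B: np.ndarray
    theta: np.ndarray
    slope_loadings: np.ndarray   # (2,T), fixed
    mu: np.ndarray | None = None           # (2T,) when saturated means
    factor_means: np.ndarray | None = None  # (4,) when structured means
    means_mode: Literal["saturated", "structured"] = "saturated"

    def __post_init__(self):
        self.phi = np.asarray(self.phi, float)
        self.theta1 = np.asarray(self.theta1, float)
        self.B = np.asarray(self.B, float)
        self.theta = np.asarray(self.theta, float)
        self.slope_loadings = np.asarray(self.slope_loadings, float)
        if self.mu is not None:
            self.mu = np.asarray(self.mu, float)
        if self.factor_means is not None:
            self.factor_means = np.asarray(self.factor_means, float)

    @property
    def T(self) -> int:
        return self.slope_loadings.shape[1]

    def loading_matrix(self) -> np.ndarray:
        """(2T, 4) fixed loadings of intercepts and slopes."""
        T = self.T
        Lam = np.zeros((2 * T, 4))
        for t in range(T):
            for c in range(2):
                Lam[2 * t + c, c] = 1.0
                Lam[2 * t + c, 2 + c] = self.slope_loadings[c, t]
        return Lam

    def validate(self) -> None:
        _check_sym_psd("phi", self.phi, strict=False)
        _check_sym_psd("theta1", self.theta1, strict=False)
        for t in range(self.theta.shape[0]):
            _check_sym_psd(f"theta[{t + 2}]", self.theta[t], strict=True)
        lam = self.slope_loadings
        if np.any(lam[:, 0] != 0) or np.any(np.diff(lam, axis=1) <= 0):
            raise InvalidParameterError("slope loadings must start at 0 and increase")


# ---------------------------------------------------------------------------
# free-parameter counting

def _riclpm_free(T: int) -> int:
    return 3 + 3 + 4 * (T - 1) + 3 * (T - 1) + 2 * T


def _altsr_free(T: int, means_mode: str) -> int:
    base = 10 + 3 + 4 * (T - 1) + 3 * (T - 1)
    return base + (2 * T if means_mode == "saturated" else 4)


def model_df(T: int) -> int:
    """Degrees of freedom of the lag-1 RI-CLPM with saturated means.

    Observed moments are all means plus the unique covariance entries of the
    2T observed variables: p(p+3)/2 with p = 2T.
    """
    if T < 1:
        raise ValueError("T must be at least 1")
    p = 2 * T
    df = p * (p + 3) // 2 - _riclpm_free(T)
    if df < 0:
        raise NotIdentifiedError(
            f"RI-CLPM with T={T} has {_riclpm_free(T)} free parameters but only "
            f"{p * (p + 3) // 2} observed moments"
        )
    return df


def altsr_df(T: int, means_mode: str = "saturated") -> int:
    if T < 1:
        raise ValueError("T must be at least 1")
    p = 2 * T
    df = p * (p + 3) // 2 - _altsr_free(T, means_mode)
    if df < 0:
        raise NotIdentifiedError(f"ALT-SR with T={T} is not identified")
    return df


# ---------------------------------------------------------------------------
# Cholesky packing helpers (2x2 analytic, general for the 4x4 phi block)

def _chol_factor(S: np.ndarray) -> np.ndarray:
    """Lower Cholesky factor tolerating the PSD boundary."""
    S = np.asarray(S, float)
    try:
        return np.linalg.cholesky(S)
    except np.linalg.LinAlgError:
        w, V = np.linalg.eigh((S + S.T) / 2.0)
        w = np.clip(w, 0.0, None)
        # re-orthogonalize into a lower-triangular factor via QR of (V sqrt(w))^T
        A = V * np.sqrt(w)
        q, r = np.linalg.qr(A.T)
        L = r.T * np.sign(np.diag(r))
        return L


def _pack_cov(S: np.ndarray) -> np.ndarray:
    """Pack a symmetric PSD matrix as lower-triangular Cholesky entries,
    row-major, with log diagonals (floored)."""
    L = _chol_factor(S)
    d = L.shape[0]
    out = []
    for i in range(d):
        for j in range(i + 1):
            if i == j:
                out.append(np.log(max(L[i, i], np.exp(_LOG_FLOOR))))
            else:
                out.append(L[i, j])
    return np.array(out)


def _unpack_chol(v: np.ndarray, d: int) -> np.ndarray:
    L = np.zeros((d, d))
    k = 0
    for i in range(d):
        for j in range(i + 1):
            L[i, j] = np.exp(v[k]) if i == j else v[k]
            k += 1
    return L


def _chol_grad_to_packed(Sbar: np.ndarray, L: np.ndarray) -> np.ndarray:
    """Chain rule through S = L L^T onto the packed Cholesky entries.

    ``Sbar`` is the (symmetric) full-matrix gradient d(objective)/dS.
    """
    Abar = (Sbar + Sbar.T) @ L
    d = L.shape[0]
    out = []
    for i in range(d):
        for j in range(i + 1):
            out.append(Abar[i, i] * L[i, i] if i == j else Abar[i, j])
    return np.array(out)


_NTRI2 = 3   # packed length of a 2x2 covariance
_NTRI4 = 10  # packed length of a 4x4 covariance


# ---------------------------------------------------------------------------
# within-process chain

def _chain_matrix(B: np.ndarray, T: int) -> np.ndarray:
    """Block lower-triangular map from stacked innovations to within-components.

    Block (t, s) equals B_{t-1} ... B_s for s < t (0-based waves) and I on the
    diagonal, so that ``within = Lmat @ innovations``.
    """
    Lmat = np.zeros((2 * T, 2 * T))
    blocks = [[None] * T for _ in range(T)]
    for t in range(T):
        blocks[t][t] = np.eye(2)
        for s in range(t - 1, -1, -1):
            blocks[t][s] = B[t - 1] @ blocks[t - 1][s]
    for t in range(T):
        for s in range(t + 1):
            Lmat[2 * t:2 * t + 2, 2 * s:2 * s + 2] = blocks[t][s]
    return Lmat


def within_covariance(params: RICLPMParams | ALTSRParams) -> np.ndarray:
    """Model-implied covariance of the within-components (2T x 2T)."""
    T = params.T
    Lmat = _chain_matrix(params.B, T)
    D = np.zeros((2 * T, 2 * T))
    D[0:2, 0:2] = params.theta1
    for t in range(1, T):
        D[2 * t:2 * t + 2, 2 * t:2 * t + 2] = params.theta[t - 1]
    return Lmat @ D @ Lmat.T


def implied_moments(params: RICLPMParams | ALTSRParams) -> tuple[np.ndarray, np.ndarray]:
    """Model-implied mean vector (2T) and covariance (2T x 2T).

    The covariance is the between-person part (intercepts, and slopes for the
    ALT-SR) plus the within-process covariance implied by the lag-1 recursion.
    """
    params.validate()
    T = params.T
    W = within_covariance(params)
    if isinstance(params, ALTSRParams):
        Lam = params.loading_matrix()
        Sigma = Lam @ params.phi @ Lam.T + W
        if params.means_mode == "structured":
            mu = Lam @ params.factor_means
        else:
            mu = params.mu
    else:
        Sigma = np.tile(params.psi, (T, T)) + W
        mu = params.mu
    return np.asarray(mu, float).copy(), (Sigma + Sigma.T) / 2.0


# ---------------------------------------------------------------------------
# parameter index: pack/unpack bijection and adjoint gradients

@dataclass
class ParameterIndex:
    """Bijection between the optimizer vector and structured parameters.

    Packing order: between-person covariance block (Cholesky, log-diagonal),
    wave-1 within block, lagged matrices ``B_t`` (lag-major, row-major),
    innovation blocks, then means.
    """

    kind: Literal["riclpm", "altsr"]
    T: int
    means_mode: Literal["saturated", "structured"] = "saturated"
    slope_loadings: np.ndarray | None = None

    @property
    def n_free(self) -> int:
        if self.kind == "riclpm":
            return _riclpm_free(self.T)
        return _altsr_free(self.T, self.means_mode)

    @property
    def df(self) -> int:
        return model_df(self.T) if self.kind == "riclpm" else altsr_df(self.T, self.means_mode)

    @property
    def n_cov(self) -> int:
        return _NTRI2 if self.kind == "riclpm" else _NTRI4

    def _offsets(self) -> dict[str, slice]:
        T, nc = self.T, self.n_cov
        o = {}
        k = 0
        o["between"] = slice(k, k + nc); k += nc
        o["theta1"] = slice(k, k + _NTRI2); k += _NTRI2
        o["B"] = slice(k, k + 4 * (T - 1)); k += 4 * (T - 1)
        o["theta"] = slice(k, k + 3 * (T - 1)); k += 3 * (T - 1)
        nmu = 2 * T if (self.kind == "riclpm" or self.means_mode == "saturated") else 4
        o["mu"] = slice(k, k + nmu); k += nmu
        assert k == self.n_free
        return o

    def param_names(self) -> list[str]:
        T = self.T
        names: list[str] = []
        dim = 2 if self.kind == "riclpm" else 4
        pre = "psi" if self.kind == "riclpm" else "phi"
        names += [f"{pre}_chol_{i}{j}" for i in range(dim) for j in range(i + 1)]
        names += [f"theta1_chol_{i}{j}" for i in range(2) for j in range(i + 1)]
        for t in range(1, T):
            names += [f"B{t}_{i}{j}" for i in range(2) for j in range(2)]
        for t in range(2, T + 1):
            names += [f"theta{t}_chol_{i}{j}" for i in range(2) for j in range(i + 1)]
        if self.kind == "riclpm" or self.means_mode == "saturated":
            names += [f"mu_{v}" for v in range(2 * T)]
        else:
            names += ["mean_int_a", "mean_int_b", "mean_slope_a", "mean_slope_b"]
        return names

    # -- pack / unpack -----------------------------------------------------
    def pack(self, params: RICLPMParams | ALTSRParams) -> np.ndarray:
        o = self._offsets()
        x = np.empty(self.n_free)
        if self.kind == "riclpm":
            x[o["between"]] = _pack_cov(params.psi)
        else:
            x[o["between"]] = _pack_cov(params.phi)
        x[o["theta1"]] = _pack_cov(params.theta1)
        x[o["B"]] = np.asarray(params.B).reshape(-1)
        x[o["theta"]] = np.concatenate([_pack_cov(params.theta[t]) for t in range(self.T - 1)])
        if self.kind == "riclpm" or self.means_mode == "saturated":
            x[o["mu"]] = params.mu
        else:
            x[o["mu"]] = params.factor_means
        return x

    def unpack(self, x: np.ndarray) -> RICLPMParams | ALTSRParams:
        x = np.asarray(x, float)
        if x.shape != (self.n_free,):
            raise ValueError(f"expected packed vector of length {self.n_free}, got {x.shape}")
        o = self._offsets()
        T = self.T
        dim = 2 if self.kind == "riclpm" else 4
        Lb = _unpack_chol(x[o["between"]], dim)
        L1 = _unpack_chol(x[o["theta1"]], 2)
        B = x[o["B"]].reshape(T - 1, 2, 2).copy()
        th = x[o["theta"]].reshape(T - 1, 3)
        theta = np.stack([_unpack_chol(th[t], 2) @ _unpack_chol(th[t], 2).T for t in range(T - 1)])
        if self.kind == "riclpm":
            return RICLPMParams(psi=Lb @ Lb.T, theta1=L1 @ L1.T, B=B, theta=theta, mu=x[o["mu"]].copy())
        if self.means_mode == "saturated":
            return ALTSRParams(phi=Lb @ Lb.T, theta1=L1 @ L1.T, B=B, theta=theta,
                               slope_loadings=self.slope_loadings, mu=x[o["mu"]].copy(),
                               means_mode="saturated")
        return ALTSRParams(phi=Lb @ Lb.T, theta1=L1 @ L1.T, B=B, theta=theta,
                           slope_loadings=self.slope_loadings,
                           factor_means=x[o["mu"]].copy(), means_mode="structured")

    # -- moments and adjoint ----------------------------------------------
    def moments(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        return implied_moments(self.unpack_nocheck(x))

    def unpack_nocheck(self, x: np.ndarray) -> RICLPMParams | ALTSRParams:
        # identical to unpack; structured validation happens in implied_moments
        return self.unpack(x)

    def moments_and_adjoint(
        self, x: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray, Callable[[np.ndarray, np.ndarray], np.ndarray]]:
        """Implied (mu, Sigma) plus a reverse-mode map for gradients.

        The returned ``backward(Sigma_bar, mu_bar)`` maps full-matrix
        gradients with respect to the implied moments onto the packed
        parameter vector.  ``Sigma_bar`` must be the derivative treating all
        entries of Sigma as independent (the natural output of Gaussian
        likelihood calculus) and symmetric.
        """
        x = np.asarray(x, float)
        o = self._offsets()
        T = self.T
        dim = 2 if self.kind == "riclpm" else 4
        Lb = _unpack_chol(x[o["between"]], dim)
        L1 = _unpack_chol(x[o["theta1"]], 2)
        B = x[o["B"]].reshape(T - 1, 2, 2)
        th_chols = [_unpack_chol(x[o["theta"]][3 * t:3 * t + 3], 2) for t in range(T - 1)]

        Lmat = _chain_matrix(B, T)
        D = np.zeros((2 * T, 2 * T))
        D[0:2, 0:2] = L1 @ L1.T
        for t in range(1, T):
            A = th_chols[t - 1]
            D[2 * t:2 * t + 2, 2 * t:2 * t + 2] = A @ A.T
        W = Lmat @ D @ Lmat.T

        if self.kind == "riclpm":
            Sigma = np.tile(Lb @ Lb.T, (T, T)) + W
            Lam = None
            mu = x[o["mu"]].copy()
        else:
            Lam = np.zeros((2 * T, dim))
            for t in range(T):
                for c in range(2):
                    Lam[2 * t + c, c] = 1.0
                    Lam[2 * t + c, 2 + c] = self.slope_loadings[c, t]
            Sigma = Lam @ (Lb @ Lb.T) @ Lam.T + W
            mu = x[o["mu"]].copy() if self.means_mode == "saturated" else Lam @ x[o["mu"]]
        Sigma = (Sigma + Sigma.T) / 2.0

        def backward(Sigma_bar: np.ndarray, mu_bar: np.ndarray) -> np.ndarray:
            G = (Sigma_bar + Sigma_bar.T) / 2.0
            grad = np.zeros(self.n_free)
            # between-person block
            if self.kind == "riclpm":
                Sb = G.reshape(T, 2, T, 2).sum(axis=(0, 2))
            else:
                Sb = Lam.T @ G @ Lam
            grad[o["between"]] = _chol_grad_to_packed(Sb, Lb)
            # innovation blocks: D_bar = Lmat^T G Lmat
            Dbar = Lmat.T @ G @ Lmat
            grad[o["theta1"]] = _chol_grad_to_packed(Dbar[0:2, 0:2], L1)
            gth = np.empty(3 * (T - 1))
            for t in range(1, T):
                gth[3 * (t - 1):3 * t] = _chol_grad_to_packed(
                    Dbar[2 * t:2 * t + 2, 2 * t:2 * t + 2], th_chols[t - 1]
                )
            grad[o["theta"]] = gth
            # lagged matrices via the chain recursion, processed backwards
            Lbar_full = 2.0 * G @ Lmat @ D
            Lbar = [[Lbar_full[2 * t:2 * t + 2, 2 * s:2 * s + 2].copy() for s in range(T)] for t in range(T)]
            Lblocks = [[Lmat[2 * t:2 * t + 2, 2 * s:2 * s + 2] for s in range(T)] for t in range(T)]
            Bbar = np.zeros((T - 1, 2, 2))
            for t in range(T - 1, 0, -1):
                for s in range(t):
                    Bbar[t - 1] += Lbar[t][s] @ Lblocks[t - 1][s].T
                    Lbar[t - 1][s] += B[t - 1].T @ Lbar[t][s]
            grad[o["B"]] = Bbar.reshape(-1)
            # means
            if self.kind == "riclpm" or self.means_mode == "saturated":
                grad[o["mu"]] = mu_bar
            else:
                grad[o["mu"]] = Lam.T @ mu_bar
            return grad

        return mu, Sigma, backward


def build_riclpm(T: int) -> ParameterIndex:
    """Parameter index for the lag-1 RI-CLPM with T >= 3 waves."""
    if T <= 2:
        raise NotIdentifiedError(
            f"RI-CLPM needs T >= 3 waves (T={T} gives negative degrees of freedom)"
        )
    model_df(T)  # raises if not identified
    return ParameterIndex(kind="riclpm", T=T)


def build_altsr(
    T: int,
    schedule: WaveSchedule,
    means_mode: Literal["saturated", "structured"] = "saturated",
) -> ParameterIndex:
    """Parameter index for the ALT-SR with linear latent growth.

    Slope loadings are fixed to years since each construct's first wave, read
    off the schedule.  With saturated means the slope means are fixed at 0
    (they would be collinear with the free observed means); structured means
    replace the 2T free means with 4 factor means.
    """
    if T <= 3:
        raise NotIdentifiedError("ALT-SR with linear growth needs T >= 4 waves")
    if schedule.n_waves != T:
        raise ValueError(f"schedule has {schedule.n_waves} waves, expected {T}")
    lam = np.array([[a - seq[0] for a in seq] for seq in schedule.ages])
    return ParameterIndex(kind="altsr", T=T, means_mode=means_mode, slope_loadings=lam)
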