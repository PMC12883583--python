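"""Synthetic two-construct panels with RI-CLPM structure.

Generates raw-scale datasets that look like a birth-cohort follow-up of
depressive-symptom questionnaire totals (integers 0-26, right-skewed) and a
positive, right-skewed cardio-metabolic marker (fat mass index, kg/m^2),
measured at uneven ages with substantial and rising missingness.  The
generator draws exactly the latent structure the analysis model assumes —
random intercepts, lag-1 within-person dynamics, wave-specific innovation
correlations — on the normalized [0, 1] scale and then maps through the
inverse of the preprocessing transforms (squaring for the questionnaire,
exponentiation for the marker), so the preprocessing and estimation stages
can be exercised end to end against a known truth.

Draw order under a single seed (stable contract for fixtures): random
intercepts, wave-1 within-components, innovations for waves 2..T, then
missingness uniforms construct-by-construct in wave order.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit

from .model import InvalidParameterError, RICLPMParams
from .panel import RawPanel, WaveSchedule, write_panel
from . import reference

__all__ = [
    "MissingSpec",
    "LinkSpec",
    "GeneratingTruth",
    "alspac_like_truth",
    "simulate_panel",
    "emit_fixture",
]


@dataclass(frozen=True)
class MissingSpec:
    """Per-construct, per-wave missingness targets and mechanism.

    mechanism:
        ``"none"``  — no cells are removed;
        ``"mcar"``  — each cell independently missing at its wave's rate;
        ``"mar"``   — wave 1 is MCAR; from wave 2 on, the missingness log-odds
        are linear in the participant's *observed* previous-wave raw score of
        the same construct (slope ``mar_slopes``, per raw-score unit).  Rows
        whose previous-wave value is itself missing revert to the marginal
        rate.  Intercepts are calibrated per wave on the realized sample so
        the marginal missing fraction matches the target.
    """

    rates: tuple[tuple[float, ...], tuple[float, ...]]
    mechanism: Literal["none", "mcar", "mar"] = "mar"
    mar_slopes: tuple[float, float] = (0.08, 0.10)

    def __post_init__(self):
        object.__setattr__(self, "rates", tuple(tuple(float(r) for r in seq) for seq in self.rates))
        arr = np.asarray(self.rates)
        if arr.min() < 0 or arr.max() > 1:
            raise ValueError("missing proportions must lie in [0, 1]")
        if self.mechanism not in ("none", "mcar", "mar"):
            raise ValueError(f"unknown mechanism {self.mechanism!r}")
        if self.mechanism == "mar" and arr.shape[1] < 2:
            raise ValueError("MAR-on-previous-wave requires at least 2 waves")

    @classmethod
    def none(cls, T: int) -> "MissingSpec":
        return cls(rates=(tuple([0.0] * T), tuple([0.0] * T)), mechanism="none")

    @classmethod
    def alspac_like(cls, mechanism: Literal["mcar", "mar"] = "mar") -> "MissingSpec":
        """The reference cohort's missingness profile (15%-54%)."""
        return cls(rates=(reference.REFERENCE_MISSING_DEP, reference.REFERENCE_MISSING_CM),
                   mechanism=mechanism)


@dataclass(frozen=True)
class LinkSpec:
    """Raw-scale link: inverse of the preprocessing transform for a construct.

    ``kind="square"`` maps the normalized score through the sqrt scale
    [lo, hi] and squares (questionnaire totals; rounded to integers and
    clipped to [lo^2, hi^2]); ``kind="exp"`` maps through the ln scale and
    exponentiates; ``kind="identity"`` rescales linearly to [lo, hi].
    """

    kind: Literal["square", "exp", "identity"]
    lo: float
    hi: float
    integer: bool = False

    def __post_init__(self):
        if self.hi <= self.lo:
            raise ValueError("link requires hi > lo")

    def to_raw(self, y_norm: np.ndarray) -> np.ndarray:
        s = y_norm * (self.hi - self.lo) + self.lo
        if self.kind == "square":
            s = np.clip(s, self.lo, self.hi)
            raw = s ** 2
        elif self.kind == "exp":
            raw = np.exp(s)
        else:
            raw = s
        if self.integer:
            raw = np.round(raw)
        return raw


@dataclass(frozen=True)
class GeneratingTruth:
    """A normalized-scale RI-CLPM truth plus raw-scale links per construct."""

    params: RICLPMParams
    links: tuple[LinkSpec, LinkSpec]

    def model_scale(self) -> "GeneratingTruth":
        """A copy whose links are the identity on [0, 1].

        Panels simulated from it are already on the model (normalized) scale
        — the exact Gaussian structure the estimator assumes — and can be fed
        to :func:`riclpm.estimation.fit` without preprocessing.
        """
        ident = (LinkSpec(kind="identity", lo=0.0, hi=1.0),
                 LinkSpec(kind="identity", lo=0.0, hi=1.0))
        return GeneratingTruth(params=self.params, links=ident)

    def standardized_B(self) -> np.ndarray:
        """Lagged coefficients on the within-component SD scale.

        Returned in the same layout as ``params.B``; equals ``params.B``
        whenever the construction holds all within variances constant.
        """
        from .model import within_covariance

        W = within_covariance(self.params)
        T = self.params.T
        sd = np.sqrt(np.diag(W)).reshape(T, 2)
        out = np.empty_like(self.params.B)
        for t in range(T - 1):
            for i in range(2):
                for j in range(2):
                    out[t, i, j] = self.params.B[t, i, j] * sd[t, j] / sd[t + 1, i]
        return out


def alspac_like_truth(
    within_var: tuple[float, float] = (0.016, 0.006),
    between_var: tuple[float, float] = (0.008, 0.009),
    ri_cor: float | None = None,
) -> GeneratingTruth:
    """Default six-wave truth calibrated to the reference cohort magnitudes.

    Lagged coefficients are set to the published standardized estimates
    (adiposity AR ~0.54-0.84, depressive-symptom AR ~0.12-0.38, cross-lagged
    paths 0.03-0.13), innovation correlations to the published wave-specific
    residual correlations, and the intercept correlation to 0.11.  Within-
    component variances are held constant over waves (innovations absorb the
    difference), which makes standardized and unstandardized coefficients
    coincide at the truth.  Variance magnitudes are on the normalized [0, 1]
    scale; the defaults imply between-person shares of ~1/3 for depressive
    symptoms and ~0.6 for adiposity.
    """
    T = 6
    if ri_cor is None:
        ri_cor = reference.REFERENCE_RI_COR[0]
    sd_w = np.sqrt(np.asarray(within_var, float))
    # The published targets are standardized; within variances are constant
    # over waves here, so AR entries carry over directly while CL entries are
    # rescaled by the cross-construct within-SD ratio (beta = b * sd_pred/sd_out).
    B = np.empty((T - 1, 2, 2))
    for k in range(T - 1):
        B[k, 0, 0] = reference.REFERENCE_PATHS["ar_dep"][k][1]
        B[k, 1, 1] = reference.REFERENCE_PATHS["ar_cm"][k][1]
        B[k, 0, 1] = reference.REFERENCE_PATHS["cl_cm_to_dep"][k][1] * sd_w[0] / sd_w[1]
        B[k, 1, 0] = reference.REFERENCE_PATHS["cl_dep_to_cm"][k][1] * sd_w[1] / sd_w[0]
    resid_cor = np.array([row[1] for row in reference.REFERENCE_RESIDUAL_CORS])

    # hold within variances constant: C_t has diag within_var at every wave
    C = np.diag(within_var).astype(float)
    C[0, 1] = C[1, 0] = resid_cor[0] * sd_w[0] * sd_w[1]
    theta1 = C.copy()
    theta = np.empty((T - 1, 2, 2))
    for k in range(T - 1):
        prop = B[k] @ C @ B[k].T
        d = np.asarray(within_var) - np.diag(prop)
        if np.any(d <= 0):
            raise InvalidParameterError("within variances too small for the AR magnitudes")
        off = resid_cor[k + 1] * np.sqrt(d[0] * d[1])
        theta[k] = np.array([[d[0], off], [off, d[1]]])
        C = prop + theta[k]
    psi = np.diag(between_var).astype(float)
    psi[0, 1] = psi[1, 0] = ri_cor * np.sqrt(between_var[0] * between_var[1])

    # normalized-scale means rising slightly with age, matching the medians
    # of the reference cohort after sqrt/ln mapping
    mu = np.empty(2 * T)
    mu[0::2] = (0.34, 0.35, 0.38, 0.40, 0.43, 0.44)   # depressive symptoms
    mu[1::2] = (0.48, 0.52, 0.53, 0.55, 0.59, 0.64)   # fat mass index
    params = RICLPMParams(psi=psi, theta1=theta1, B=B, theta=theta, mu=mu)
    links = (
        LinkSpec(kind="square", lo=0.0, hi=float(np.sqrt(26.0)), integer=True),
        LinkSpec(kind="exp", lo=float(np.log(0.6)), hi=float(np.log(28.5))),
    )
    return GeneratingTruth(params=params, links=links)


def _calibrate_mar_intercept(z: np.ndarray, slope: float, target: float) -> float:
    """Intercept a such that mean(expit(a + slope * z)) == target."""
    if target <= 0.0:
        return -np.inf
    if target >= 1.0:
        return np.inf
    def f(a):
        return expit(a + slope * z).mean() - target
    lo, hi = -30.0, 30.0
    return brentq(f, lo, hi, xtol=1e-10)


def simulate_panel(
    truth: GeneratingTruth,
    schedule: WaveSchedule | None = None,
    n: int = 1000,
    missing: MissingSpec | None = None,
    seed: int = 0,
    return_latent: bool = False,
):
    """Simulate a raw-scale panel of ``n`` participants from ``truth``.

    Per participant: draw the random-intercept pair from ``psi``, the wave-1
    within-components from ``theta1``, propagate the lag-1 recursion with
    wave-specific innovations, add means, map through the raw-scale links,
    then apply missingness.  With ``return_latent=True`` a debug dict with
    the latent intercepts, within-components and normalized scores is
    attached for oracle tests (never written to CSV fixtures).

    Returns a :class:`RawPanel`, or ``(RawPanel, latent_dict)``.
    """
    if n < 1:
        raise ValueError(f"n must be at least 1, got {n}")
    params = truth.params
    params.validate()
    T = params.T
    if schedule is None:
        schedule = reference.default_schedule()
    if schedule.n_waves != T:
        raise ValueError(f"truth has {T} waves but schedule has {schedule.n_waves}")
    if missing is None:
        missing = MissingSpec.none(T)
    if len(missing.rates[0]) != T:
        raise ValueError("missing spec wave count does not match the truth")

    rng = np.random.default_rng(seed)

    def draw_mvn(cov: np.ndarray, size: int) -> np.ndarray:
        w, V = np.linalg.eigh((cov + cov.T) / 2.0)
        if w.min() < -1e-10:
            raise InvalidParameterError(f"covariance block is not PSD (eigenvalues {w})")
        A = V * np.sqrt(np.clip(w, 0.0, None))
        return rng.standard_normal((size, cov.shape[0])) @ A.T

    eta = draw_mvn(params.psi, n)                       # (n, 2)
    within = np.empty((n, T, 2))
    within[:, 0, :] = draw_mvn(params.theta1, n)
    for t in range(1, T):
        innov = draw_mvn(params.theta[t - 1], n)
        within[:, t, :] = within[:, t - 1, :] @ params.B[t - 1].T + innov

    y_norm = np.empty((n, 2 * T))
    for t in range(T):
        for c in range(2):
            y_norm[:, 2 * t + c] = params.mu[2 * t + c] + eta[:, c] + within[:, t, c]

    raw = np.empty_like(y_norm)
    for c in range(2):
        raw[:, c::2] = truth.links[c].to_raw(y_norm[:, c::2])

    observed = raw.copy()
    if missing.mechanism != "none":
        for c in range(2):
            for t in range(T):
                target = missing.rates[c][t]
                col = 2 * t + c
                if target <= 0:
                    continue
                if missing.mechanism == "mcar" or t == 0:
                    miss = rng.uniform(size=n) < target
                else:
                    prev = observed[:, 2 * (t - 1) + c]
                    has_prev = ~np.isnan(prev)
                    p = np.full(n, target)
                    if has_prev.sum() >= 2:
                        slope = missing.mar_slopes[c]
                        a = _calibrate_mar_intercept(prev[has_prev], slope, target)
                        p[has_prev] = expit(a + slope * prev[has_prev])
                    miss = rng.uniform(size=n) < p
                observed[miss, col] = np.nan

    panel = RawPanel(ids=np.arange(1, n + 1), values=observed, schedule=schedule)
    if return_latent:
        return panel, {"eta": eta, "within": within, "y_norm": y_norm, "raw": raw}
    return panel


def emit_fixture(panel: RawPanel, path) -> None:
    """Write the panel as a wide CSV plus schedule sidecar (lossless)."""
    write_panel(panel, path)
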