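"""Reference magnitudes used to calibrate the default synthetic cohort.

The default data-generating truth emulates a large UK birth-cohort analysis
of self-reported depressive symptoms (SMFQ totals, 0-26) and fat mass index
(kg/m^2) measured six times each between ages ~10 and ~25.  The constants
below hold the published standardized path estimates, wave schedule,
missingness profile and global fit summary of that analysis.  They serve two
purposes: calibrating the synthetic-data generator, and exercising the
reporting arithmetic (time-adjusted estimates, path summaries) on a known
table.
"""
from __future__ import annotations

from .panel import WaveSchedule

#: Median ages (years) at each wave: depressive symptoms, then fat mass index.
DEP_AGES = (10.6, 12.8, 13.8, 16.6, 17.8, 23.8)
CM_AGES = (9.8, 11.8, 13.8, 15.4, 17.8, 24.5)


def default_schedule(labels: tuple[str, str] = ("dep", "cm")) -> WaveSchedule:
    """The six-wave schedule of the reference cohort."""
    return WaveSchedule(labels=labels, ages=(DEP_AGES, CM_AGES))


#: Standardized lag-1 path estimates with 95% CIs, keyed by path.
#: Path keys: construct 0 = depressive symptoms ("dep"), construct 1 = fat
#: mass index ("cm").  Each entry: (lag, beta, ci_low, ci_high).
REFERENCE_PATHS: dict[str, list[tuple[int, float, float, float]]] = {
    "ar_cm": [
        (1, 0.84, 0.82, 0.85),
        (2, 0.73, 0.71, 0.76),
        (3, 0.84, 0.82, 0.85),
        (4, 0.82, 0.80, 0.84),
        (5, 0.54, 0.47, 0.60),
    ],
    "ar_dep": [
        (1, 0.12, 0.08, 0.16),
        (2, 0.32, 0.28, 0.35),
        (3, 0.21, 0.18, 0.25),
        (4, 0.38, 0.34, 0.42),
        (5, 0.26, 0.21, 0.30),
    ],
    "cl_cm_to_dep": [
        (1, 0.04, 0.00, 0.09),
        (2, 0.03, -0.01, 0.06),
        (3, 0.13, 0.09, 0.17),
        (4, 0.08, 0.03, 0.12),
        (5, 0.08, 0.03, 0.13),
    ],
    "cl_dep_to_cm": [
        (1, 0.03, 0.01, 0.05),
        (2, 0.04, 0.01, 0.06),
        (3, 0.05, 0.03, 0.07),
        (4, 0.03, 0.00, 0.05),
        (5, 0.06, 0.00, 0.12),
    ],
}

#: Published time-adjusted (yearly) estimates for the same rows,
#: (lag, yearly, ci_low, ci_high), for regression checks of the reporting
#: arithmetic (yearly = beta / lag duration, rounded half-away-from-zero).
REFERENCE_YEARLY: dict[str, list[tuple[int, float, float, float]]] = {
    "ar_cm": [
        (1, 0.42, 0.41, 0.43),
        (2, 0.37, 0.36, 0.38),
        (3, 0.52, 0.51, 0.53),
        (4, 0.34, 0.33, 0.35),
        (5, 0.08, 0.07, 0.09),
    ],
    "ar_dep": [
        (1, 0.05, 0.04, 0.07),
        (2, 0.32, 0.28, 0.35),
        (3, 0.08, 0.06, 0.09),
        (4, 0.31, 0.28, 0.35),
        (5, 0.04, 0.03, 0.05),
    ],
    "cl_cm_to_dep": [
        (1, 0.01, 0.00, 0.03),
        (2, 0.01, -0.01, 0.03),
        (3, 0.05, 0.03, 0.06),
        (4, 0.03, 0.01, 0.05),
        (5, 0.01, 0.01, 0.02),
    ],
    "cl_dep_to_cm": [
        (1, 0.03, 0.01, 0.05),
        (2, 0.04, 0.01, 0.06),
        (3, 0.03, 0.02, 0.04),
        (4, 0.02, 0.00, 0.04),
        (5, 0.01, 0.00, 0.02),
    ],
}

#: Cross-sectional residual correlations per wave, (wave, r, ci_low, ci_high).
REFERENCE_RESIDUAL_CORS: list[tuple[int, float, float, float]] = [
    (1, -0.08, -0.12, -0.04),
    (2, 0.02, -0.02, 0.06),
    (3, 0.10, 0.07, 0.13),
    (4, 0.11, 0.07, 0.14),
    (5, -0.02, -0.06, 0.01),
    (6, 0.10, 0.03, 0.17),
]

#: Correlation between the two random intercepts, with 95% CI.
REFERENCE_RI_COR = (0.11, 0.06, 0.16)

#: Global fit of the reference six-wave model.
REFERENCE_FIT = {
    "n": 7970,
    "chi2": 356.77,
    "df": 37,
    "rmsea": 0.033,
    "rmsea_ci": (0.030, 0.036),
    "cfi": 0.991,
    "tli": 0.983,
    "srmr": 0.027,
}

#: Per-wave missing-value proportions in the analysis sample (total column).
REFERENCE_MISSING_DEP = (0.15, 0.19, 0.24, 0.43, 0.45, 0.54)
REFERENCE_MISSING_CM = (0.50, 0.51, 0.24, 0.36, 0.40, 0.53)
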