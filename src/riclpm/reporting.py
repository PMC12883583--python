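"""Table-shaped reporting of lagged estimates with time-adjusted columns.

Because waves are unevenly spaced (and the two constructs are measured at
different ages), a lag-1 coefficient spans anywhere from ~1 to ~7 years.
Each path row therefore carries its lag duration in years and a
time-adjusted ("yearly") estimate beta / dt, which assumes linear additivity
of effects over time and exists purely for comparability across lags.

Lag-duration convention: auto-regressive paths span consecutive ages of the
same construct; cross-lagged paths run from the *predictor* construct's age
at wave t to the *outcome* construct's age at wave t+1.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .estimation import FitResult
from .panel import WaveSchedule

__all__ = [
    "round_half_away",
    "lag_durations",
    "yearly_estimate",
    "summarize_paths",
    "render_lag_table",
]


def round_half_away(x: float, ndigits: int = 2) -> float:
    """Round half away from zero (0.075 -> 0.08, -0.075 -> -0.08)."""
    if not np.isfinite(x):
        return float(x)
    factor = 10 ** ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


def lag_durations(schedule: WaveSchedule) -> pd.DataFrame:
    """Per-path lag durations in years, from the wave schedule.

    Columns: path, lag, age_from, age_to, dt.  AR paths use same-construct
    consecutive ages; CL paths pair the predictor's wave-t age with the
    outcome's wave-(t+1) age.
    """
    la, lb = schedule.labels
    ages = schedule.ages
    rows = []
    specs = [
        (f"ar_{la}", 0, 0), (f"ar_{lb}", 1, 1),
        (f"cl_{lb}_to_{la}", 1, 0), (f"cl_{la}_to_{lb}", 0, 1),
    ]
    for path, pred, out in specs:
        for t in range(1, schedule.n_waves):
            a_from = ages[pred][t - 1]
            a_to = ages[out][t]
            dt = a_to - a_from
            if dt <= 0:
                raise ValueError(
                    f"{path} lag {t}: non-positive lag duration "
                    f"({a_from} -> {a_to}); check the wave schedule"
                )
            rows.append({"path": path, "lag": t, "age_from": a_from,
                         "age_to": a_to, "dt": dt})
    return pd.DataFrame(rows)


def yearly_estimate(beta: float, dt: float) -> float:
    """Time-adjusted estimate beta / dt (full precision; round for display)."""
    if dt <= 0:
        raise ValueError(f"lag duration must be positive, got {dt}")
    return beta / dt


def summarize_paths(betas, ses=None) -> dict:
    """Mean, range and mean SE of the per-lag estimates of one path."""
    b = np.asarray(list(betas), float)
    if b.size == 0:
        raise ValueError("at least one estimate is required")
    out = {
        "mean": float(b.mean()),
        "min": float(b.min()),
        "max": float(b.max()),
        "mean_display": round_half_away(float(b.mean()), 2),
    }
    if ses is not None:
        s = np.asarray(list(ses), float)
        out["mean_se"] = float(s.mean())
        out["mean_se_display"] = round_half_away(float(s.mean()), 3)
    return out


def render_lag_table(fit: FitResult, schedule: WaveSchedule) -> tuple[pd.DataFrame, str]:
    """Emit the four path blocks, residual correlations and intercept
    correlation as a tidy table plus an aligned text rendering.

    Rows whose 95% CI excludes zero are flagged significant (the analogue of
    bold marking in a printed table).  Full precision is retained in the
    DataFrame; the ``*_display`` columns and text use half-away-from-zero
    rounding to 2 decimals.
    """
    durations = lag_durations(schedule)
    paths = fit.paths().merge(durations, on=["path", "lag"], how="left")
    paths["yearly"] = paths["beta"] / paths["dt"]
    paths["yearly_low"] = paths["ci_low"] / paths["dt"]
    paths["yearly_high"] = paths["ci_high"] / paths["dt"]
    paths["significant"] = (paths["ci_low"] > 0) | (paths["ci_high"] < 0)
    for col in ["beta", "ci_low", "ci_high", "yearly", "yearly_low", "yearly_high"]:
        paths[col + "_display"] = paths[col].map(lambda v: round_half_away(v, 2))

    resid = fit.residual_correlations().copy()
    resid["significant"] = (resid["ci_low"] > 0) | (resid["ci_high"] < 0)
    ri = fit.intercept_correlation()

    lines = ["Auto-regressive and cross-lag associations", "=" * 60]
    for path, block in paths.groupby("path", sort=False):
        lines.append(f"\n{path}")
        for _, r in block.iterrows():
            mark = "*" if r["significant"] else " "
            lines.append(
                f"  lag {int(r['lag'])}: {r['beta_display']:+.2f} "
                f"[{r['ci_low_display']:+.2f}; {r['ci_high_display']:+.2f}]{mark}  "
                f"{r['age_from']:.1f} -> {r['age_to']:.1f} y (dt = {r['dt']:.1f})  "
                f"yearly {r['yearly_display']:+.2f} "
                f"[{r['yearly_low_display']:+.2f}; {r['yearly_high_display']:+.2f}]"
            )
    lines.append("\nCross-sectional residual correlations")
    for _, r in resid.iterrows():
        mark = "*" if r["significant"] else " "
        lines.append(f"  wave {int(r['wave'])}: {round_half_away(r['r'], 2):+.2f} "
                     f"[{round_half_away(r['ci_low'], 2):+.2f}; "
                     f"{round_half_away(r['ci_high'], 2):+.2f}]{mark}")
    lines.append("\nRandom-intercept correlation")
    lines.append(f"  r = {round_half_away(ri['r'], 2):+.2f} "
                 f"[{round_half_away(ri['ci_low'], 2):+.2f}; "
                 f"{round_half_away(ri['ci_high'], 2):+.2f}]")
    text = "\n".join(lines)

    resid_rows = resid.rename(columns={"wave": "lag"}).assign(path="resid_cor")
    resid_rows = resid_rows.rename(columns={"r": "beta"})
    ri_row = pd.DataFrame([{"path": "ri_cor", "lag": 0, "beta": ri["r"], "se": ri["se"],
                            "ci_low": ri["ci_low"], "ci_high": ri["ci_high"],
                            "significant": (ri["ci_low"] > 0) or (ri["ci_high"] < 0)}])
    table = pd.concat([paths, resid_rows, ri_row], ignore_index=True)
    return table, text
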