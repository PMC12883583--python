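"""Data cleaning for the panel analysis.

The pipeline mirrors the conventional preparation of skewed repeated
measures for panel SEM, applied in this fixed order:

1. inclusion filter — keep participants with at least one non-missing value
   for *each* construct;
2. outlier masking — per construct and wave, set values more than
   ``k`` (default 5) interquartile ranges above Q3 or below Q1 to missing
   (strict inequality at the fences; quartiles by linear interpolation);
3. variance-stabilizing transform — square root or natural log per
   construct (missing propagates);
4. min-max normalization to [0, 1] per construct and wave, with the
   observed min/max recorded so the mapping is invertible.

Min/max are computed on the analysis sample after masking and transform.
Because min-max normalization is affine per variable, standardized model
estimates are unaffected by it; it only conditions the optimization.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .panel import RawPanel, WaveSchedule

__all__ = [
    "NormalizationRecord",
    "PreprocessSpec",
    "ModelPanel",
    "inclusion_filter",
    "mask_outliers",
    "transform",
    "minmax_normalize",
    "preprocess_panel",
]

TransformKind = Literal["sqrt", "ln", "identity"]


class TransformDomainError(ValueError):
    """A value lies outside the domain of the requested transform."""


@dataclass(frozen=True)
class NormalizationRecord:
    """Per-variable record sufficient to invert the normalization."""

    construct: str
    wave: int
    transform: TransformKind
    vmin: float
    vmax: float

    def invert(self, x_norm: np.ndarray) -> np.ndarray:
        """Map normalized values back to the raw scale."""
        x = np.asarray(x_norm, float) * (self.vmax - self.vmin) + self.vmin
        if self.transform == "sqrt":
            return x ** 2
        if self.transform == "ln":
            return np.exp(x)
        return x


@dataclass(frozen=True)
class PreprocessSpec:
    """Per-construct transform kinds and the IQR fence multiplier."""

    transforms: tuple[TransformKind, TransformKind] = ("sqrt", "ln")
    iqr_k: float = 5.0
    quartile_method: str = "linear"  # numpy interpolation rule; fences depend on it


@dataclass
class ModelPanel:
    """Preprocessed panel: values in [0, 1] (or missing) plus provenance.

    ``values`` is (n, 2T) in interleaved model order.  ``records`` holds one
    :class:`NormalizationRecord` per construct x wave; ``log`` counts rows
    dropped and cells masked.
    """

    ids: np.ndarray
    values: np.ndarray
    schedule: WaveSchedule
    records: list[NormalizationRecord] = field(default_factory=list)
    log: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def to_matrix(self) -> np.ndarray:
        return np.asarray(self.values, float)


def inclusion_filter(panel: RawPanel) -> tuple[RawPanel, int]:
    """Retain participants with >= 1 non-missing value for each construct.

    Returns the filtered panel and the number of participants dropped.
    """
    if panel.n == 0:
        raise ValueError("panel is empty")
    keep = np.ones(panel.n, dtype=bool)
    for c in range(2):
        keep &= ~np.all(np.isnan(panel.construct_values(c)), axis=1)
    dropped = int((~keep).sum())
    out = RawPanel(ids=panel.ids[keep], values=panel.values[keep], schedule=panel.schedule)
    return out, dropped


def mask_outliers(series: np.ndarray, k: float = 5.0, method: str = "linear") -> tuple[np.ndarray, int]:
    """Set values strictly beyond Q1 - k*IQR or Q3 + k*IQR to missing.

    Quartiles are computed on the non-missing values (linear interpolation by
    default).  Returns the masked copy and the number of cells masked.
    """
    x = np.asarray(series, float).copy()
    obs = ~np.isnan(x)
    if obs.sum() == 0:
        warnings.warn("all-missing series passed to mask_outliers; returned unchanged")
        return x, 0
    if obs.sum() < 4:
        warnings.warn("fewer than 4 observed values; quartiles unreliable, nothing masked")
        return x, 0
    q1, q3 = np.percentile(x[obs], [25, 75], method=method)
    iqr = q3 - q1
    lo, hi = q1 - k * iqr, q3 + k * iqr
    bad = obs & ((x < lo) | (x > hi))
    x[bad] = np.nan
    return x, int(bad.sum())


def transform(series: np.ndarray, kind: TransformKind, label: str = "series") -> np.ndarray:
    """Elementwise sqrt / ln / identity; missing propagates."""
    x = np.asarray(series, float)
    obs = ~np.isnan(x)
    if kind == "identity":
        return x.copy()
    if kind == "sqrt":
        if np.any(x[obs] < 0):
            bad = float(x[obs][x[obs] < 0][0])
            raise TransformDomainError(f"{label}: sqrt transform requires values >= 0, found {bad}")
        out = np.full_like(x, np.nan)
        out[obs] = np.sqrt(x[obs])
        return out
    if kind == "ln":
        if np.any(x[obs] <= 0):
            bad = float(x[obs][x[obs] <= 0][0])
            raise TransformDomainError(f"{label}: ln transform requires values > 0, found {bad}")
        out = np.full_like(x, np.nan)
        out[obs] = np.log(x[obs])
        return out
    raise ValueError(f"unknown transform kind {kind!r}")


def minmax_normalize(series: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Map the observed range onto [0, 1]: (x - min) / (max - min).

    Returns the normalized series and the observed (min, max).
    """
    x = np.asarray(series, float)
    obs = ~np.isnan(x)
    if obs.sum() < 2:
        raise ValueError("min-max normalization needs at least 2 non-missing values")
    vmin, vmax = float(np.min(x[obs])), float(np.max(x[obs]))
    if vmax <= vmin:
        raise ValueError(f"constant series (min = max = {vmin}): zero normalization denominator")
    out = np.full_like(x, np.nan)
    out[obs] = (x[obs] - vmin) / (vmax - vmin)
    return out, vmin, vmax


def preprocess_panel(panel: RawPanel, spec: PreprocessSpec | None = None) -> ModelPanel:
    """Run the full cleaning pipeline: filter, mask, transform, normalize."""
    if spec is None:
        spec = PreprocessSpec()
    filtered, dropped = inclusion_filter(panel)
    T = filtered.schedule.n_waves
    values = filtered.values.copy()
    masked_cells = 0
    records: list[NormalizationRecord] = []
    for c in range(2):
        label = filtered.schedule.labels[c]
        kind = spec.transforms[c]
        for t in range(1, T + 1):
            j = filtered.schedule.var_index(c, t)
            col, n_masked = mask_outliers(values[:, j], k=spec.iqr_k, method=spec.quartile_method)
            masked_cells += n_masked
            col = transform(col, kind, label=f"{label} wave {t}")
            col, vmin, vmax = minmax_normalize(col)
            values[:, j] = col
            records.append(NormalizationRecord(construct=label, wave=t, transform=kind,
                                               vmin=vmin, vmax=vmax))
    log = {
        "n_input": panel.n,
        "n_retained": filtered.n,
        "n_dropped": dropped,
        "cells_masked": masked_cells,
        "iqr_k": spec.iqr_k,
        "quartile_method": spec.quartile_method,
        "transforms": dict(zip(filtered.schedule.labels, spec.transforms)),
    }
    return ModelPanel(ids=filtered.ids, values=values, schedule=filtered.schedule,
                      records=records, log=log)
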