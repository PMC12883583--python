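"""Panel containers and CSV I/O for two-construct longitudinal data.

A panel holds one row per participant and, per construct, one score per
measurement wave.  Waves are indexed 1..T and each construct carries its own
schedule of median ages, so lag durations are uneven and differ between
constructs.  In-memory matrices use the interleaved model order
(a_1, b_1, a_2, b_2, ...); CSV files group columns by construct
(id, a_1..a_T, b_1..b_T) with a plain-text sidecar recording the schedule.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "WaveSchedule",
    "RawPanel",
    "read_panel",
    "write_panel",
    "long_to_wide",
    "read_long_panel",
]


@dataclass(frozen=True)
class WaveSchedule:
    """Median ages (years) at each measurement wave, per construct.

    Parameters
    ----------
    labels : pair of short construct labels, e.g. ``("dep", "cm")``.
        Used as CSV column prefixes.
    ages : pair of age sequences, one per construct, each of length T and
        strictly increasing.
    """

    labels: tuple[str, str]
    ages: tuple[tuple[float, ...], tuple[float, ...]]

    def __post_init__(self):
        if len(self.labels) != 2:
            raise ValueError("exactly two constructs are supported")
        if len(self.ages) != 2:
            raise ValueError("one age sequence per construct is required")
        object.__setattr__(self, "labels", tuple(self.labels))
        object.__setattr__(self, "ages", tuple(tuple(float(a) for a in seq) for seq in self.ages))
        t0, t1 = (len(seq) for seq in self.ages)
        if t0 != t1:
            raise ValueError(f"both constructs need the same wave count, got {t0} and {t1}")
        if t0 < 1:
            raise ValueError("at least one wave is required")
        for lab, seq in zip(self.labels, self.ages):
            arr = np.asarray(seq)
            if np.any(arr <= 0):
                raise ValueError(f"{lab}: ages must be positive")
            if np.any(np.diff(arr) <= 0):
                raise ValueError(f"{lab}: ages must be strictly increasing")

    @property
    def n_waves(self) -> int:
        return len(self.ages[0])

    def var_names(self) -> list[str]:
        """Variable names in interleaved model order (a_1, b_1, a_2, ...)."""
        return [f"{self.labels[c]}_{t}" for t in range(1, self.n_waves + 1) for c in range(2)]

    def csv_columns(self) -> list[str]:
        """Column names in construct-grouped CSV order."""
        return [f"{lab}_{t}" for lab in self.labels for t in range(1, self.n_waves + 1)]

    def var_index(self, construct: int, wave: int) -> int:
        """Index into the interleaved order for construct 0/1 at wave 1..T."""
        if not 0 <= construct <= 1:
            raise ValueError("construct must be 0 or 1")
        if not 1 <= wave <= self.n_waves:
            raise ValueError(f"wave must be in 1..{self.n_waves}")
        return 2 * (wave - 1) + construct

    def to_sidecar(self) -> str:
        lines = [
            f"{lab}: {', '.join(format(a, 'g') for a in seq)}"
            for lab, seq in zip(self.labels, self.ages)
        ]
        return "\n".join(lines) + "\n"

    @classmethod
    def from_sidecar(cls, text: str) -> "WaveSchedule":
        labels, ages = [], []
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            lab, _, rest = line.partition(":")
            labels.append(lab.strip())
            ages.append(tuple(float(tok) for tok in rest.replace(",", " ").split()))
        if len(labels) != 2:
            raise ValueError("schedule sidecar must define exactly two constructs")
        return cls(labels=(labels[0], labels[1]), ages=(ages[0], ages[1]))


@dataclass
class RawPanel:
    """Participant-by-wave raw scores for two constructs (missing = NaN).

    ``values`` is (n, 2T) in interleaved model order; use
    :meth:`to_frame` / :func:`write_panel` for the construct-grouped CSV view.
    """

    ids: np.ndarray
    values: np.ndarray
    schedule: WaveSchedule

    def __post_init__(self):
        self.ids = np.asarray(self.ids)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != 2 * self.schedule.n_waves:
            raise ValueError(
                f"values must be (n, {2 * self.schedule.n_waves}), got {self.values.shape}"
            )
        if len(self.ids) != self.values.shape[0]:
            raise ValueError("ids and values disagree on participant count")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def construct_values(self, construct: int) -> np.ndarray:
        """(n, T) slice of one construct in wave order."""
        return self.values[:, construct::2]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.schedule.var_names())
        df.insert(0, "id", self.ids)
        return df[["id"] + self.schedule.csv_columns()]

    @classmethod
    def from_frame(cls, df: pd.DataFrame, schedule: WaveSchedule) -> "RawPanel":
        cols = schedule.csv_columns()
        missing_cols = [c for c in cols if c not in df.columns]
        if missing_cols:
            raise ValueError(f"panel is missing columns: {missing_cols}")
        grouped = df[cols].to_numpy(dtype=float)
        # regroup construct-major columns into interleaved order
        T = schedule.n_waves
        values = np.empty_like(grouped)
        values[:, 0::2] = grouped[:, :T]
        values[:, 1::2] = grouped[:, T:]
        ids = df["id"].to_numpy() if "id" in df.columns else np.arange(len(df))
        return cls(ids=ids, values=values, schedule=schedule)


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".schedule.txt") if path.suffix == "" else path.with_name(path.stem + ".schedule.txt")


def write_panel(panel: RawPanel, path: str | Path) -> Path:
    """Write a wide CSV plus schedule sidecar; missing cells become empty fields."""
    path = Path(path)
    try:
        path.parent.mkdir(parents=True, exist_ok=True)
        panel.to_frame().to_csv(path, index=False, float_format="%.17g")
        _sidecar_path(path).write_text(panel.schedule.to_sidecar())
    except OSError as exc:
        raise OSError(f"failed writing panel to {path}: {exc}") from exc
    return path


def read_panel(path: str | Path, schedule: WaveSchedule | None = None) -> RawPanel:
    """Read a wide CSV written by :func:`write_panel`.

    If ``schedule`` is None the sidecar next to ``path`` is consulted.
    """
    path = Path(path)
    if schedule is None:
        sidecar = _sidecar_path(path)
        if not sidecar.exists():
            raise FileNotFoundError(
                f"no schedule given and sidecar {sidecar} not found next to {path}"
            )
        schedule = WaveSchedule.from_sidecar(sidecar.read_text())
    df = pd.read_csv(path, float_precision="round_trip")
    return RawPanel.from_frame(df, schedule)


def long_to_wide(df: pd.DataFrame, schedule: WaveSchedule) -> RawPanel:
    """Convert long records (id, construct, wave, value) to a wide panel."""
    required = {"id", "construct", "wave", "value"}
    if not required.issubset(df.columns):
        raise ValueError(f"long format needs columns {sorted(required)}")
    wide = df.pivot_table(index="id", columns=["construct", "wave"], values="value", aggfunc="first")
    out = pd.DataFrame({"id": wide.index.to_numpy()})
    for lab in schedule.labels:
        for t in range(1, schedule.n_waves + 1):
            col = f"{lab}_{t}"
            out[col] = wide[(lab, t)].to_numpy() if (lab, t) in wide.columns else np.nan
    return RawPanel.from_frame(out, schedule)


def read_long_panel(path: str | Path, schedule: WaveSchedule) -> RawPanel:
    return long_to_wide(pd.read_csv(path), schedule)
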