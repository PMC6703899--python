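"""Core containers: trace matrices, hypnograms, bouts.

Conventions used throughout the package:

* frames are sampled at ``frame_rate_hz`` (default 10 frames/s) and indexed
  from 0; epochs are fixed-length scoring windows (default 4 s) indexed from 0;
* all intervals are half-open ``[start, end)``;
* behavioral states form a closed vocabulary: AW (active wake), QW (quiet
  wake), NREMS, REMS, CATAPLEXY.  Derived bout labels (SC, EC, HAW, AWO)
  refine CATAPLEXY and post-odor AW bouts and never appear in hypnograms.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

#: Closed hypnogram state vocabulary.
STATES = ("AW", "QW", "NREMS", "REMS", "CATAPLEXY")
#: Wake states (either qualifies as "wakefulness" for the cataplexy prior-wake rule).
WAKE_STATES = frozenset({"AW", "QW"})
#: Derived labels attached to bouts by the sleepstate module.
DERIVED_LABELS = ("SC", "EC", "HAW", "AWO")

TRACE_KINDS = ("raw", "dff", "zscore")


@dataclass
class TraceMatrix:
    """Cells x frames fluorescence matrix aligned to a hypnogram.

    ``kind`` tracks the normalization stage: ``raw`` (positive fluorescence),
    ``dff`` (ΔF/F) or ``zscore`` (per-cell standardized ΔF/F).
    """

    values: np.ndarray
    frame_rate_hz: float
    kind: str
    cell_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D cells x frames matrix")
        if self.kind not in TRACE_KINDS:
            raise ValueError(f"unknown trace kind {self.kind!r}")
        if len(self.cell_ids) != self.values.shape[0]:
            raise ValueError("cell_ids length must match number of rows")
        if not np.isfinite(self.values).all():
            raise ValueError("trace matrix contains non-finite values")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.frame_rate_hz

    def cell_index(self, cell_id: str) -> int:
        return self.cell_ids.index(cell_id)

    def to_csv(self, path: str | Path) -> None:
        """Write the trace CSV dialect: ``frame`` column then one column per cell."""
        df = pd.DataFrame(self.values.T, columns=self.cell_ids)
        df.insert(0, "frame", np.arange(self.n_frames))
        df.to_csv(path, index=False, float_format="%.10g")

    @classmethod
    def from_csv(
        cls, path: str | Path, frame_rate_hz: float = 10.0, kind: str = "raw"
    ) -> "TraceMatrix":
        df = pd.read_csv(path)
        if df.columns[0] != "frame":
            raise ValueError(f"{path}: first column must be 'frame'")
        cells = [str(c) for c in df.columns[1:]]
        return cls(df.iloc[:, 1:].to_numpy().T, frame_rate_hz, kind, cells)


@dataclass
class Hypnogram:
    """Per-epoch behavioral-state labels at fixed epoch resolution."""

    labels: np.ndarray
    epoch_s: float = 4.0

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype="U9")
        bad = set(self.labels.tolist()) - set(STATES)
        if bad:
            raise ValueError(f"unknown state labels {sorted(bad)}")

    @property
    def n_epochs(self) -> int:
        return self.labels.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_epochs * self.epoch_s

    def frames_per_epoch(self, frame_rate_hz: float) -> int:
        fpe = frame_rate_hz * self.epoch_s
        if abs(fpe - round(fpe)) > 1e-9:
            raise ValueError("frame_rate_hz * epoch_s must be an integer")
        return int(round(fpe))

    def frame_labels(self, frame_rate_hz: float) -> np.ndarray:
        """Expand epoch labels to a per-frame label vector."""
        return np.repeat(self.labels, self.frames_per_epoch(frame_rate_hz))

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"epoch_index": np.arange(self.n_epochs), "state": self.labels}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, epoch_s: float = 4.0) -> "Hypnogram":
        df = pd.read_csv(path)
        return cls(df["state"].to_numpy(), epoch_s)


@dataclass
class Bout:
    """A maximal run of one state, as half-open epoch and frame intervals.

    ``derived_label`` refines the state after rule application: SC/EC on
    CATAPLEXY bouts, HAW/AWO on post-odor AW bouts.  ``chain_start_epoch``
    marks cataplexy bouts validated through sequential-cataplexy chaining and
    points at the first bout of the chain.  ``note`` carries data-quality
    flags (e.g. ambiguous wake context).
    """

    state: str
    start_epoch: int
    end_epoch: int
    epoch_s: float = 4.0
    frames_per_epoch: int = 40
    derived_label: str | None = None
    chain_start_epoch: int | None = None
    note: str | None = None

    def __post_init__(self) -> None:
        if self.end_epoch <= self.start_epoch:
            raise ValueError("bout must span at least one epoch")

    @property
    def start_frame(self) -> int:
        return self.start_epoch * self.frames_per_epoch

    @property
    def end_frame(self) -> int:
        return self.end_epoch * self.frames_per_epoch

    @property
    def n_epochs(self) -> int:
        return self.end_epoch - self.start_epoch

    @property
    def start_s(self) -> float:
        return self.start_epoch * self.epoch_s

    @property
    def end_s(self) -> float:
        return self.end_epoch * self.epoch_s

    @property
    def duration_s(self) -> float:
        return self.n_epochs * self.epoch_s

    @property
    def effective_label(self) -> str:
        """Derived label if set, else the raw state."""
        return self.derived_label or self.state

    def frame_slice(self) -> slice:
        return slice(self.start_frame, self.end_frame)

    def relabeled(self, **kwargs) -> "Bout":
        return replace(self, **kwargs)


def bouts_to_frame(bouts: Sequence[Bout]) -> pd.DataFrame:
    """Tabulate labeled bouts (the labeled-bout CSV dialect)."""
    return pd.DataFrame(
        {
            "state": [b.state for b in bouts],
            "derived_label": [b.derived_label or "" for b in bouts],
            "start_epoch": [b.start_epoch for b in bouts],
            "end_epoch": [b.end_epoch for b in bouts],
            "start_s": [b.start_s for b in bouts],
            "duration_s": [b.duration_s for b in bouts],
            "note": [b.note or "" for b in bouts],
        }
    )


def frame_labels_from_bouts(
    bouts: Sequence[Bout], effective: bool = True
) -> np.ndarray:
    """Per-frame label vector from a bout partition (derived labels if present)."""
    n_frames = max(b.end_frame for b in bouts)
    out = np.empty(n_frames, dtype="U9")
    for b in bouts:
        out[b.start_frame : b.end_frame] = b.effective_label if effective else b.state
    return out
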