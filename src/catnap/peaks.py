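"""Prominent calcium transient peaks and their amplitude/frequency statistics.

A prominent peak is a local maximum of the Z-scored trace whose height is at
least 80% of the cell's maximum Z over the whole recording, with a 2 s
minimum interval between adjacent peaks.  Interval conflicts are resolved by
amplitude-priority greedy selection (keep the larger peak; ties go to the
earlier frame), preserving the "prominent" semantics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .core import Bout, TraceMatrix
from .stats import ks_two_sample


@dataclass
class PeakTrain:
    cell_id: str
    peak_frames: np.ndarray
    peak_amplitudes: np.ndarray
    threshold_used: float
    degenerate: bool = False  # max_z <= 0: no peaks detectable

    @property
    def n_peaks(self) -> int:
        return int(self.peak_frames.shape[0])


def _candidate_maxima(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Local maxima strictly above both neighbors; plateaus resolve to their
    leftmost frame; boundary frames are eligible."""
    padded = np.concatenate([[-np.inf], x, [-np.inf]])
    idx, props = find_peaks(padded, plateau_size=1)
    left = props["left_edges"] - 1
    return left, x[left]


def detect_peaks(
    zmatrix: TraceMatrix,
    min_interval_s: float = 2.0,
    threshold_frac: float = 0.8,
) -> list[PeakTrain]:
    """Detect prominent peaks per cell.

    Candidates at or above ``threshold_frac`` x max_z are accepted in
    decreasing amplitude order (ties by earlier frame); a candidate within
    ``min_interval_s`` of an already-accepted peak is rejected.
    """
    if zmatrix.kind != "zscore":
        raise ValueError("detect_peaks expects a zscore matrix")
    min_frames = int(round(min_interval_s * zmatrix.frame_rate_hz))
    trains = []
    for i, cid in enumerate(zmatrix.cell_ids):
        z = zmatrix.values[i]
        max_z = float(z.max())
        if max_z <= 0:
            warnings.warn(f"cell {cid}: max Z <= 0, no peak threshold defined")
            trains.append(
                PeakTrain(cid, np.empty(0, int), np.empty(0), 0.0, degenerate=True)
            )
            continue
        thr = threshold_frac * max_z
        frames, heights = _candidate_maxima(z)
        keep = heights >= thr
        frames, heights = frames[keep], heights[keep]
        order = np.lexsort((frames, -heights))
        accepted: list[int] = []
        for j in order:
            f = int(frames[j])
            if all(abs(f - g) >= min_frames for g in accepted):
                accepted.append(f)
        accepted.sort()
        acc = np.asarray(accepted, dtype=int)
        trains.append(PeakTrain(cid, acc, z[acc], thr))
    return trains


def peak_stats_by_state(
    trains: Sequence[PeakTrain], labeled_bouts: Sequence[Bout]
) -> pd.DataFrame:
    """Per-cell per-state peak frequency (peaks/min) and mean amplitude.

    A peak belongs to the bout containing its frame (effective bout label).
    States with zero scored time are absent from the output, not zero.
    """
    state_minutes: dict[str, float] = {}
    for b in labeled_bouts:
        lab = b.effective_label
        state_minutes[lab] = state_minutes.get(lab, 0.0) + b.duration_s / 60.0
    records = []
    for train in trains:
        counts = {lab: 0 for lab in state_minutes}
        amps: dict[str, list[float]] = {lab: [] for lab in state_minutes}
        for f, a in zip(train.peak_frames, train.peak_amplitudes):
            for b in labeled_bouts:
                if b.start_frame <= f < b.end_frame:
                    counts[b.effective_label] += 1
                    amps[b.effective_label].append(float(a))
                    break
        for lab, minutes in state_minutes.items():
            records.append(
                {
                    "cell_id": train.cell_id,
                    "state": lab,
                    "n_peaks": counts[lab],
                    "minutes": minutes,
                    "frequency_per_min": counts[lab] / minutes,
                    "mean_amplitude": (
                        float(np.mean(amps[lab])) if amps[lab] else np.nan
                    ),
                }
            )
    return pd.DataFrame(records)


def ks_compare(freq_a: Sequence[float], freq_b: Sequence[float]) -> dict:
    """Two-sample KS comparison of per-cell peak-frequency distributions."""
    a = np.asarray(freq_a, dtype=float)
    b = np.asarray(freq_b, dtype=float)
    if a.size < 5 or b.size < 5:
        warnings.warn("fewer than 5 observations: asymptotic p is unreliable")
    d, p = ks_two_sample(a, b)
    return {"D": d, "p": p, "n_a": int(a.size), "n_b": int(b.size)}


def peaks_to_frame(trains: Sequence[PeakTrain], frame_rate_hz: float) -> pd.DataFrame:
    """Peaks CSV dialect: cell_id, frame, time_s, amplitude."""
    records = []
    for t in trains:
        for f, a in zip(t.peak_frames, t.peak_amplitudes):
            records.append(
                {"cell_id": t.cell_id, "frame": int(f),
                 "time_s": f / frame_rate_hz, "amplitude": float(a)}
            )
    return pd.DataFrame(records, columns=["cell_id", "frame", "time_s", "amplitude"])
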