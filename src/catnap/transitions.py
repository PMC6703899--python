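"""Normalized-time activity profiles across wake→cataplexy transitions.

Each cataplexy bout's duration is normalized to 0–100% and every member
cell's Z trace is resampled to 101 points by linear interpolation; profiles
average across cells first (equal cell weight), then across bouts (equal
bout weight regardless of duration).  A fixed-length pre-onset window is
kept at native resolution, right-aligned to bout onset.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .core import Bout, TraceMatrix

N_PROFILE_POINTS = 101  # 0..100% inclusive


@dataclass
class TransitionProfile:
    group_label: str
    bout_type: str
    pre_window: np.ndarray       # native frames, right-aligned to onset
    pre_window_sem: np.ndarray
    bout_profile: np.ndarray     # length 101
    bout_profile_sem: np.ndarray
    n_cells: int
    n_bouts: int


def _resample_bout(z: np.ndarray) -> np.ndarray:
    n = z.shape[0]
    if n < 2:
        raise ValueError("bout shorter than 2 frames")
    return np.interp(
        np.linspace(0.0, n - 1.0, N_PROFILE_POINTS), np.arange(n), z
    )


def transition_profile(
    zmatrix: TraceMatrix,
    bouts: Sequence[Bout],
    cell_ids: Sequence[str],
    bout_type: str = "EC",
    group_label: str = "",
    pre_window_s: float = 60.0,
) -> TransitionProfile:
    """Average Z of a cell group across all bouts of ``bout_type``.

    ``cell_ids`` selects the group (e.g. all HAW-ON cells).  Bouts shorter
    than 2 frames are skipped.  The pre-onset window is truncated at the
    recording start; truncated frames are averaged over the bouts that have
    them.
    """
    if not cell_ids:
        raise ValueError("empty cell group")
    rows = [zmatrix.cell_index(c) for c in cell_ids]
    selected = [b for b in bouts if b.effective_label == bout_type]
    if not selected:
        raise ValueError(f"no bouts of type {bout_type!r}")
    w = int(round(pre_window_s * zmatrix.frame_rate_hz))

    bout_curves, pre_curves = [], []
    for b in selected:
        seg = zmatrix.values[np.ix_(rows, range(b.start_frame, b.end_frame))]
        if seg.shape[1] < 2:
            continue
        cell_mean = seg.mean(axis=0)  # cells weighted equally
        bout_curves.append(_resample_bout(cell_mean))
        pre = np.full(w, np.nan)
        lo = max(0, b.start_frame - w)
        chunk = zmatrix.values[np.ix_(rows, range(lo, b.start_frame))].mean(axis=0)
        pre[w - chunk.shape[0]:] = chunk
        pre_curves.append(pre)
    if not bout_curves:
        raise ValueError("all bouts shorter than 2 frames")

    bout_arr = np.vstack(bout_curves)
    pre_arr = np.vstack(pre_curves)
    n_b = bout_arr.shape[0]

    def nansem(a: np.ndarray) -> np.ndarray:
        n = (~np.isnan(a)).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(
                n >= 2, np.nanstd(a, axis=0, ddof=1) / np.sqrt(n), np.nan
            )

    return TransitionProfile(
        group_label=group_label,
        bout_type=bout_type,
        pre_window=np.nanmean(pre_arr, axis=0),
        pre_window_sem=nansem(pre_arr),
        bout_profile=bout_arr.mean(axis=0),  # bouts weighted equally
        bout_profile_sem=nansem(bout_arr),
        n_cells=len(rows),
        n_bouts=n_b,
    )


def profile_to_frame(profile: TransitionProfile) -> pd.DataFrame:
    """Profile CSV dialect: group, normalized_pct, mean_z, sem_z."""
    return pd.DataFrame(
        {
            "group": profile.group_label,
            "bout_type": profile.bout_type,
            "normalized_pct": np.arange(N_PROFILE_POINTS),
            "mean_z": profile.bout_profile,
            "sem_z": profile.bout_profile_sem,
        }
    )


def pre_window_to_frame(
    profile: TransitionProfile, frame_rate_hz: float
) -> pd.DataFrame:
    w = profile.pre_window.shape[0]
    t = (np.arange(w) - w) / frame_rate_hz
    return pd.DataFrame(
        {
            "group": profile.group_label,
            "bout_type": profile.bout_type,
            "time_to_onset_s": t,
            "mean_z": profile.pre_window,
            "sem_z": profile.pre_window_sem,
        }
    )
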