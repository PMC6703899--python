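"""Bout-conditioned pairwise synchrony: Pearson R, Fisher Z_R, spatial maps.

For each sufficiently long bout, the Pearson correlation R is computed for
every unordered cell pair over the bout's frames and variance-stabilized with
the Fisher transform Z_R = 0.5[ln(1+R) − ln(1−R)].  The per-cell summary is
the mean Z_R over partners with positive R only; the bout summary averages
that over cells.  Strong positive pairs (R >= 0.6) become edges of the
spatial connectivity map.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import Bout, TraceMatrix
from .stats import TwoWayAnovaResult, sem, two_way_anova_balanced

#: |R| clip bound: keeps Z_R finite for perfectly (anti)correlated pairs.
R_CLIP = 1.0 - 1e-6
#: Minimum bout length in frames (10 s at 10 frames/s) to bound estimator noise.
MIN_BOUT_FRAMES = 100


def fisher_z(r):
    """Fisher Z transform, odd and strictly increasing; |r| clipped to
    1 - 1e-6 before the transform so the result stays finite."""
    r = np.clip(np.asarray(r, dtype=float), -R_CLIP, R_CLIP)
    out = 0.5 * (np.log1p(r) - np.log1p(-r))
    return float(out) if out.ndim == 0 else out


def fisher_z_inv(z):
    return np.tanh(z)


@dataclass
class SynchronyResult:
    bout: Bout
    cell_ids: list[str]
    R: np.ndarray            # NaN diagonal and zero-variance pairs
    Z_R: np.ndarray
    per_cell_mean_pos_zr: np.ndarray  # NaN when a cell has no positive partner
    state_mean_zr: float
    state_sem_zr: float


def boutwise_correlation(
    zmatrix: TraceMatrix, bout: Bout, min_frames: int = MIN_BOUT_FRAMES
) -> SynchronyResult | None:
    """Pairwise correlation structure of one bout; None for short bouts."""
    n_frames = bout.end_frame - bout.start_frame
    if n_frames < min_frames:
        warnings.warn(
            f"bout at epoch {bout.start_epoch}: {n_frames} frames < {min_frames}, skipped"
        )
        return None
    if zmatrix.n_cells < 2:
        raise ValueError("need at least 2 cells")
    sub = zmatrix.values[:, bout.frame_slice()]
    sd = sub.std(axis=1)
    valid = sd > 0
    n = zmatrix.n_cells
    R = np.full((n, n), np.nan)
    if valid.sum() >= 2:
        R_valid = np.corrcoef(sub[valid])
        idx = np.flatnonzero(valid)
        R[np.ix_(idx, idx)] = R_valid
    np.fill_diagonal(R, np.nan)
    Z = np.where(np.isnan(R), np.nan, fisher_z(np.nan_to_num(R)))
    per_cell = np.full(n, np.nan)
    for i in range(n):
        pos = (R[i] > 0) & ~np.isnan(R[i])
        if pos.any():
            per_cell[i] = Z[i][pos].mean()
    finite = per_cell[~np.isnan(per_cell)]
    return SynchronyResult(
        bout=bout,
        cell_ids=list(zmatrix.cell_ids),
        R=R,
        Z_R=Z,
        per_cell_mean_pos_zr=per_cell,
        state_mean_zr=float(finite.mean()) if finite.size else float("nan"),
        state_sem_zr=sem(finite),
    )


def session_synchrony(
    zmatrix: TraceMatrix, bouts: Sequence[Bout], min_frames: int = MIN_BOUT_FRAMES
) -> list[SynchronyResult]:
    """Correlation structure of every sufficiently long bout."""
    out = []
    for b in bouts:
        res = boutwise_correlation(zmatrix, b, min_frames)
        if res is not None:
            out.append(res)
    return out


def state_summary(
    results_by_group: Mapping[str, Sequence[SynchronyResult]]
) -> tuple[pd.DataFrame, TwoWayAnovaResult | None]:
    """Per-group per-state mean ± SEM of bout Z_R, with a two-way
    (group x state) ANOVA when the design is balanced.

    Bouts are the replicates; states are the bouts' effective labels.  The
    ANOVA is computed from closed-form sums of squares and reported only for
    balanced layouts (equal bout counts in every group x state cell with
    n >= 2); otherwise the summary table is returned alone.
    """
    records = []
    cells: dict[tuple[str, str], list[float]] = {}
    for group, results in results_by_group.items():
        by_state: dict[str, list[float]] = {}
        for r in results:
            by_state.setdefault(r.bout.effective_label, []).append(r.state_mean_zr)
        for state, vals in sorted(by_state.items()):
            records.append(
                {"group": group, "state": state, "n_bouts": len(vals),
                 "mean_zr": float(np.mean(vals)), "sem_zr": sem(vals)}
            )
            cells[(group, state)] = vals
    table = pd.DataFrame(records)
    anova = None
    groups = sorted({g for g, _ in cells})
    states = sorted({s for _, s in cells})
    if len(groups) >= 2 and len(states) >= 2:
        counts = {
            (g, s): len(cells.get((g, s), [])) for g in groups for s in states
        }
        n = min(counts.values())
        if n >= 2 and len(set(counts.values())) == 1:
            arr = np.array(
                [[cells[(g, s)] for s in states] for g in groups], dtype=float
            )
            anova = two_way_anova_balanced(arr)
        else:
            warnings.warn("unbalanced group x state layout: ANOVA omitted")
    return table, anova


@dataclass
class ConnectivityEdge:
    cell_a: str
    cell_b: str
    r: float
    centroid_a: tuple
    centroid_b: tuple


def connectivity_map(
    result: SynchronyResult,
    centroids: Mapping[str, tuple],
    r_min: float = 0.6,
) -> list[ConnectivityEdge]:
    """Edges for every unordered pair with R >= r_min (default the 0.6–1.0
    strong-positive band).  Cells without a centroid are dropped from the map
    (with a warning) but remain in the correlation statistics."""
    edges = []
    ids = result.cell_ids
    missing = [c for c in ids if c not in centroids]
    if missing:
        warnings.warn(f"missing centroids for {len(missing)} cells; dropped from map")
    for i in range(len(ids)):
        if ids[i] not in centroids:
            continue
        for j in range(i + 1, len(ids)):
            if ids[j] not in centroids:
                continue
            r = result.R[i, j]
            if not np.isnan(r) and r >= r_min:
                edges.append(
                    ConnectivityEdge(
                        ids[i], ids[j], float(r),
                        tuple(centroids[ids[i]]), tuple(centroids[ids[j]]),
                    )
                )
    return edges


def edges_to_frame(edges: Sequence[ConnectivityEdge]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"cell_a": e.cell_a, "cell_b": e.cell_b, "R": e.r,
             "x_a": e.centroid_a[0], "y_a": e.centroid_a[1],
             "x_b": e.centroid_b[0], "y_b": e.centroid_b[1]}
            for e in edges
        ],
        columns=["cell_a", "cell_b", "R", "x_a", "y_a", "x_b", "y_b"],
    )


def plot_connectivity_map(
    edges: Sequence[ConnectivityEdge], centroids: Mapping[str, tuple], ax=None
):
    """Spatial map with edges colored by R over the 0.6–1.0 band."""
    import matplotlib.pyplot as plt
    from matplotlib import cm, colors

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    norm = colors.Normalize(vmin=0.6, vmax=1.0)
    cmap = cm.get_cmap("coolwarm") if hasattr(cm, "get_cmap") else plt.get_cmap("coolwarm")
    for e in edges:
        ax.plot(
            [e.centroid_a[0], e.centroid_b[0]],
            [e.centroid_a[1], e.centroid_b[1]],
            color=cmap(norm(e.r)), lw=0.8, alpha=0.8,
        )
    xs = [xy[0] for xy in centroids.values()]
    ys = [xy[1] for xy in centroids.values()]
    ax.scatter(xs, ys, s=12, c="k", zorder=3)
    ax.set_aspect("equal")
    ax.set_xlabel("x (px)")
    ax.set_ylabel("y (px)")
    return ax
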