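"""ON-cell classification against the QW baseline, with composition summaries.

A cell is "ON" in a state when its mean Z-score over all frames of that
state's bouts is at least the cell's mean QW Z-score plus one (boundary
inclusive).  Cells not ON in any undisturbed state are "unscored"; EC-ON and
HAW-ON are additional non-exclusive flags crossed against the pre-odor
categories in the composition table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .core import Bout, TraceMatrix
from .stats import one_way_anova, percent

#: Mutually exclusive reporting categories, in display order.
CATEGORY_ORDER = (
    "REMS_ON", "REMS_AW_ON", "AW_ON", "NREMS_ON", "SC_ON", "unscored",
)
#: States eligible for pre-odor ON membership (QW is the baseline itself).
_PRE_ODOR_STATES = ("AW", "QW", "NREMS", "REMS", "SC")


@dataclass
class CellProfile:
    cell_id: str
    state_mean_z: dict
    z_qw: float
    on_states: set
    category: str
    max_z: float
    ec_on: bool = False
    haw_on: bool = False
    awo_on: bool = False


def _frame_label_masks(bouts: Sequence[Bout], n_frames: int) -> dict:
    """Frame masks keyed by effective bout label (derived label if set)."""
    masks: dict[str, np.ndarray] = {}
    for b in bouts:
        lab = b.effective_label
        if lab not in masks:
            masks[lab] = np.zeros(n_frames, dtype=bool)
        masks[lab][b.start_frame : min(b.end_frame, n_frames)] = True
    return {k: v for k, v in masks.items() if v.any()}


def _category(on_states: set) -> str:
    if "REMS" in on_states and "AW" in on_states:
        return "REMS_AW_ON"
    if "AW" in on_states:
        return "AW_ON"
    if "REMS" in on_states:
        return "REMS_ON"
    if "SC" in on_states:
        return "SC_ON"
    if "NREMS" in on_states:
        return "NREMS_ON"
    return "unscored"


def classify_cells(
    zmatrix: TraceMatrix, labeled_bouts: Sequence[Bout]
) -> list[CellProfile]:
    """Per-cell state means and ON classification (threshold z_qw + 1).

    Precedence for the exclusive category: ON in both REMS and AW ->
    REMS_AW_ON; then AW, REMS, SC, NREMS; ON in no pre-odor state ->
    unscored.  EC/HAW/AWO membership is kept as flags.
    """
    if zmatrix.kind != "zscore":
        raise ValueError("classify_cells expects a zscore matrix")
    masks = _frame_label_masks(labeled_bouts, zmatrix.n_frames)
    if "QW" not in masks:
        raise ValueError("no QW epochs: baseline undefined")
    profiles = []
    for i, cid in enumerate(zmatrix.cell_ids):
        z = zmatrix.values[i]
        means = {lab: float(z[m].mean()) for lab, m in masks.items()}
        z_qw = means["QW"]
        thr = z_qw + 1.0
        on = {s for s in _PRE_ODOR_STATES if s in means and means[s] >= thr}
        profiles.append(
            CellProfile(
                cell_id=cid,
                state_mean_z=means,
                z_qw=z_qw,
                on_states=on,
                category=_category(on),
                max_z=float(z.max()),
                ec_on=means.get("EC", -np.inf) >= thr,
                haw_on=means.get("HAW", -np.inf) >= thr,
                awo_on=means.get("AWO", -np.inf) >= thr,
            )
        )
    return profiles


def verify_on_separation(
    profiles: Sequence[CellProfile], states: Sequence[str] | None = None
) -> dict:
    """Confirm ON cells sit above non-ON cells: per-state one-way ANOVA on
    state-mean Z of ON vs non-ON cells, Bonferroni-adjusted across states."""
    if states is None:
        states = sorted({s for p in profiles for s in p.state_mean_z})
    results: dict[str, dict] = {}
    for s in states:
        def is_on(p: CellProfile) -> bool:
            if s == "EC":
                return p.ec_on
            if s == "HAW":
                return p.haw_on
            if s == "AWO":
                return p.awo_on
            return s in p.on_states
        on = [p.state_mean_z[s] for p in profiles if s in p.state_mean_z and is_on(p)]
        off = [p.state_mean_z[s] for p in profiles
               if s in p.state_mean_z and not is_on(p)]
        if len(on) < 2 or len(off) < 2:
            warnings.warn(f"state {s}: degenerate group sizes, skipped")
            continue
        results[s] = {"anova": one_way_anova([on, off]),
                      "n_on": len(on), "n_off": len(off)}
    k = len(results)
    for s, r in results.items():
        r["p_bonferroni"] = min(1.0, r["anova"].p * k)
    return results


_COMPOSITION_COLUMNS = (
    "unscored", "AW_ON", "REMS_ON/REMS_AW_ON", "NREMS_ON/SC_ON",
)


@dataclass
class CompositionTable:
    """HAW-ON / EC-ON rows decomposed by pre-odor category.

    ``rows`` maps row label -> {column -> (count, percent of row total)};
    the cross column reports the EC-ON/HAW-ON overlap.
    """

    rows: dict
    row_totals: dict

    def to_frame(self) -> pd.DataFrame:
        records = []
        for row_label, cols in self.rows.items():
            rec = {"group": row_label, "total": self.row_totals[row_label]}
            for col, (count, pct) in cols.items():
                rec[col] = f"{count} ({pct:.2f}%)"
            records.append(rec)
        return pd.DataFrame(records)


def composition_table(profiles: Sequence[CellProfile]) -> CompositionTable:
    """Table-2-style composition of HAW-ON and EC-ON cells."""
    def col_of(p: CellProfile) -> str:
        if p.category == "unscored":
            return "unscored"
        if p.category == "AW_ON":
            return "AW_ON"
        if p.category in ("REMS_ON", "REMS_AW_ON"):
            return "REMS_ON/REMS_AW_ON"
        return "NREMS_ON/SC_ON"

    rows = {}
    totals = {}
    overlap = sum(1 for p in profiles if p.haw_on and p.ec_on)
    for row_label, member in (
        ("HAW_ON", lambda p: p.haw_on),
        ("EC_ON", lambda p: p.ec_on),
    ):
        cells = [p for p in profiles if member(p)]
        total = len(cells)
        totals[row_label] = total
        cols = {}
        for col in _COMPOSITION_COLUMNS:
            count = sum(1 for p in cells if col_of(p) == col)
            cols[col] = (count, percent(count, total))
        cross = "EC_ON" if row_label == "HAW_ON" else "HAW_ON"
        cols[cross] = (overlap, percent(overlap, total))
        rows[row_label] = cols
    return CompositionTable(rows=rows, row_totals=totals)


def summarize_fractions(
    profiles: Sequence[CellProfile], group_label: str = ""
) -> pd.DataFrame:
    """Per-category counts and percentages of all recorded cells.

    Percentages are 100 * count / total rounded half-up to 2 decimals.  The
    SC-ON/NREMS overlap (cells ON in both) is reported as an extra row rather
    than folded into either category.
    """
    if not profiles:
        raise ValueError("empty profile list")
    total = len(profiles)
    records = []
    for cat in CATEGORY_ORDER:
        count = sum(1 for p in profiles if p.category == cat)
        records.append(
            {"group": group_label, "category": cat, "count": count,
             "total": total, "percent": percent(count, total)}
        )
    overlap = sum(
        1 for p in profiles if "SC" in p.on_states and "NREMS" in p.on_states
    )
    records.append(
        {"group": group_label, "category": "SC_ON∩NREMS_ON", "count": overlap,
         "total": total, "percent": percent(overlap, total)}
    )
    return pd.DataFrame(records)


def activity_heatmap(
    zmatrix: TraceMatrix, profiles: Sequence[CellProfile]
) -> tuple[np.ndarray, list[str]]:
    """Percent-of-max traces for heat-map display.

    Each included cell's Z trace is scaled to 100 * z / max_z and clipped
    below at 0; rows are ordered by category then cell id.  Cells with
    max_z <= 0 are excluded with a warning.
    """
    by_id = {p.cell_id: p for p in profiles}
    order = sorted(
        (p for p in profiles),
        key=lambda p: (CATEGORY_ORDER.index(p.category), p.cell_id),
    )
    rows, ids = [], []
    for p in order:
        if p.max_z <= 0:
            warnings.warn(f"cell {p.cell_id}: max Z <= 0, excluded from heat map")
            continue
        z = zmatrix.values[zmatrix.cell_index(p.cell_id)]
        rows.append(np.clip(100.0 * z / p.max_z, 0.0, None))
        ids.append(p.cell_id)
    if not rows:
        return np.empty((0, zmatrix.n_frames)), []
    return np.vstack(rows), ids


def plot_heatmap(matrix: np.ndarray, cell_ids: Sequence[str],
                 bouts: Sequence[Bout] | None = None, ax=None):
    """Render the percent-of-max matrix; bout boundaries as vertical lines."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(10, 0.15 * max(len(cell_ids), 10) + 2))
    im = ax.imshow(matrix, aspect="auto", cmap="viridis", vmin=0, vmax=100)
    if bouts is not None:
        for b in bouts:
            ax.axvline(b.start_frame, color="w", lw=0.3, alpha=0.5)
    ax.set_xlabel("frame")
    ax.set_ylabel("cell (by category)")
    ax.figure.colorbar(im, ax=ax, label="% of max Z")
    return ax
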