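"""Epoch scoring, bout segmentation, and cataplexy / HAW / SC / EC rules.

Scoring operates on per-epoch EEG/EMG summary features (delta power, theta
power, EMG RMS, movement flag) at 4 s resolution.  Cataplexy is validated by
the four-criterion rule: an abrupt atonic episode of at least 8 s (2 epochs),
immobility throughout, theta-dominant EEG throughout, and at least 40 s
(10 epochs) of preceding wakefulness — or chaining onto a preceding
qualifying cataplexy bout across a short all-wake gap (sequential cataplexy).

After predator-odor onset, AW bouts are tested for hyperactivity against the
pooled pre-odor AW baseline (one-sample t test on per-cell bout means);
significantly elevated bouts become HAW, the rest AWO.  Cataplexy bouts are
then typed by their nearest preceding AW-family bout: HAW -> emotion-induced
(EC), undisturbed AW or AWO -> spontaneous (SC).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .core import Bout, Hypnogram, TraceMatrix, WAKE_STATES
from .stats import AnovaResult, one_sample_t, one_way_anova, sem

REQUIRED_FEATURES = ("delta_power", "theta_power", "emg_rms", "movement_flag")

#: Minimum cataplexy duration in epochs (8 s at 4 s epochs).
MIN_CATAPLEXY_EPOCHS = 2
#: Required preceding wake run in epochs (40 s at 4 s epochs).
PRIOR_WAKE_EPOCHS = 10


@dataclass
class ScoringThresholds:
    """Decision thresholds for epoch scoring.

    Defaults are calibrated to the synthetic feature model's state medians:
    wake EMG >= ``emg_wake``; AW additionally needs movement or EMG >=
    ``emg_active``; atonia (REMS/cataplexy) needs EMG < ``emg_atonia`` and
    theta/delta >= ``theta_ratio``.
    """

    emg_wake: float = 0.8
    emg_active: float = 2.5
    emg_atonia: float = 0.3
    theta_ratio: float = 2.0


def _check_features(features: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_FEATURES if c not in features.columns]
    if missing:
        raise ValueError(f"missing feature channels: {missing}")


def _raw_epoch_labels(
    features: pd.DataFrame, thresholds: ScoringThresholds
) -> np.ndarray:
    """Per-epoch rules; atonic theta-dominant epochs become CATAPLEXY
    candidates (context later decides REMS vs cataplexy)."""
    delta = features["delta_power"].to_numpy(dtype=float)
    theta = features["theta_power"].to_numpy(dtype=float)
    emg = features["emg_rms"].to_numpy(dtype=float)
    moving = features["movement_flag"].to_numpy(dtype=bool)
    labels = np.full(delta.shape[0], "QW", dtype="U9")
    wake = emg >= thresholds.emg_wake
    labels[wake & (moving | (emg >= thresholds.emg_active))] = "AW"
    atonic = (~wake) & (emg < thresholds.emg_atonia)
    candidate = atonic & (theta / delta >= thresholds.theta_ratio) & (~moving)
    nrem = (~wake) & (~candidate) & (delta > theta)
    labels[nrem] = "NREMS"
    labels[candidate] = "CATAPLEXY"
    return labels


def segment_bouts(
    hypnogram: Hypnogram, frame_rate_hz: float = 10.0
) -> list[Bout]:
    """Maximal runs of identical labels; bouts partition the recording."""
    labels = hypnogram.labels
    fpe = hypnogram.frames_per_epoch(frame_rate_hz)
    change = np.flatnonzero(labels[1:] != labels[:-1]) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [labels.shape[0]]])
    return [
        Bout(
            state=str(labels[s]),
            start_epoch=int(s),
            end_epoch=int(e),
            epoch_s=hypnogram.epoch_s,
            frames_per_epoch=fpe,
        )
        for s, e in zip(starts, ends)
    ]


def _bouts_to_hypnogram(bouts: Sequence[Bout]) -> Hypnogram:
    n = max(b.end_epoch for b in bouts)
    labels = np.empty(n, dtype="U9")
    for b in bouts:
        labels[b.start_epoch : b.end_epoch] = b.state
    return Hypnogram(labels, bouts[0].epoch_s)


def validate_cataplexy(
    bouts: Sequence[Bout],
    features: pd.DataFrame,
    thresholds: ScoringThresholds | None = None,
) -> list[Bout]:
    """Apply the four cataplexy criteria to candidate bouts.

    Qualifying candidates keep the CATAPLEXY state (chained bouts record the
    chain root in ``chain_start_epoch``); non-qualifying candidates are
    relabeled REMS when immediately preceded by NREMS, else QW, and the bout
    list is re-segmented.
    """
    if thresholds is None:
        thresholds = ScoringThresholds()
    _check_features(features)
    delta = features["delta_power"].to_numpy(dtype=float)
    theta = features["theta_power"].to_numpy(dtype=float)
    emg = features["emg_rms"].to_numpy(dtype=float)
    moving = features["movement_flag"].to_numpy(dtype=bool)

    epoch_states = np.empty(max(b.end_epoch for b in bouts), dtype="U9")
    for b in bouts:
        epoch_states[b.start_epoch : b.end_epoch] = b.state

    qualified: list[tuple[int, int, int]] = []  # (start, end, chain_root_start)
    relabel: dict[int, str] = {}  # start_epoch -> replacement state
    ordered = sorted(bouts, key=lambda b: b.start_epoch)
    for i, b in enumerate(ordered):
        if b.state != "CATAPLEXY":
            continue
        sl = slice(b.start_epoch, b.end_epoch)
        ok = (
            b.n_epochs >= MIN_CATAPLEXY_EPOCHS
            and bool((emg[sl] < thresholds.emg_atonia).all())
            and not bool(moving[sl].any())
            and bool((theta[sl] > delta[sl]).all())
        )
        chain_root = None
        if ok:
            prior = epoch_states[max(0, b.start_epoch - PRIOR_WAKE_EPOCHS) : b.start_epoch]
            discrete = (
                prior.shape[0] == PRIOR_WAKE_EPOCHS
                and all(s in WAKE_STATES for s in prior)
            )
            if not discrete:
                # sequential-cataplexy chaining: short all-wake gap after a
                # qualifying bout
                chained = False
                for qs, qe, root in reversed(qualified):
                    gap = b.start_epoch - qe
                    if 0 <= gap < PRIOR_WAKE_EPOCHS:
                        gap_states = epoch_states[qe : b.start_epoch]
                        if all(s in WAKE_STATES for s in gap_states):
                            chain_root = root
                            chained = True
                    break  # only the immediately preceding qualifying bout
                ok = chained
        if ok:
            qualified.append(
                (b.start_epoch, b.end_epoch,
                 chain_root if chain_root is not None else b.start_epoch)
            )
        else:
            prev_state = ordered[i - 1].state if i > 0 else None
            relabel[b.start_epoch] = "REMS" if prev_state == "NREMS" else "QW"

    if not relabel and not qualified:
        return list(ordered)

    new_states = epoch_states.copy()
    for b in ordered:
        if b.start_epoch in relabel:
            new_states[b.start_epoch : b.end_epoch] = relabel[b.start_epoch]
    out = segment_bouts(
        Hypnogram(new_states, ordered[0].epoch_s),
        ordered[0].frames_per_epoch / ordered[0].epoch_s,
    )
    roots = {qs: root for qs, qe, root in qualified}
    return [
        b.relabeled(chain_start_epoch=roots[b.start_epoch])
        if b.state == "CATAPLEXY" and b.start_epoch in roots
        else b
        for b in out
    ]


def score_epochs(
    features: pd.DataFrame,
    thresholds: ScoringThresholds | None = None,
    epoch_s: float = 4.0,
    frame_rate_hz: float = 10.0,
) -> Hypnogram:
    """Score epochs into AW/QW/NREMS/REMS/CATAPLEXY.

    Applies the per-epoch threshold rules, then resolves atonic theta-dominant
    candidates into REMS or cataplexy from their wake context (the four
    cataplexy criteria).  On noise-free synthetic features this recovers the
    generating hypnogram exactly.
    """
    if thresholds is None:
        thresholds = ScoringThresholds()
    _check_features(features)
    raw = Hypnogram(_raw_epoch_labels(features, thresholds), epoch_s)
    bouts = segment_bouts(raw, frame_rate_hz)
    bouts = validate_cataplexy(bouts, features, thresholds)
    return _bouts_to_hypnogram(bouts)


def score_and_segment(
    features: pd.DataFrame,
    thresholds: ScoringThresholds | None = None,
    epoch_s: float = 4.0,
    frame_rate_hz: float = 10.0,
) -> list[Bout]:
    """Scored, cataplexy-validated bout list (chain info preserved)."""
    if thresholds is None:
        thresholds = ScoringThresholds()
    _check_features(features)
    raw = Hypnogram(_raw_epoch_labels(features, thresholds), epoch_s)
    bouts = segment_bouts(raw, frame_rate_hz)
    return validate_cataplexy(bouts, features, thresholds)


# ---------------------------------------------------------------------------
# HAW / AWO and SC / EC labeling
# ---------------------------------------------------------------------------

def label_haw(
    bouts: Sequence[Bout],
    zmatrix: TraceMatrix,
    odor_onset_s: float,
    alpha: float = 0.05,
) -> list[Bout]:
    """Label post-odor AW bouts as hyperactive (HAW) or not (AWO).

    Baseline is the mean Z over all frames of all pre-odor AW bouts pooled
    across cells.  For each AW bout starting at or after odor onset, per-cell
    mean Z values within the bout are tested against the baseline with a
    one-sided one-sample t test; p < alpha with an elevated mean gives HAW.
    Bouts with fewer than 2 cells cannot be tested and become AWO.
    """
    if zmatrix.kind != "zscore":
        raise ValueError("label_haw expects a zscore matrix")
    pre_frames = [
        b.frame_slice()
        for b in bouts
        if b.state == "AW" and b.start_s < odor_onset_s
    ]
    if not pre_frames:
        raise ValueError("no pre-odor AW bouts: baseline undefined")
    onset_frame = int(round(odor_onset_s * zmatrix.frame_rate_hz))
    baseline_chunks = [
        zmatrix.values[:, sl.start : min(sl.stop, onset_frame)] for sl in pre_frames
    ]
    baseline_chunks = [c for c in baseline_chunks if c.shape[1] > 0]
    mu_aw = float(np.concatenate(baseline_chunks, axis=1).mean())

    out = []
    for b in bouts:
        if b.state == "AW" and b.start_s >= odor_onset_s:
            cell_means = zmatrix.values[:, b.frame_slice()].mean(axis=1)
            if cell_means.size < 2:
                out.append(b.relabeled(derived_label="AWO", note="too few cells"))
                continue
            res = one_sample_t(cell_means, mu_aw)
            label = "HAW" if (res.p_one_sided < alpha and res.mean > mu_aw) else "AWO"
            out.append(b.relabeled(derived_label=label))
        else:
            out.append(b)
    return out


def label_cataplexy_type(bouts: Sequence[Bout]) -> list[Bout]:
    """Label cataplexy bouts SC or EC from the nearest preceding AW-family bout.

    The backward scan skips QW; a preceding HAW gives EC, an undisturbed AW
    or a non-hyperactive AWO gives SC.  Chained cataplexy bouts inherit the
    type of the chain's first bout.  Bouts whose wake context required
    skipping sleep states are flagged in ``note``.
    """
    ordered = sorted(bouts, key=lambda b: b.start_epoch)
    typed: dict[int, str] = {}  # start_epoch -> SC/EC
    out: list[Bout] = []
    for i, b in enumerate(ordered):
        if b.state != "CATAPLEXY":
            out.append(b)
            continue
        if (
            b.chain_start_epoch is not None
            and b.chain_start_epoch != b.start_epoch
            and b.chain_start_epoch in typed
        ):
            label = typed[b.chain_start_epoch]
            typed[b.start_epoch] = label
            out.append(b.relabeled(derived_label=label))
            continue
        label = None
        note = b.note
        for j in range(i - 1, -1, -1):
            prev = ordered[j]
            if prev.state in ("QW", "CATAPLEXY"):
                # QW interludes and earlier (non-chained) cataplexy bouts do
                # not define the wake context; keep scanning for AW-family
                continue
            if prev.state == "AW":
                label = "EC" if prev.derived_label == "HAW" else "SC"
                break
            # intervening sleep bout: keep scanning but flag the ambiguity
            note = "wake context beyond intervening sleep"
        if label is None:
            raise ValueError(
                f"cataplexy bout at epoch {b.start_epoch} has no preceding wake bout"
            )
        typed[b.start_epoch] = label
        out.append(b.relabeled(derived_label=label, note=note))
    return out


@dataclass
class DurationSummary:
    durations_by_label: dict
    mean_by_label: dict
    sem_by_label: dict
    anova: AnovaResult | None


def bout_durations(
    bouts: Sequence[Bout], labels: Sequence[str] = ("SC", "EC")
) -> DurationSummary:
    """Durations (s) of labeled bouts with mean +/- SEM and a one-way ANOVA
    across labels (omitted when any group has fewer than 2 bouts)."""
    groups = {
        lab: [b.duration_s for b in bouts if b.effective_label == lab]
        for lab in labels
    }
    anova = None
    if len(groups) >= 2 and all(len(g) >= 2 for g in groups.values()):
        anova = one_way_anova(list(groups.values()))
    return DurationSummary(
        durations_by_label=groups,
        mean_by_label={
            lab: (float(np.mean(g)) if g else float("nan"))
            for lab, g in groups.items()
        },
        sem_by_label={lab: sem(g) for lab, g in groups.items()},
        anova=anova,
    )
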