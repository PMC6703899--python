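"""Synthetic miniscope sessions with known ground truth.

Emulates the statistical structure the downstream analysis assumes: a
semi-Markov sleep/wake hypnogram with cataplexy only in narcoleptic animals,
an odor-exposure window that elevates activity and cataplexy hazard, state-
conditioned EEG/EMG epoch features, and per-cell fluorescence traces built
from Poisson event trains convolved with a fast-rise/slow-decay calcium
kernel.  Every piece of randomness flows from the session seed through
tagged ``numpy`` seed sequences, so identical configs reproduce byte-
identical sessions; per-cell substreams are derived by stable hashing of the
cell id.
"""

from __future__ import annotations

import json
import math
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal import fftconvolve

from .core import Bout, Hypnogram, TraceMatrix, WAKE_STATES

GENOTYPES = ("narcoleptic", "control")

# Tags keep the hypnogram / feature / trace substreams independent.
_TAG_HYPNO = 101
_TAG_FEATURES = 202
_TAG_TRACES = 303
_TAG_SHARED = 404
_TAG_TUNING = 505

TUNING_CLASSES = (
    "REMS_ON",
    "AW_ON",
    "REMS_AW_ON",
    "NREMS_ON",
    "SC_ON",
    "unscored_ECrecruit",
    "unscored_flat",
)


def _cell_stream(seed: int, tag: int, cell_id: str) -> np.random.Generator:
    """Substream keyed by a stable CRC32 hash of the cell id."""
    return np.random.default_rng(
        np.random.SeedSequence([seed, tag, zlib.crc32(cell_id.encode())])
    )


@dataclass
class SessionConfig:
    """Recording-session parameters.

    ``odor_onset_s`` marks the start of predator-odor exposure (absent for
    undisturbed sessions); ``odor_duration_s`` defaults to one hour.
    """

    genotype: str
    n_cells: int = 40
    duration_s: float = 7200.0
    frame_rate_hz: float = 10.0
    epoch_s: float = 4.0
    odor_onset_s: float | None = None
    odor_duration_s: float = 3600.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.genotype not in GENOTYPES:
            raise ValueError(f"genotype must be one of {GENOTYPES}")
        if self.n_cells < 1:
            raise ValueError("n_cells must be positive")
        n_epochs = self.duration_s / self.epoch_s
        if abs(n_epochs - round(n_epochs)) > 1e-9:
            raise ValueError("duration_s must be an integer multiple of epoch_s")
        fpe = self.frame_rate_hz * self.epoch_s
        if abs(fpe - round(fpe)) > 1e-9:
            raise ValueError("frame_rate_hz * epoch_s must be an integer")
        if self.odor_onset_s is not None:
            if self.odor_onset_s + self.odor_duration_s > self.duration_s + 1e-9:
                raise ValueError("odor window must end within the recording")

    @property
    def n_epochs(self) -> int:
        return int(round(self.duration_s / self.epoch_s))

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s * self.frame_rate_hz))

    @property
    def frames_per_epoch(self) -> int:
        return int(round(self.frame_rate_hz * self.epoch_s))

    def in_odor_window(self, t_s: float) -> bool:
        if self.odor_onset_s is None:
            return False
        return self.odor_onset_s <= t_s < self.odor_onset_s + self.odor_duration_s


@dataclass
class StateModel:
    """Semi-Markov sleep architecture with cataplexy insertion.

    Bout durations are exponential with state-specific means, truncated below
    at one epoch.  REMS is reachable only from NREMS.  After any wake run of
    at least 10 epochs (40 s) a cataplexy bout is inserted with probability
    ``cataplexy_hazard`` (multiplied during the odor window); chained follow-up
    bouts occur with probability ``chain_prob`` after a short wake gap.
    ``haw_fraction`` is the probability that a post-odor AW bout is generated
    as hyperactive (ground truth only — the analysis must rediscover it).
    """

    mean_bout_duration_s: dict = field(
        default_factory=lambda: {
            "AW": 120.0,
            "QW": 60.0,
            "NREMS": 160.0,
            "REMS": 70.0,
            "CATAPLEXY": 30.0,
        }
    )
    transition_weights: dict = field(
        default_factory=lambda: {
            "AW": {"QW": 0.7, "NREMS": 0.3},
            "QW": {"AW": 0.4, "NREMS": 0.6},
            "NREMS": {"QW": 0.25, "AW": 0.30, "REMS": 0.45},
            "REMS": {"AW": 0.6, "QW": 0.4},
            "CATAPLEXY": {"AW": 0.6, "QW": 0.4},
        }
    )
    cataplexy_hazard: float = 0.25
    odor_cataplexy_hazard_multiplier: float = 3.0
    chain_prob: float = 0.25
    haw_fraction: float = 0.8

    def __post_init__(self) -> None:
        for state, weights in self.transition_weights.items():
            total = sum(weights.values())
            if total <= 0 or any(w < 0 for w in weights.values()):
                raise ValueError(f"invalid outgoing weights for {state}")


def default_state_model(genotype: str) -> StateModel:
    model = StateModel()
    if genotype == "control":
        model.cataplexy_hazard = 0.0
    return model


@dataclass
class CellTuning:
    """Per-cell event-rate tuning across behavioral contexts.

    ``event_rate_by_state`` keys cover the scored states (AW, QW, NREMS,
    REMS) plus the derived contexts SC (spontaneous cataplexy), HAW
    (hyperactive post-odor wake) and EC (emotion-induced cataplexy).
    ``coupling`` weights the shared latent drive during EC bouts, producing
    the hyper-synchrony the analysis must detect.
    """

    cell_id: str
    tuning_class: str
    event_rate_by_state: dict
    coupling: float = 0.0
    amplitude_mu: float = math.log(30.0)
    amplitude_sigma: float = 0.35
    centroid_xy: tuple = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.tuning_class not in TUNING_CLASSES:
            raise ValueError(f"unknown tuning class {self.tuning_class!r}")
        if any(r < 0 for r in self.event_rate_by_state.values()):
            raise ValueError("event rates must be nonnegative")
        if not 0.0 <= self.coupling <= 1.0:
            raise ValueError("coupling must be in [0, 1]")

    def rate(self, context: str) -> float:
        return self.event_rate_by_state.get(context, 0.0)


# Default per-class event rates (events/s).  QW is the quietest context for
# every class so the QW-baseline ON rule has a valid floor; each class's
# designated ON context carries the maximal rate.
_BASE = {"AW": 0.05, "QW": 0.02, "NREMS": 0.05, "REMS": 0.05,
         "SC": 0.05, "HAW": 0.05, "EC": 0.05}


def _rates(**over: float) -> dict:
    r = dict(_BASE)
    r.update(over)
    return r


_CLASS_RATES = {
    "REMS_ON": _rates(REMS=0.45, EC=0.08),
    "AW_ON": _rates(AW=0.45, HAW=0.50, EC=0.30),
    "REMS_AW_ON": _rates(REMS=0.55, AW=0.55, HAW=0.55, EC=0.25),
    "NREMS_ON": _rates(NREMS=0.35),
    "SC_ON": _rates(SC=0.50),
    "unscored_ECrecruit": _rates(HAW=0.55, EC=0.60),
    "unscored_flat": _rates(),
}
_CLASS_COUPLING = {
    "REMS_ON": 0.15,
    "AW_ON": 0.5,
    "REMS_AW_ON": 0.4,
    "NREMS_ON": 0.0,
    "SC_ON": 0.0,
    "unscored_ECrecruit": 0.8,
    "unscored_flat": 0.0,
}

# Class mix per genotype (fractions; remainder goes to unscored_flat).
_CLASS_MIX = {
    "narcoleptic": {
        "REMS_ON": 0.22, "AW_ON": 0.25, "REMS_AW_ON": 0.06,
        "NREMS_ON": 0.05, "SC_ON": 0.08, "unscored_ECrecruit": 0.20,
    },
    "control": {
        "REMS_ON": 0.24, "AW_ON": 0.29, "REMS_AW_ON": 0.05, "NREMS_ON": 0.04,
    },
}


def make_tunings(config: SessionConfig, field_px: float = 300.0) -> list[CellTuning]:
    """Default tuning assignment: fixed class mix, uniform centroids."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, _TAG_TUNING]))
    mix = _CLASS_MIX[config.genotype]
    counts = {cls: int(round(frac * config.n_cells)) for cls, frac in mix.items()}
    assigned = sum(counts.values())
    counts["unscored_flat"] = max(0, config.n_cells - assigned)
    classes: list[str] = []
    for cls in TUNING_CLASSES:
        classes.extend([cls] * counts.get(cls, 0))
    classes = classes[: config.n_cells]
    while len(classes) < config.n_cells:
        classes.append("unscored_flat")
    tunings = []
    for i, cls in enumerate(classes):
        cid = f"cell{i:03d}"
        tunings.append(
            CellTuning(
                cell_id=cid,
                tuning_class=cls,
                event_rate_by_state=dict(_CLASS_RATES[cls]),
                coupling=_CLASS_COUPLING[cls],
                centroid_xy=tuple(rng.uniform(0.0, field_px, size=2).round(2)),
            )
        )
    return tunings


# ---------------------------------------------------------------------------
# Hypnogram generation
# ---------------------------------------------------------------------------

def generate_hypnogram(
    config: SessionConfig, model: StateModel | None = None
) -> tuple[Hypnogram, list[dict]]:
    """Semi-Markov hypnogram plus ground-truth bout records.

    Returns the hypnogram and a list of bout dicts with keys ``state``,
    ``start_epoch``, ``end_epoch`` and ``gt_label`` (HAW/AWO on post-odor AW
    bouts, SC/EC on cataplexy bouts, else None).  Cataplexy bouts are at
    least 2 epochs (8 s) and only follow wake runs of >= 10 epochs (40 s) or
    chain onto a preceding bout across a short all-wake gap.
    """
    if model is None:
        model = default_state_model(config.genotype)
    if config.genotype == "control" and model.cataplexy_hazard != 0:
        raise ValueError("control sessions must have zero cataplexy hazard")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, _TAG_HYPNO]))
    n_epochs = config.n_epochs
    records: list[dict] = []
    total = 0

    def draw_epochs(state: str, min_epochs: int = 1) -> int:
        d = rng.exponential(model.mean_bout_duration_s[state])
        return max(min_epochs, int(round(d / config.epoch_s)))

    def emit(state: str, n: int, gt_label: str | None) -> None:
        nonlocal total
        n = min(n, n_epochs - total)
        if n <= 0:
            return
        records.append(
            {"state": state, "start_epoch": total, "end_epoch": total + n,
             "gt_label": gt_label}
        )
        total += n

    def trailing_wake_epochs() -> int:
        run = 0
        for rec in reversed(records):
            if rec["state"] in WAKE_STATES:
                run += rec["end_epoch"] - rec["start_epoch"]
            else:
                break
        return run

    def nearest_aw_label() -> str | None:
        for rec in reversed(records):
            if rec["state"] == "AW":
                return rec["gt_label"]  # None (undisturbed), "AWO" or "HAW"
            # QW and sleep states are skipped; cataplexy handled via chaining
        return None

    def aw_gt(start_epoch: int) -> str | None:
        if config.genotype != "narcoleptic":
            return None
        if not config.in_odor_window(start_epoch * config.epoch_s):
            return None
        return "HAW" if rng.random() < model.haw_fraction else "AWO"

    state = "AW"
    while total < n_epochs:
        emit(state, draw_epochs(state), aw_gt(total) if state == "AW" else None)
        if (
            config.genotype == "narcoleptic"
            and state in WAKE_STATES
            and total < n_epochs
            and trailing_wake_epochs() >= 10
        ):
            hazard = model.cataplexy_hazard
            if config.in_odor_window(total * config.epoch_s):
                hazard *= model.odor_cataplexy_hazard_multiplier
            if hazard > 0 and rng.random() < min(hazard, 1.0):
                cat_type = "EC" if nearest_aw_label() == "HAW" else "SC"
                emit("CATAPLEXY", draw_epochs("CATAPLEXY", min_epochs=2), cat_type)
                # sequential cataplexy: short all-wake gap, then another bout
                while total < n_epochs and rng.random() < model.chain_prob:
                    gap = int(rng.integers(1, 10))  # < 10 epochs keeps the chain
                    emit("AW", gap, aw_gt(total))
                    if total >= n_epochs:
                        break
                    emit("CATAPLEXY", draw_epochs("CATAPLEXY", min_epochs=2), cat_type)
                state = "CATAPLEXY"
        weights = model.transition_weights[state]
        nxt = list(weights)
        probs = np.array([weights[s] for s in nxt], dtype=float)
        state = str(rng.choice(nxt, p=probs / probs.sum()))

    labels = np.empty(n_epochs, dtype="U9")
    for rec in records:
        labels[rec["start_epoch"] : rec["end_epoch"]] = rec["state"]
    return Hypnogram(labels, config.epoch_s), records


def gt_records_to_bouts(records: Sequence[dict], config: SessionConfig) -> list[Bout]:
    """Ground-truth records as Bout objects with derived labels set."""
    return [
        Bout(
            state=r["state"],
            start_epoch=r["start_epoch"],
            end_epoch=r["end_epoch"],
            epoch_s=config.epoch_s,
            frames_per_epoch=config.frames_per_epoch,
            derived_label=r["gt_label"],
        )
        for r in records
    ]


# ---------------------------------------------------------------------------
# Epoch features
# ---------------------------------------------------------------------------

_ATONIC_EMG = 0.1  # shared by REMS and cataplexy (nuchal atonia)


@dataclass
class FeatureParams:
    """State-conditioned lognormal EEG/EMG feature model.

    ``medians`` maps state -> (delta_power, theta_power, emg_rms); values are
    lognormal with shape ``sigma`` around those medians.  Cataplexy shares
    the REMS atonic EMG parameter by construction.  ``sigma = 0`` gives the
    noise-free setting under which default scoring thresholds recover the
    generating hypnogram exactly.
    """

    medians: dict = field(
        default_factory=lambda: {
            "AW": (1.0, 1.5, 4.0),
            "QW": (1.2, 1.0, 1.5),
            "NREMS": (4.0, 1.0, 0.5),
            "REMS": (0.8, 3.0, _ATONIC_EMG),
            "CATAPLEXY": (0.8, 3.0, _ATONIC_EMG),
        }
    )
    movement_prob: dict = field(
        default_factory=lambda: {
            "AW": 1.0, "QW": 0.0, "NREMS": 0.0, "REMS": 0.0, "CATAPLEXY": 0.0,
        }
    )
    sigma: float = 0.2

    @classmethod
    def noise_free(cls) -> "FeatureParams":
        return cls(sigma=0.0)


def generate_epoch_features(
    hypnogram: Hypnogram, seed: int, params: FeatureParams | None = None
) -> pd.DataFrame:
    """Per-epoch delta/theta power, EMG RMS and movement flag."""
    if params is None:
        params = FeatureParams()
    rng = np.random.default_rng(np.random.SeedSequence([seed, _TAG_FEATURES]))
    n = hypnogram.n_epochs
    med = np.array([params.medians[s] for s in hypnogram.labels])
    noise = (
        np.exp(params.sigma * rng.standard_normal((n, 3)))
        if params.sigma > 0
        else np.ones((n, 3))
    )
    vals = med * noise
    move_p = np.array([params.movement_prob[s] for s in hypnogram.labels])
    movement = rng.random(n) < move_p
    return pd.DataFrame(
        {
            "epoch_index": np.arange(n),
            "delta_power": vals[:, 0],
            "theta_power": vals[:, 1],
            "emg_rms": vals[:, 2],
            "movement_flag": movement,
        }
    )


# ---------------------------------------------------------------------------
# Fluorescence traces
# ---------------------------------------------------------------------------

@dataclass
class TraceParams:
    """Calcium-trace synthesis parameters.

    Kernel k(t) = exp(-t/tau_d) - exp(-t/tau_r) with rise tau_r << decay
    tau_d (GCaMP6s-like at 10 frames/s).  ``shared_rate`` is the latent
    Poisson drive (events/s) mixed into coupled cells during EC bouts.
    """

    tau_r_s: float = 0.2
    tau_d_s: float = 1.5
    baseline: float = 100.0
    noise_sigma: float = 1.5
    shared_rate: float = 0.6
    kernel_cutoff_s: float = 12.0

    def __post_init__(self) -> None:
        if self.tau_r_s >= self.tau_d_s:
            raise ValueError("tau_r must be smaller than tau_d")
        if self.baseline <= 0:
            raise ValueError("baseline must be positive")


def calcium_kernel(params: TraceParams, frame_rate_hz: float) -> np.ndarray:
    t = np.arange(0.0, params.kernel_cutoff_s, 1.0 / frame_rate_hz)
    return np.exp(-t / params.tau_d_s) - np.exp(-t / params.tau_r_s)


def _frame_contexts(
    hypnogram: Hypnogram, gt_records: Sequence[dict] | None, frame_rate_hz: float
) -> np.ndarray:
    """Per-frame rate-lookup context: states plus SC/EC/HAW overlays."""
    labels = hypnogram.frame_labels(frame_rate_hz).copy()
    labels[labels == "CATAPLEXY"] = "SC"
    if gt_records:
        fpe = hypnogram.frames_per_epoch(frame_rate_hz)
        for rec in gt_records:
            if rec["gt_label"] in ("HAW", "EC"):
                labels[rec["start_epoch"] * fpe : rec["end_epoch"] * fpe] = rec[
                    "gt_label"
                ]
    return labels


def generate_traces(
    hypnogram: Hypnogram,
    tunings: Sequence[CellTuning],
    config: SessionConfig,
    gt_records: Sequence[dict] | None = None,
    params: TraceParams | None = None,
) -> tuple[TraceMatrix, dict]:
    """Raw fluorescence traces plus ground-truth event frames per cell.

    Events are inhomogeneous Poisson with the tuning's context-conditioned
    rate; during EC bouts each cell receives a mixture of private events
    (rate scaled by 1 - coupling) and a thinned copy of one shared latent
    Poisson train (inclusion probability = coupling), which is what makes EC
    bouts hyper-synchronous.  Events are convolved with the calcium kernel,
    then baseline offset and Gaussian noise are added.
    """
    if not tunings:
        raise ValueError("tunings must be nonempty")
    if params is None:
        params = TraceParams()
    rate_hz = config.frame_rate_hz
    dt = 1.0 / rate_hz
    contexts = _frame_contexts(hypnogram, gt_records, rate_hz)
    n_frames = contexts.shape[0]
    kernel = calcium_kernel(params, rate_hz)
    ec_mask = contexts == "EC"

    shared_rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, _TAG_SHARED])
    )
    shared_counts = np.zeros(n_frames, dtype=np.int64)
    if ec_mask.any():
        shared_counts[ec_mask] = shared_rng.poisson(
            params.shared_rate * dt, size=int(ec_mask.sum())
        )

    unique_contexts = sorted(set(contexts.tolist()))
    values = np.empty((len(tunings), n_frames))
    event_times: dict[str, list[int]] = {}
    for row, tuning in enumerate(tunings):
        rng = _cell_stream(config.seed, _TAG_TRACES, tuning.cell_id)
        rates = np.zeros(n_frames)
        for ctx in unique_contexts:
            rates[contexts == ctx] = tuning.rate(ctx)
        private_rates = np.where(ec_mask, rates * (1.0 - tuning.coupling), rates)
        counts = rng.poisson(private_rates * dt)
        if tuning.coupling > 0 and ec_mask.any():
            counts = counts + rng.binomial(shared_counts, tuning.coupling)
        frames = np.repeat(np.arange(n_frames), counts)
        impulse = np.zeros(n_frames)
        if frames.size:
            amps = rng.lognormal(tuning.amplitude_mu, tuning.amplitude_sigma,
                                 size=frames.size)
            np.add.at(impulse, frames, amps)
        conv = fftconvolve(impulse, kernel)[:n_frames] if frames.size else impulse
        noise = rng.normal(0.0, params.noise_sigma, size=n_frames)
        values[row] = params.baseline + conv + noise
        event_times[tuning.cell_id] = frames.astype(int).tolist()

    return (
        TraceMatrix(values, rate_hz, "raw", [t.cell_id for t in tunings]),
        event_times,
    )


# ---------------------------------------------------------------------------
# Whole-session bundle and file output
# ---------------------------------------------------------------------------

@dataclass
class Session:
    """A complete synthetic session with its ground truth."""

    config: SessionConfig
    model: StateModel
    hypnogram: Hypnogram
    gt_records: list[dict]
    features: pd.DataFrame
    raw: TraceMatrix
    tunings: list[CellTuning]
    event_times: dict

    def ground_truth(self) -> dict:
        return {
            "hypnogram": self.hypnogram.labels.tolist(),
            "bouts": self.gt_records,
            "tuning_class": {t.cell_id: t.tuning_class for t in self.tunings},
            "event_times": self.event_times,
        }


def simulate_session(
    config: SessionConfig,
    model: StateModel | None = None,
    tunings: Sequence[CellTuning] | None = None,
    feature_params: FeatureParams | None = None,
    trace_params: TraceParams | None = None,
) -> Session:
    """Generate hypnogram, epoch features, tunings and traces in one call."""
    if model is None:
        model = default_state_model(config.genotype)
    hypnogram, gt_records = generate_hypnogram(config, model)
    features = generate_epoch_features(hypnogram, config.seed, feature_params)
    if tunings is None:
        tunings = make_tunings(config)
    raw, event_times = generate_traces(
        hypnogram, tunings, config, gt_records, trace_params
    )
    return Session(
        config=config, model=model, hypnogram=hypnogram, gt_records=gt_records,
        features=features, raw=raw, tunings=list(tunings), event_times=event_times,
    )


def write_config(config: SessionConfig, path: str | Path) -> None:
    """Flat key-value text file (``key = value`` per line)."""
    lines = []
    for key, value in asdict(config).items():
        lines.append(f"{key} = {'' if value is None else value}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_config(path: str | Path) -> SessionConfig:
    fields = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, _, value = line.partition("=")
        fields[key.strip()] = value.strip()
    def num(x: str) -> float:
        return float(x)
    return SessionConfig(
        genotype=fields["genotype"],
        n_cells=int(float(fields.get("n_cells", 40))),
        duration_s=num(fields.get("duration_s", "7200")),
        frame_rate_hz=num(fields.get("frame_rate_hz", "10")),
        epoch_s=num(fields.get("epoch_s", "4")),
        odor_onset_s=(num(fields["odor_onset_s"]) if fields.get("odor_onset_s")
                      else None),
        odor_duration_s=num(fields.get("odor_duration_s", "3600")),
        seed=int(float(fields.get("seed", 0))),
    )


def write_session(session: Session, outdir: str | Path) -> dict:
    """Write the session's file set; returns {name: path}."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "config": outdir / "config.txt",
        "traces": outdir / "traces_raw.csv",
        "hypnogram": outdir / "hypnogram.csv",
        "features": outdir / "epoch_features.csv",
        "ground_truth": outdir / "ground_truth.json",
        "centroids": outdir / "centroids.csv",
    }
    write_config(session.config, paths["config"])
    session.raw.to_csv(paths["traces"])
    session.hypnogram.to_csv(paths["hypnogram"])
    session.features.to_csv(paths["features"], index=False, float_format="%.10g")
    paths["ground_truth"].write_text(json.dumps(session.ground_truth(), indent=1))
    pd.DataFrame(
        {
            "cell_id": [t.cell_id for t in session.tunings],
            "x": [t.centroid_xy[0] for t in session.tunings],
            "y": [t.centroid_xy[1] for t in session.tunings],
        }
    ).to_csv(paths["centroids"], index=False)
    return {k: str(v) for k, v in paths.items()}
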