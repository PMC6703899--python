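import warnings

import numpy as np
import pytest

from catnap import pipeline, synth
from catnap.core import Bout, TraceMatrix

DEMO_SEED = 7


def narco_config(seed=DEMO_SEED, n_cells=60):
    return synth.SessionConfig(
        genotype="narcoleptic", n_cells=n_cells, duration_s=7200.0,
        odor_onset_s=3600.0, odor_duration_s=3600.0, seed=seed,
    )


@pytest.fixture(scope="session")
def narco_session():
    """2 h narcoleptic session, 60 cells, odor in the second hour."""
    return synth.simulate_session(narco_config())


@pytest.fixture(scope="session")
def narco_analysis(narco_session):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return pipeline.analyze_session(narco_session)


@pytest.fixture(scope="session")
def control_session():
    cfg = synth.SessionConfig(
        genotype="control", n_cells=40, duration_s=7200.0,
        odor_onset_s=3600.0, odor_duration_s=3600.0, seed=DEMO_SEED,
    )
    return synth.simulate_session(cfg)


@pytest.fixture(scope="session")
def control_analysis(control_session):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return pipeline.analyze_session(control_session)


def make_zmatrix(values, frame_rate_hz=10.0, prefix="c"):
    values = np.asarray(values, dtype=float)
    return TraceMatrix(
        values, frame_rate_hz, "zscore",
        [f"{prefix}{i}" for i in range(values.shape[0])],
    )


def make_bouts(labels, epoch_s=4.0, frames_per_epoch=40):
    """Bout list from a per-epoch label sequence (raw states only)."""
    bouts = []
    start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[start]:
            bouts.append(
                Bout(labels[start], start, i, epoch_s, frames_per_epoch)
            )
            start = i
    return bouts
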