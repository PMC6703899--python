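"""Fluorescence normalization: ΔF/F and per-cell Z-scores."""

from __future__ import annotations

import numpy as np

from .core import TraceMatrix


def compute_dff(raw: TraceMatrix) -> TraceMatrix:
    """ΔF/F with per-cell background F0 = full-recording mean of the raw trace.

    (ΔF/F)_i = (F_i - F0) / F0.  The per-cell mean of the output is zero by
    construction.  Raw values must be strictly positive.
    """
    if raw.kind != "raw":
        raise ValueError(f"compute_dff expects a raw matrix, got {raw.kind!r}")
    bad = np.where((raw.values <= 0).any(axis=1))[0]
    if bad.size:
        names = ", ".join(raw.cell_ids[i] for i in bad[:10])
        raise ValueError(f"nonpositive raw fluorescence in cells: {names}")
    f0 = raw.values.mean(axis=1, keepdims=True)
    return TraceMatrix(
        (raw.values - f0) / f0, raw.frame_rate_hz, "dff", list(raw.cell_ids)
    )


def compute_zscore(dff: TraceMatrix) -> TraceMatrix:
    """Per-cell standardization over the full recording: z = (x - mean) / SD.

    SD is the population standard deviation (denominator N).  Flat cells
    (SD = 0) are an error so they cannot silently corrupt classification;
    callers may drop them and retry.
    """
    if dff.kind != "dff":
        raise ValueError(f"compute_zscore expects a dff matrix, got {dff.kind!r}")
    mean = dff.values.mean(axis=1, keepdims=True)
    sd = dff.values.std(axis=1, keepdims=True)  # population SD, ddof=0
    flat = np.where(sd[:, 0] == 0)[0]
    if flat.size:
        names = ", ".join(dff.cell_ids[i] for i in flat)
        raise ValueError(f"flat cells with zero SD: {names}")
    return TraceMatrix(
        (dff.values - mean) / sd, dff.frame_rate_hz, "zscore", list(dff.cell_ids)
    )


def normalize(raw: TraceMatrix) -> TraceMatrix:
    """Convenience: raw -> ΔF/F -> Z-score."""
    return compute_zscore(compute_dff(raw))
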