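"""End-to-end session runs: simulate → normalize → score → classify →
peaks → synchrony → transitions → report.

Every run writes a manifest (config snapshot, seed, output inventory with
SHA-256 digests, captured warnings) so reruns with the same config and seed
can be verified byte-identical on the CSV outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__, cellclass, peaks, signal, sleepstate, synchrony, synth, transitions
from .core import bouts_to_frame
from .stats import percent

log = logging.getLogger("catnap")


@dataclass
class RunManifest:
    config: dict
    seed: int
    version: str
    outputs: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)
    timings_s: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, default=str))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def demo_config(genotype: str, seed: int = 0, n_cells: int = 40) -> synth.SessionConfig:
    """Default demo session: 2 h recording, odor exposure in the second hour."""
    return synth.SessionConfig(
        genotype=genotype,
        n_cells=n_cells,
        duration_s=7200.0,
        odor_onset_s=3600.0,
        odor_duration_s=3600.0,
        seed=seed,
    )


def analyze_session(
    session: synth.Session,
    thresholds: sleepstate.ScoringThresholds | None = None,
    alpha: float = 0.05,
) -> dict:
    """Run the full analysis chain on an in-memory session.

    Returns a dict with the Z-scored matrix, labeled bouts, cell profiles,
    peak trains/statistics, synchrony results and transition profiles.
    """
    cfg = session.config
    zmat = signal.normalize(session.raw)
    bouts = sleepstate.score_and_segment(
        session.features, thresholds, cfg.epoch_s, cfg.frame_rate_hz
    )
    if cfg.odor_onset_s is not None:
        bouts = sleepstate.label_haw(bouts, zmat, cfg.odor_onset_s, alpha)
    if any(b.state == "CATAPLEXY" for b in bouts):
        bouts = sleepstate.label_cataplexy_type(bouts)
    profiles = cellclass.classify_cells(zmat, bouts)
    trains = peaks.detect_peaks(zmat)
    peak_stats = peaks.peak_stats_by_state(trains, bouts)
    sync = synchrony.session_synchrony(zmat, bouts)
    durations = sleepstate.bout_durations(bouts)

    trans = {}
    if any(b.effective_label == "EC" for b in bouts):
        groups = {
            "HAW_ON": [p.cell_id for p in profiles if p.haw_on],
            "REMS_ON": [p.cell_id for p in profiles if p.category == "REMS_ON"],
            "unscored": [p.cell_id for p in profiles if p.category == "unscored"],
        }
        for name, ids in groups.items():
            if ids:
                trans[name] = transitions.transition_profile(
                    zmat, bouts, ids, bout_type="EC", group_label=name
                )
    return {
        "zmatrix": zmat,
        "bouts": bouts,
        "profiles": profiles,
        "peak_trains": trains,
        "peak_stats": peak_stats,
        "synchrony": sync,
        "durations": durations,
        "transitions": trans,
    }


def profiles_to_frame(profiles: Sequence[cellclass.CellProfile]) -> pd.DataFrame:
    states = sorted({s for p in profiles for s in p.state_mean_z})
    records = []
    for p in profiles:
        rec = {"cell_id": p.cell_id, "category": p.category, "z_qw": p.z_qw,
               "max_z": p.max_z, "on_states": "|".join(sorted(p.on_states)),
               "ec_on": p.ec_on, "haw_on": p.haw_on, "awo_on": p.awo_on}
        for s in states:
            rec[f"mean_z_{s}"] = p.state_mean_z.get(s, np.nan)
        records.append(rec)
    return pd.DataFrame(records)


def run_session(
    config: synth.SessionConfig | str | Path,
    outdir: str | Path,
    thresholds: sleepstate.ScoringThresholds | None = None,
    alpha: float = 0.05,
) -> RunManifest:
    """Simulate and analyze one session, writing all per-module outputs."""
    if not isinstance(config, synth.SessionConfig):
        config = synth.read_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=asdict(config), seed=config.seed,
                           version=__version__)

    def stage(name):
        class _Timer:
            def __enter__(self_inner):
                log.info("stage %s", name)
                self_inner.t0 = time.perf_counter()
                return self_inner

            def __exit__(self_inner, exc_type, exc, tb):
                manifest.timings_s[name] = round(
                    time.perf_counter() - self_inner.t0, 3
                )
                if exc is not None:
                    raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc
        return _Timer()

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        with stage("simulate"):
            session = synth.simulate_session(config)
            synth.write_session(session, outdir)
        with stage("analyze"):
            res = analyze_session(session, thresholds, alpha)
        with stage("write"):
            res["zmatrix"].to_csv(outdir / "traces_zscore.csv")
            bouts_to_frame(res["bouts"]).to_csv(outdir / "bouts.csv", index=False)
            profiles_to_frame(res["profiles"]).to_csv(
                outdir / "cell_profiles.csv", index=False, float_format="%.10g"
            )
            cellclass.summarize_fractions(
                res["profiles"], config.genotype
            ).to_csv(outdir / "category_fractions.csv", index=False)
            cellclass.composition_table(res["profiles"]).to_frame().to_csv(
                outdir / "composition_table.csv", index=False
            )
            peaks.peaks_to_frame(
                res["peak_trains"], config.frame_rate_hz
            ).to_csv(outdir / "peaks.csv", index=False, float_format="%.10g")
            res["peak_stats"].to_csv(
                outdir / "peak_stats_by_state.csv", index=False, float_format="%.10g"
            )
            table, anova = synchrony.state_summary({config.genotype: res["synchrony"]})
            table.to_csv(outdir / "synchrony_state_summary.csv", index=False,
                         float_format="%.10g")
            centroids = {t.cell_id: t.centroid_xy for t in session.tunings}
            edge_frames = []
            for r in res["synchrony"]:
                lab = r.bout.effective_label
                if lab in ("EC", "SC", "HAW"):
                    df = synchrony.edges_to_frame(
                        synchrony.connectivity_map(r, centroids)
                    )
                    df.insert(0, "bout_state", lab)
                    df.insert(1, "bout_start_epoch", r.bout.start_epoch)
                    edge_frames.append(df)
            if edge_frames:
                pd.concat(edge_frames).to_csv(
                    outdir / "connectivity_edges.csv", index=False,
                    float_format="%.10g"
                )
            for name, prof in res["transitions"].items():
                transitions.profile_to_frame(prof).to_csv(
                    outdir / f"transition_profile_{name}.csv", index=False,
                    float_format="%.10g"
                )
        with stage("report"):
            report = build_report(res, config)
            (outdir / "report.md").write_text(report)

    manifest.warnings = sorted({str(w.message) for w in caught})
    for p in sorted(outdir.glob("*")):
        if p.name == "manifest.json" or p.is_dir():
            continue
        manifest.outputs[p.name] = {"path": str(p), "sha256": _sha256(p)}
    manifest.to_json(outdir / "manifest.json")
    return manifest


def build_report(res: dict, config: synth.SessionConfig) -> str:
    """Markdown summary: cell counts, composition, Z_R table, durations."""
    profiles = res["profiles"]
    lines = [
        "# Session report",
        "",
        f"- genotype: {config.genotype}",
        f"- cells: {len(profiles)}",
        f"- duration: {config.duration_s:.0f} s, seed {config.seed}",
        "",
        "## Cell categories",
        "",
        cellclass.summarize_fractions(profiles, config.genotype).to_markdown(index=False),
        "",
        "## HAW-ON / EC-ON composition",
        "",
        cellclass.composition_table(profiles).to_frame().to_markdown(index=False),
        "",
        "## Synchrony by state (mean positive Z_R per bout)",
        "",
    ]
    table, _ = synchrony.state_summary({config.genotype: res["synchrony"]})
    lines.append(table.to_markdown(index=False))
    dur = res["durations"]
    lines += ["", "## Cataplexy bout durations (s)", ""]
    for lab, vals in dur.durations_by_label.items():
        mean = dur.mean_by_label[lab]
        lines.append(
            f"- {lab}: n={len(vals)}, mean={mean:.1f} s, sem={dur.sem_by_label[lab]:.2f}"
            if vals else f"- {lab}: none observed"
        )
    if dur.anova is not None:
        lines.append(
            f"- SC vs EC one-way ANOVA: F={dur.anova.F:.3f}, p={dur.anova.p:.4f}"
        )
    lines.append("")
    return "\n".join(lines)


def aggregate_fraction_tables(tables: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Pool per-session category counts (multi-mouse aggregation); percentages
    are recomputed from the pooled counts."""
    df = pd.concat(tables)
    out = (
        df.groupby("category", sort=False)
        .agg(count=("count", "sum"))
        .reset_index()
    )
    # each session reports the same total on every row; pool across sessions
    total = int(df.groupby("category")["total"].sum().iloc[0])
    out["total"] = total
    out["percent"] = [percent(int(c), total) for c in out["count"]]
    return out
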