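"""End-to-end pipeline driver: trajectory CSVs + arena -> ethograms,
event tables, per-fly metrics, population summaries, manifest."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import io as ffio
from .arena import Arena
from .ethogram import EthogramLabels, classify_activity
from .events import segment_events
from .kinematics import RawTrack, SmoothTrack, qc_track, smooth_track
from .metrics import compute_fly_metrics, population_metrics

log = logging.getLogger("flyforage")


@dataclass
class FlyResult:
    fly_id: str
    track: SmoothTrack
    labels: EthogramLabels
    encounters: list
    micromovements: list
    visits: list
    metrics: dict


def analyze_track(
    raw: RawTrack, arena: Arena, config: ffio.RunConfig | None = None,
    fly_id: str = "fly",
) -> FlyResult:
    """Classify, segment, and score one fly."""
    config = config or ffio.RunConfig()
    smooth = smooth_track(raw)
    labels = classify_activity(smooth, config.thresholds)
    enc, mms, vis = segment_events(smooth, labels, arena, config.event_thresholds)
    row = compute_fly_metrics(
        smooth, labels, enc, mms, vis, arena, th=config.event_thresholds
    )
    row["fly_id"] = fly_id
    return FlyResult(fly_id, smooth, labels, enc, mms, vis, row)


def run_pipeline(
    trajectory_paths: list,
    arena: Arena,
    out_dir,
    config: ffio.RunConfig | None = None,
    conditions: dict | None = None,
) -> pd.DataFrame:
    """Run the full pipeline over a set of trajectory CSVs.

    QC-failed flies are excluded from analysis and listed in the manifest.
    Returns the per-fly metrics table; all declared CSV outputs plus a
    manifest JSON are written under ``out_dir``.
    """
    config = config or ffio.RunConfig()
    trajectory_paths = [Path(p) for p in trajectory_paths]
    if not trajectory_paths:
        raise ValueError("no input trajectories given")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    rows = []
    excluded = []
    for path in trajectory_paths:
        fly_id = path.stem
        raw = ffio.read_trajectory(path, config)
        qc = qc_track(raw)
        if config.qc_enabled and not qc.passed:
            log.info("excluding %s: lost fraction %.3f", fly_id, qc.lost_fraction)
            excluded.append({"fly_id": fly_id, "lost_fraction": qc.lost_fraction})
            continue
        log.info("analyzing %s", fly_id)
        res = analyze_track(raw, arena, config, fly_id)
        ffio.write_ethogram(out / f"{fly_id}_ethogram.csv", res.labels, raw.fps)
        ffio.write_bouts(out / f"{fly_id}_bouts.csv", res.labels, raw.fps)
        ffio.events_to_frame(
            res.encounters, res.micromovements, res.visits, raw.fps
        ).to_csv(out / f"{fly_id}_events.csv", index=False)
        row = dict(res.metrics)
        if conditions:
            row["condition"] = conditions.get(fly_id, "unknown")
        rows.append(row)

    metrics = pd.DataFrame(rows)
    if len(metrics):
        lead = ["fly_id"] + (["condition"] if "condition" in metrics else [])
        metrics = metrics[lead + [c for c in metrics.columns if c not in lead]]
    metrics.to_csv(out / "metrics.csv", index=False, float_format="%.6f")
    if "condition" in metrics.columns and len(metrics):
        population_metrics(metrics).to_csv(
            out / "population.csv", index=False, float_format="%.6f"
        )
    ffio.write_manifest(
        out / "manifest.json",
        config,
        {"n_flies": len(rows), "excluded": excluded},
    )
    return metrics
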