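"""Readers, writers, and run configuration.

Trajectory CSV schema: columns ``frame, time_s, body_x, body_y, head_x,
head_y[, tail_x, tail_y]`` with a mandatory header.  Units are declared via
the config (``units: px|mm``) or per-file by suffixing coordinate columns
with ``_px`` / ``_mm``; pixel inputs are converted once at load.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .arena import Arena
from .ethogram import Thresholds
from .events import EventThresholds
from .kinematics import MAX_LOST_FRACTION, RawTrack


class TrajectoryFormatError(ValueError):
    pass


@dataclass
class RunConfig:
    """Pipeline configuration; defaults equal the published constants."""

    thresholds: Thresholds = field(default_factory=Thresholds)
    event_thresholds: EventThresholds = field(default_factory=EventThresholds)
    units: str = "mm"  # px | mm
    mm_per_px: float = 0.155
    fps: float = 50.0
    max_lost_fraction: float = MAX_LOST_FRACTION
    qc_enabled: bool = True
    non_eater_max_min: float = 1.0
    window_s: float = 300.0
    step_s: float = 240.0
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "thresholds" in d and isinstance(d["thresholds"], dict):
            d["thresholds"] = Thresholds(**d["thresholds"])
        if "event_thresholds" in d and isinstance(d["event_thresholds"], dict):
            d["event_thresholds"] = EventThresholds(**d["event_thresholds"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


_BASE_COLS = ("body_x", "body_y", "head_x", "head_y")


def read_trajectory(path, config: RunConfig | None = None) -> RawTrack:
    """Read a trajectory CSV into a RawTrack in mm."""
    config = config or RunConfig()
    df = pd.read_csv(path)
    cols = set(df.columns)

    # per-file unit suffixes override the config flag
    units = None
    suffix = ""
    if {c + "_px" for c in _BASE_COLS} <= cols:
        units, suffix = "px", "_px"
    elif {c + "_mm" for c in _BASE_COLS} <= cols:
        units, suffix = "mm", "_mm"
    elif set(_BASE_COLS) <= cols:
        units = config.units
    else:
        missing = [c for c in _BASE_COLS if c not in cols]
        raise TrajectoryFormatError(f"{path}: missing mandatory columns {missing}")
    if "frame" not in cols:
        raise TrajectoryFormatError(f"{path}: missing 'frame' column")

    frames = df["frame"].to_numpy(int)
    if np.any(np.diff(frames) <= 0):
        bad = int(np.nonzero(np.diff(frames) <= 0)[0][0]) + 2  # 1-based data row
        raise TrajectoryFormatError(
            f"{path}: frames not strictly increasing at row {bad}"
        )

    scale = config.mm_per_px if units == "px" else 1.0

    def get(name):
        col = name + suffix
        return df[col].to_numpy(float) * scale if col in cols else None

    body = np.column_stack([get("body_x"), get("body_y")])
    head = np.column_stack([get("head_x"), get("head_y")])
    tail = None
    if {"tail_x" + suffix, "tail_y" + suffix} <= cols:
        tail = np.column_stack([get("tail_x"), get("tail_y")])
    time = (
        df["time_s"].to_numpy(float) if "time_s" in cols else frames / config.fps
    )
    return RawTrack(
        frame=frames, time=time, body=body, head=head, tail=tail, fps=config.fps
    )


def write_trajectory(path, track: RawTrack) -> None:
    df = pd.DataFrame(
        {
            "frame": track.frame,
            "time_s": track.time,
            "body_x": track.body[:, 0],
            "body_y": track.body[:, 1],
            "head_x": track.head[:, 0],
            "head_y": track.head[:, 1],
        }
    )
    if track.tail is not None:
        df["tail_x"] = track.tail[:, 0]
        df["tail_y"] = track.tail[:, 1]
    df.to_csv(path, index=False, float_format="%.6f")


def write_ethogram(path, labels, fps: float) -> None:
    pd.DataFrame(
        {
            "frame": np.arange(len(labels)),
            "label": labels.label_names(),
            "sharp_turn": labels.sharp_turn.astype(int),
        }
    ).to_csv(path, index=False)


def write_bouts(path, labels, fps: float) -> None:
    pd.DataFrame(
        [
            {
                "label": name,
                "start_frame": s,
                "end_frame": e,
                "duration_s": (e - s) / fps,
            }
            for name, s, e in labels.bouts
        ]
    ).to_csv(path, index=False)


def events_to_frame(encounters, micromovements, visits, fps: float) -> pd.DataFrame:
    rows = []
    for kind, evs in (
        ("encounter", encounters),
        ("micromovement", micromovements),
        ("visit", visits),
    ):
        for ev in evs:
            row = {
                "kind": kind,
                "patch_id": ev.patch_id,
                "substrate": ev.substrate,
                "start_frame": ev.start,
                "end_frame": ev.end,
                "duration_s": ev.duration_s(fps),
            }
            row["min_dist_mm"] = getattr(ev, "min_dist_mm", np.nan)
            rows.append(row)
    return pd.DataFrame(rows)


def write_manifest(path, config: RunConfig, extra: dict | None = None) -> None:
    import flyforage

    manifest = {
        "config_hash": config.config_hash(),
        "config": config.to_dict(),
        "version": flyforage.__version__,
        "seed": config.seed,
    }
    manifest.update(extra or {})
    Path(path).write_text(json.dumps(manifest, indent=2, default=str) + "\n")
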