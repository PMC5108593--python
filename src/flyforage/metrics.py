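"""Per-fly exploitation / exploration / locomotion parameters, transition
classification, and yeast-quartile dynamics.

Durations are reported in minutes (frames / fps / 60).  Undefined ratios
(zero encounters, zero visits, censored latency) propagate as NaN, never as
zeros, and are excluded pairwise from group statistics downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .arena import Arena, distances_to_patches
from .ethogram import WALK, EthogramLabels
from .events import (
    Encounter,
    EventThresholds,
    FoodMicromovement,
    Visit,
    latency_to_first_long_visit,
)
from .kinematics import SmoothTrack

#: Head-excursion / center-distance threshold for transition classes (mm).
TRANSITION_MM = 16.0

SAME = "same"
ADJACENT = "adjacent"
DISTANT = "distant"


@dataclass
class TransitionRecord:
    from_patch: int
    to_patch: int
    kind: str  # same | adjacent | distant
    path_length_mm: float
    max_excursion_mm: float  # max head distance from previous patch center


def _total_min(intervals, fps: float) -> float:
    return sum(iv.end - iv.start for iv in intervals) / fps / 60.0


def micromovement_metrics(
    micromovements: list[FoodMicromovement],
    substrate: str,
    fps: float,
    n_frames: int,
) -> dict:
    """Totals and the per-frame cumulative curve for one substrate.

    Returns total duration (min), event count, and the cumulative yeast-time
    curve in minutes sampled every frame.
    """
    mms = [m for m in micromovements if m.substrate == substrate]
    mask = np.zeros(n_frames, dtype=bool)
    for m in mms:
        mask[m.start : m.end] = True
    cumulative = np.cumsum(mask) / fps / 60.0
    return {
        "total_min": _total_min(mms, fps),
        "count": len(mms),
        "cumulative_min": cumulative,
    }


def time_walking_outside_min(
    labels: EthogramLabels,
    track: SmoothTrack,
    arena: Arena,
    outside_mm: float = 2.5,
) -> float:
    """Minutes spent walking with the head farther than ``outside_mm`` from
    every patch center."""
    dists = distances_to_patches(track.head, arena)
    with np.errstate(invalid="ignore"):
        outside = np.all(dists > outside_mm, axis=1)
    return float(np.sum(labels.frames_of(WALK) & outside)) / track.fps / 60.0


def encounter_metrics(
    encounters: list[Encounter],
    micromovements: list[FoodMicromovement],
    labels: EthogramLabels,
    track: SmoothTrack,
    arena: Arena,
    substrate: str = "yeast",
) -> dict:
    """Approach and stop decisions: encounter count, encounter rate per
    minute of walking outside the patches, and P(stop).

    P(stop) = encounters containing at least one food micromovement divided
    by the total encounter count; NaN when there are no encounters.
    """
    encs = [e for e in encounters if e.substrate == substrate]
    mms = [m for m in micromovements if m.substrate == substrate]
    walking_min = time_walking_outside_min(labels, track, arena)
    n = len(encs)
    if n == 0:
        return {"n_encounters": 0, "rate_per_min": 0.0, "p_stop": np.nan}
    stopped = sum(
        any(
            m.patch_id == e.patch_id and m.start >= e.start and m.end <= e.end
            for m in mms
        )
        for e in encs
    )
    rate = n / walking_min if walking_min > 0 else np.nan
    return {"n_encounters": n, "rate_per_min": rate, "p_stop": stopped / n}


def visit_metrics(
    visits: list[Visit], track: SmoothTrack, substrate: str = "yeast"
) -> dict:
    """Exploitation measures over one substrate's visits.

    Includes the mean per-visit minimum head-to-center distance, the mean
    per-visit head-covered area (0.155 mm grid cells), and the mean
    1.2 s-filtered body speed and mean |angular speed| over in-visit frames.
    """
    vs = [v for v in visits if v.substrate == substrate]
    fps = track.fps
    if not vs:
        return {
            "n_visits": 0,
            "total_min": 0.0,
            "avg_min": np.nan,
            "avg_min_dist_mm": np.nan,
            "avg_area_cells": np.nan,
            "body_speed_mm_s": np.nan,
            "angular_speed_deg_s": np.nan,
        }
    durations = [v.duration_s(fps) / 60.0 for v in vs]
    in_visit = np.zeros(len(track), dtype=bool)
    for v in vs:
        in_visit[v.start : v.end] = True
    return {
        "n_visits": len(vs),
        "total_min": float(np.sum(durations)),
        "avg_min": float(np.mean(durations)),
        "avg_min_dist_mm": float(np.mean([v.min_dist_mm for v in vs])),
        "avg_area_cells": float(np.mean([v.area_cells for v in vs])),
        "body_speed_mm_s": float(np.nanmean(track.body_speed_smooth[in_visit])),
        "angular_speed_deg_s": float(
            np.nanmean(np.abs(track.angular_speed[in_visit]))
        ),
    }


def speed_outside_visits(
    visits: list[Visit], track: SmoothTrack, end_frame: int | None = None
) -> float:
    """Mean 1.2 s-filtered body speed over frames not inside any food visit
    (both substrates), optionally restricted to frames before ``end_frame``."""
    n = len(track) if end_frame is None else min(end_frame, len(track))
    outside = np.ones(n, dtype=bool)
    for v in visits:
        outside[min(v.start, n) : min(v.end, n)] = False
    if not outside.any():
        return np.nan
    return float(np.nanmean(track.body_speed_smooth[:n][outside]))


def sliding_window_visit_duration(
    visits: list[Visit],
    fps: float,
    assay_s: float,
    substrate: str = "yeast",
    window_s: float = 300.0,
    step_s: float = 240.0,
) -> pd.DataFrame:
    """Summed visit∩window overlap (s) for a sliding window.

    Visits overlapping a window boundary contribute only their overlap, so
    the series is interpretable under window tiling.  Returns a frame with
    ``t_start_s``, ``t_end_s``, ``visit_s`` columns.
    """
    vs = [(v.start / fps, v.end / fps) for v in visits if v.substrate == substrate]
    rows = []
    t = 0.0
    while t < assay_s:
        hi = min(t + window_s, assay_s)
        total = sum(max(0.0, min(e, hi) - max(s, t)) for s, e in vs)
        rows.append({"t_start_s": t, "t_end_s": hi, "visit_s": total})
        t += step_s
    return pd.DataFrame(rows)


def classify_transitions(
    visits: list[Visit],
    track: SmoothTrack,
    arena: Arena,
    substrate: str = "yeast",
) -> tuple[list[TransitionRecord], dict]:
    """Classify consecutive same-substrate visit pairs as same / adjacent /
    distant using the 16 mm center-distance and head-excursion rules.

    same: same patch and the head stayed <= 16 mm from its center throughout
    the inter-visit interval; adjacent: different patches with centers
    <= 16 mm apart and the head stayed <= 16 mm from the previous center;
    distant: everything else.  Probabilities are class counts over the total
    number of transitions; NaN when fewer than two visits exist.
    """
    vs = sorted(
        (v for v in visits if v.substrate == substrate), key=lambda v: v.start
    )
    centers = {p.id: np.asarray(p.center) for p in arena.patches}
    col = {p.id: k for k, p in enumerate(arena.patches)}
    dists = distances_to_patches(track.head, arena)

    records: list[TransitionRecord] = []
    for prev, cur in zip(vs, vs[1:]):
        gap = slice(prev.end, cur.start)
        exc_seg = dists[gap, col[prev.patch_id]]
        excursion = float(exc_seg.max()) if exc_seg.size else 0.0
        seg = track.head[prev.end : cur.start + 1]
        path = (
            float(np.sum(np.linalg.norm(np.diff(seg, axis=0), axis=1)))
            if len(seg) > 1
            else 0.0
        )
        center_d = float(
            np.linalg.norm(centers[prev.patch_id] - centers[cur.patch_id])
        )
        if excursion > TRANSITION_MM or (
            prev.patch_id != cur.patch_id and center_d > TRANSITION_MM
        ):
            kind = DISTANT
        elif prev.patch_id == cur.patch_id:
            kind = SAME
        else:
            kind = ADJACENT
        records.append(
            TransitionRecord(prev.patch_id, cur.patch_id, kind, path, excursion)
        )

    if not records:
        probs = {SAME: np.nan, ADJACENT: np.nan, DISTANT: np.nan}
    else:
        n = len(records)
        probs = {
            k: sum(r.kind == k for r in records) / n for k in (SAME, ADJACENT, DISTANT)
        }
    return records, probs


def scale_probs_to_100(medians: dict) -> dict:
    """Rescale median transition probabilities so they sum to 100 (pie-chart
    convention)."""
    total = sum(medians.values())
    if not np.isfinite(total) or total <= 0:
        return {k: np.nan for k in medians}
    return {k: 100.0 * v / total for k, v in medians.items()}


def distance_to_next_yeast_visit(
    visits: list[Visit], track: SmoothTrack, substrate: str = "yeast"
) -> float:
    """Mean path length (mm) from the end of any visit to the start of the
    next ``substrate`` visit, summed over smoothed-head displacements."""
    vs = sorted(visits, key=lambda v: v.start)
    lengths = []
    for i, v in enumerate(vs[1:], start=1):
        if v.substrate != substrate:
            continue
        prev = vs[i - 1]
        seg = track.head[prev.end : v.start + 1]
        if len(seg) > 1:
            lengths.append(float(np.sum(np.linalg.norm(np.diff(seg, axis=0), axis=1))))
        else:
            lengths.append(0.0)
    return float(np.mean(lengths)) if lengths else np.nan


@dataclass
class QuartileBounds:
    """Four contiguous absolute-time windows, anchored at the latency point,
    each holding 25% of the cumulative post-latency yeast-micromovement
    time.  Frame spans are half-open."""

    windows: list[tuple[int, int]]  # 4 half-open frame spans

    def __iter__(self):
        return iter(self.windows)


def yeast_quartiles(
    micromovements: list[FoodMicromovement],
    latency_s: float,
    track: SmoothTrack,
    substrate: str = "yeast",
) -> QuartileBounds:
    """Split post-latency time into four windows each containing 25% (±1
    frame) of the cumulative yeast-micromovement time."""
    fps = track.fps
    n = len(track)
    lat_frame = int(round(latency_s * fps))
    mask = np.zeros(n, dtype=bool)
    for m in micromovements:
        if m.substrate == substrate:
            mask[m.start : m.end] = True
    mask[:lat_frame] = False
    total = int(mask.sum())
    if total < 4:
        raise ValueError("need at least 4 frames of yeast micromovement after latency")
    cum = np.cumsum(mask)
    bounds = [lat_frame]
    for q in (1, 2, 3, 4):
        target = q * total / 4.0
        idx = int(np.searchsorted(cum, target))
        bounds.append(min(idx + 1, n))
    windows = [(bounds[i], bounds[i + 1]) for i in range(4)]
    return QuartileBounds(windows=windows)


def _clip_intervals(intervals, start: int, end: int):
    """Clip events to a window, keeping only the overlapping parts."""
    out = []
    for iv in intervals:
        s, e = max(iv.start, start), min(iv.end, end)
        if s < e:
            c = type(iv)(iv.patch_id, iv.substrate, s, e)
            if isinstance(iv, Visit):
                c.min_dist_mm = iv.min_dist_mm
                c.area_cells = iv.area_cells
            out.append(c)
    return out


def quartile_metrics(
    bounds: QuartileBounds,
    visits: list[Visit],
    track: SmoothTrack,
    arena: Arena,
    substrate: str = "yeast",
) -> pd.DataFrame:
    """Recompute key exploitation/exploration metrics within each quartile
    window (events clipped to the window)."""
    rows = []
    for q, (s, e) in enumerate(bounds, start=1):
        vs = _clip_intervals(visits, s, e)
        vm = visit_metrics(vs, track, substrate)
        _, probs = classify_transitions(vs, track, arena, substrate)
        rows.append(
            {
                "quartile": q,
                "start_frame": s,
                "end_frame": e,
                "span_min": (e - s) / track.fps / 60.0,
                "n_visits": vm["n_visits"],
                "total_visit_min": vm["total_min"],
                "avg_visit_min": vm["avg_min"],
                "avg_min_dist_mm": vm["avg_min_dist_mm"],
                "angular_speed_deg_s": vm["angular_speed_deg_s"],
                "p_same": probs[SAME],
                "p_adjacent": probs[ADJACENT],
                "p_distant": probs[DISTANT],
            }
        )
    return pd.DataFrame(rows)


def population_metrics(per_fly: pd.DataFrame, condition_col: str = "condition") -> pd.DataFrame:
    """Per-condition fraction of yeast non-eaters (total yeast visit time
    < 1 min) and coefficient of variation of total yeast micromovement time."""
    rows = []
    for cond, grp in per_fly.groupby(condition_col):
        totals = grp["yeast_total_micromove_min"].to_numpy(float)
        visit_totals = grp["yeast_total_visit_min"].to_numpy(float)
        mean = np.nanmean(totals)
        cv = float(np.nanstd(totals, ddof=1) / mean) if mean > 0 else np.nan
        rows.append(
            {
                condition_col: cond,
                "n_flies": len(grp),
                "fraction_non_eaters": float(np.mean(visit_totals < 1.0)),
                "cv_micromovement_total": cv,
            }
        )
    return pd.DataFrame(rows)


def compute_fly_metrics(
    track: SmoothTrack,
    labels: EthogramLabels,
    encounters: list[Encounter],
    micromovements: list[FoodMicromovement],
    visits: list[Visit],
    arena: Arena,
    assay_s: float | None = None,
    th: EventThresholds | None = None,
) -> dict:
    """Assemble the full per-fly parameter row (one value per parameter)."""
    th = th or EventThresholds()
    fps = track.fps
    n = len(track)
    assay_s = assay_s if assay_s is not None else n / fps

    row: dict = {}
    for sub in ("yeast", "sucrose"):
        mm = micromovement_metrics(micromovements, sub, fps, n)
        vm = visit_metrics(visits, track, sub)
        row[f"{sub}_total_micromove_min"] = mm["total_min"]
        row[f"{sub}_n_micromovements"] = mm["count"]
        row[f"{sub}_total_visit_min"] = vm["total_min"]
        row[f"{sub}_n_visits"] = vm["n_visits"]
        row[f"{sub}_avg_visit_min"] = vm["avg_min"]

    em = encounter_metrics(encounters, micromovements, labels, track, arena, "yeast")
    row["yeast_n_encounters"] = em["n_encounters"]
    row["yeast_encounter_rate_per_min"] = em["rate_per_min"]
    row["yeast_p_stop"] = em["p_stop"]

    vm = visit_metrics(visits, track, "yeast")
    row["yeast_avg_min_dist_mm"] = vm["avg_min_dist_mm"]
    row["yeast_avg_area_cells"] = vm["avg_area_cells"]
    row["yeast_visit_body_speed_mm_s"] = vm["body_speed_mm_s"]
    row["yeast_visit_angular_speed_deg_s"] = vm["angular_speed_deg_s"]

    lat_s, censored = latency_to_first_long_visit(
        visits, "yeast", fps, assay_s, th.long_visit_min
    )
    row["latency_long_yeast_visit_min"] = lat_s / 60.0
    row["latency_censored"] = censored

    _, probs = classify_transitions(visits, track, arena, "yeast")
    row["p_same"] = probs[SAME]
    row["p_adjacent"] = probs[ADJACENT]
    row["p_distant"] = probs[DISTANT]

    row["dist_to_next_yeast_visit_mm"] = distance_to_next_yeast_visit(visits, track)
    row["speed_outside_mm_s"] = speed_outside_visits(visits, track)
    return row
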