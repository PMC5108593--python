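"""Patch-level event segmentation: encounters, food micromovements, visits.

All intervals are half-open ``[start, end)`` in frames; durations are
``(end - start) / fps``.  Distance tests use the smoothed head channel.

Rules, in brief:

* encounter — head within 3 mm of a patch center, with two merge rules for
  interruptions: total head displacement during the gap <= 0.31 mm (2 px),
  or head distance to that patch center never exceeding 5 mm during the gap;
* food micromovement — micromovement-labeled frames with the head within
  2.5 mm of a patch center, interruptions merged by the 0.31 mm rule;
* visit — consecutive same-patch food micromovements whose gaps keep the
  head within 5 mm of the patch center.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .arena import Arena, distances_to_patches
from .ethogram import MICROMOVEMENT, EthogramLabels
from .kinematics import SmoothTrack


@dataclass(frozen=True)
class EventThresholds:
    encounter_radius: float = 3.0  # mm
    micromove_radius: float = 2.5  # mm
    visit_merge_radius: float = 5.0  # mm
    displacement_merge: float = 0.31  # mm (2 px)
    long_visit_min: float = 30.0  # s

    def __post_init__(self) -> None:
        if not (
            self.micromove_radius < self.encounter_radius < self.visit_merge_radius
        ):
            raise ValueError(
                "need micromove_radius < encounter_radius < visit_merge_radius"
            )


@dataclass
class PatchInterval:
    """A half-open frame interval bound to one patch."""

    patch_id: int
    substrate: str
    start: int
    end: int

    def duration_s(self, fps: float) -> float:
        return (self.end - self.start) / fps


@dataclass
class Encounter(PatchInterval):
    pass


@dataclass
class FoodMicromovement(PatchInterval):
    pass


@dataclass
class Visit(PatchInterval):
    micromovements: list[FoodMicromovement] = field(default_factory=list)
    min_dist_mm: float = np.nan
    area_cells: int = 0


def _intervals_from_mask(mask: np.ndarray) -> list[tuple[int, int]]:
    m = np.asarray(mask, bool).astype(int)
    if m.size == 0:
        return []
    d = np.diff(m)
    starts = (np.nonzero(d == 1)[0] + 1).tolist()
    ends = (np.nonzero(d == -1)[0] + 1).tolist()
    if m[0]:
        starts.insert(0, 0)
    if m[-1]:
        ends.append(len(m))
    return list(zip(starts, ends))


def _gap_displacement_ok(head: np.ndarray, gap: slice, tol: float) -> bool:
    """2-px rule: every head position in the gap stays within ``tol`` of the
    gap's first head position (strictest reading of 'total displacement')."""
    seg = head[gap]
    if len(seg) == 0:
        return True
    return bool(np.max(np.linalg.norm(seg - seg[0], axis=1)) <= tol)


def _merge_intervals(
    intervals: list[tuple[int, int]],
    head: np.ndarray,
    dist_to_patch: np.ndarray,
    th: EventThresholds,
    use_5mm: bool,
) -> list[tuple[int, int]]:
    """Left-to-right merge of same-patch intervals, applying the 2-px rule
    and (optionally) the 5 mm proximity rule to each gap, to fixpoint."""
    merged: list[tuple[int, int]] = []
    for s, e in intervals:
        if merged:
            ps, pe = merged[-1]
            gap = slice(pe, s)
            ok = _gap_displacement_ok(head, gap, th.displacement_merge)
            if not ok and use_5mm:
                ok = bool(np.all(dist_to_patch[gap] <= th.visit_merge_radius))
            if ok:
                merged[-1] = (ps, e)
                continue
        merged.append((s, e))
    return merged


def detect_encounters(
    track: SmoothTrack, arena: Arena, th: EventThresholds | None = None
) -> list[Encounter]:
    """Intervals where the head is within 3 mm of a patch center, merged by
    the 2-px and 5 mm rules.  Never merges across different patches."""
    th = th or EventThresholds()
    dists = distances_to_patches(track.head, arena)
    out: list[Encounter] = []
    for k, patch in enumerate(arena.patches):
        with np.errstate(invalid="ignore"):
            inside = dists[:, k] <= th.encounter_radius
        raw = _intervals_from_mask(inside)
        for s, e in _merge_intervals(raw, track.head, dists[:, k], th, use_5mm=True):
            out.append(Encounter(patch.id, patch.substrate, s, e))
    out.sort(key=lambda ev: (ev.start, ev.patch_id))
    return out


def detect_food_micromovements(
    labels: EthogramLabels,
    track: SmoothTrack,
    arena: Arena,
    th: EventThresholds | None = None,
) -> list[FoodMicromovement]:
    """Micromovement-labeled frames with the head within 2.5 mm of a patch
    center; interruptions merged by the 2-px displacement rule."""
    th = th or EventThresholds()
    if len(labels) != len(track):
        raise ValueError("labels and track must be aligned")
    dists = distances_to_patches(track.head, arena)
    with np.errstate(invalid="ignore"):
        near = dists <= th.micromove_radius
    if np.any(near.sum(axis=1) > 1):
        raise AssertionError(
            "head within 2.5 mm of two patches at once — arena spacing violated"
        )
    micro = labels.frames_of(MICROMOVEMENT)
    out: list[FoodMicromovement] = []
    for k, patch in enumerate(arena.patches):
        raw = _intervals_from_mask(micro & near[:, k])
        for s, e in _merge_intervals(raw, track.head, dists[:, k], th, use_5mm=False):
            out.append(FoodMicromovement(patch.id, patch.substrate, s, e))
    out.sort(key=lambda ev: (ev.start, ev.patch_id))
    return out


def build_visits(
    micromovements: list[FoodMicromovement],
    track: SmoothTrack,
    arena: Arena,
    th: EventThresholds | None = None,
) -> list[Visit]:
    """Merge consecutive same-patch food micromovements into visits when the
    head stays within 5 mm of the patch center throughout each gap."""
    th = th or EventThresholds()
    dists = distances_to_patches(track.head, arena)
    patch_col = {p.id: k for k, p in enumerate(arena.patches)}

    visits: list[Visit] = []
    for mm in sorted(micromovements, key=lambda m: m.start):
        if visits:
            v = visits[-1]
            if v.patch_id == mm.patch_id:
                gap = slice(v.end, mm.start)
                col = patch_col[mm.patch_id]
                if np.all(dists[gap, col] <= th.visit_merge_radius):
                    v.end = mm.end
                    v.micromovements.append(mm)
                    continue
        visits.append(
            Visit(mm.patch_id, mm.substrate, mm.start, mm.end, micromovements=[mm])
        )

    visits.sort(key=lambda v: v.start)
    for v in visits:
        col = patch_col[v.patch_id]
        v.min_dist_mm = float(np.min(dists[v.start : v.end, col]))
        v.area_cells = area_covered(track.head[v.start : v.end], arena.mm_per_px)
    return visits


def area_covered(head: np.ndarray, cell_mm: float = 0.155) -> int:
    """Number of distinct ``cell_mm`` grid cells (arena-origin aligned)
    visited by the head."""
    pts = np.asarray(head, float).reshape(-1, 2)
    pts = pts[np.all(np.isfinite(pts), axis=1)]
    if len(pts) == 0:
        return 0
    cells = np.floor(pts / cell_mm).astype(int)
    return len({(int(x), int(y)) for x, y in cells})


def latency_to_first_long_visit(
    visits: list[Visit],
    substrate: str,
    fps: float,
    assay_s: float,
    min_s: float = 30.0,
) -> tuple[float, bool]:
    """Time (s) from assay start to the first ``substrate`` visit lasting at
    least ``min_s``.  Returns (latency_s, censored); censored latencies are
    reported at the assay end."""
    for v in sorted(visits, key=lambda v: v.start):
        if v.substrate == substrate and v.duration_s(fps) >= min_s:
            return v.start / fps, False
    return assay_s, True


def segment_events(
    track: SmoothTrack,
    labels: EthogramLabels,
    arena: Arena,
    th: EventThresholds | None = None,
) -> tuple[list[Encounter], list[FoodMicromovement], list[Visit]]:
    """Run the full event segmentation for one fly."""
    th = th or EventThresholds()
    enc = detect_encounters(track, arena, th)
    mms = detect_food_micromovements(labels, track, arena, th)
    vis = build_visits(mms, track, arena, th)
    return enc, mms, vis
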