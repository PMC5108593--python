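"""Synthetic forager: a semi-Markov agent producing head/body trajectories
with ground-truth event logs, so every pipeline stage is testable without
external tracking data.

The agent alternates walk / visit / rest bouts, moves by a correlated random
walk with activity-dependent step length and turning noise, targets patches
with a revisit bias and a distance kernel, decides to stop at encountered
patches with a per-substrate probability, and ends visits under a constant
leaving hazard.  Sharp pivots are injected at visit departures so the
sharp-turn detector has true positives.  Everything is deterministic given
the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .arena import Arena, build_standard_arena
from .ethogram import LABEL_CODES
from .kinematics import RawTrack

#: Distance from body centroid to head (and to tail), mm: half a body length.
HEAD_OFFSET_MM = 1.5


@dataclass(frozen=True)
class ForagerParams:
    """Generative parameters of the simulated forager."""

    rest_speed: float = 0.03  # mm/s body jitter while resting
    micro_speed: float = 0.8  # mm/s mean body speed during on-patch micromovement
    walk_speed: float = 10.0  # mm/s mean walking speed
    walk_speed_sd: float = 2.0
    turn_noise_rad: float = 0.08  # per-frame heading noise while walking
    steer_gain: float = 0.35  # fraction of bearing error corrected per frame
    p_stop_yeast: float = 0.5  # P(encounter -> stop), yeast patches
    p_stop_sucrose: float = 0.3
    leave_rate: float = 0.05  # 1/s hazard of ending a visit
    revisit_bias: float = 0.2  # P(next target = just-left patch)
    local_range: float = 20.0  # mm distance kernel for target choice
    yeast_pref: float = 0.5  # substrate weight for target choice
    micro_turn_deg_s: float = 40.0  # heading jiggle rate during visits
    rest_rate: float = 0.03  # 1/s hazard of a rest bout while walking
    rest_mean_s: float = 15.0
    excursion_min_mm: float = 6.0  # post-leave excursion before a revisit
    excursion_max_mm: float = 12.0

    def validate(self) -> None:
        for name in ("p_stop_yeast", "p_stop_sucrose", "revisit_bias", "yeast_pref"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("leave_rate", "rest_rate", "local_range", "walk_speed"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class GroundTruth:
    """Intent log of the simulated fly."""

    labels: np.ndarray  # (n,) int, ethogram LABEL_CODES
    encounters: list[tuple[int, int, bool]] = field(default_factory=list)
    # (frame, patch_id, stopped)
    visits: list[tuple[int, int, int]] = field(default_factory=list)
    # (patch_id, start_frame, end_frame)
    targets: list[tuple[int, int]] = field(default_factory=list)
    # (frame, patch_id)


# agent modes
_WALK, _VISIT, _REST, _PIVOT, _EXCURSION, _PASS = range(6)


def simulate_fly(
    params: ForagerParams,
    arena: Arena | None = None,
    duration_s: float = 7200.0,
    fps: float = 50.0,
    seed: int = 0,
) -> tuple[RawTrack, GroundTruth]:
    """Simulate one fly; returns the raw track (mm) and its ground truth."""
    params.validate()
    arena = arena or build_standard_arena()
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fps))
    dt = 1.0 / fps

    centers = arena.centers
    substrates = arena.substrates
    patch_ids = np.array([p.id for p in arena.patches])
    n_patches = len(patch_ids)
    wall = arena.inner_radius - HEAD_OFFSET_MM

    p_stop = np.where(substrates == "yeast", params.p_stop_yeast, params.p_stop_sucrose)
    sub_w = np.where(substrates == "yeast", params.yeast_pref, 1.0 - params.yeast_pref)
    p_leave = 1.0 - math.exp(-params.leave_rate * dt)
    p_rest = 1.0 - math.exp(-params.rest_rate * dt)

    # pre-drawn per-frame noise
    turn_eta = rng.standard_normal(n)
    speed_eta = rng.standard_normal(n)
    unif = rng.random(n)

    body = np.empty((n, 2))
    heading = np.empty(n)
    gt_labels = np.empty(n, dtype=int)
    gt = GroundTruth(labels=gt_labels)

    def pick_target(current: int | None, allow_same: bool) -> int:
        if (
            allow_same
            and current is not None
            and rng.random() < params.revisit_bias
        ):
            return current
        ref = centers[current] if current is not None else np.array([x, y])
        d = np.linalg.norm(centers - ref, axis=1)
        w = sub_w * np.exp(-d / max(params.local_range, 1e-6))
        if current is not None:
            w = w.copy()
            w[current] = 0.0
        if w.sum() <= 0:
            w = np.ones(n_patches)
            if current is not None:
                w[current] = 0.0
        return int(rng.choice(n_patches, p=w / w.sum()))

    # initial state: off-patch position, walking to a target
    theta0 = rng.uniform(0, 2 * np.pi)
    x, y = 15.0 * math.cos(theta0), 15.0 * math.sin(theta0)
    th = rng.uniform(0, 2 * np.pi)
    mode = _WALK
    target = pick_target(None, allow_same=False)
    gt.targets.append((0, int(patch_ids[target])))
    blocked = np.zeros(n_patches, dtype=bool)
    visit_patch = -1
    visit_start = -1
    rest_until = -1
    pass_patch = -1
    pass_until = -1
    pivot_left = 0
    pivot_dth = 0.0
    excursion_ref = np.zeros(2)
    excursion_goal = 0.0

    micro_turn = math.radians(params.micro_turn_deg_s) * dt

    for i in range(n):
        hx = x + HEAD_OFFSET_MM * math.cos(th)
        hy = y + HEAD_OFFSET_MM * math.sin(th)
        dx = centers[:, 0] - hx
        dy = centers[:, 1] - hy
        head_d = np.hypot(dx, dy)
        blocked &= head_d <= 5.0  # unblock once the head is far enough away

        if mode == _REST:
            speed = abs(params.rest_speed * (1.0 + 0.3 * speed_eta[i]))
            gt_labels[i] = LABEL_CODES["rest"]
            if i >= rest_until:
                mode = _WALK
        elif mode == _PIVOT:
            th += pivot_dth
            speed = 0.5
            gt_labels[i] = LABEL_CODES["micromovement"]
            pivot_left -= 1
            if pivot_left <= 0:
                mode = _EXCURSION if excursion_goal > 0 else _WALK
        elif mode == _VISIT:
            d_center = head_d[visit_patch]
            if d_center > 2.0:
                bearing = math.atan2(
                    centers[visit_patch, 1] - y, centers[visit_patch, 0] - x
                )
                err = (bearing - th + math.pi) % (2 * math.pi) - math.pi
                th += max(-0.15, min(0.15, 0.2 * err))
            else:
                th += micro_turn * turn_eta[i] * 1.5
            speed = abs(params.micro_speed * (1.0 + 0.25 * speed_eta[i]))
            gt_labels[i] = LABEL_CODES["micromovement"]
            if unif[i] < p_leave:
                gt.visits.append((int(patch_ids[visit_patch]), visit_start, i + 1))
                prev = visit_patch
                blocked[prev] = True
                target = pick_target(prev, allow_same=True)
                gt.targets.append((i, int(patch_ids[target])))
                # pivot away, then (for revisits) an excursion before return
                away = math.atan2(y - centers[prev, 1], x - centers[prev, 0])
                pivot_dth = (
                    (away - th + math.pi) % (2 * math.pi) - math.pi
                ) / 12.0
                pivot_left = 12
                if target == prev:
                    excursion_ref = centers[prev].copy()
                    excursion_goal = rng.uniform(
                        params.excursion_min_mm, params.excursion_max_mm
                    )
                else:
                    excursion_goal = 0.0
                visit_patch = -1
                mode = _PIVOT
        elif mode == _PASS:
            # declined encounter: run over the patch before moving on, so
            # the pass registers as a clear (non-stop) encounter
            bearing = math.atan2(
                centers[pass_patch, 1] - y, centers[pass_patch, 0] - x
            )
            err = (bearing - th + math.pi) % (2 * math.pi) - math.pi
            th += max(-0.3, min(0.3, 0.5 * err))
            speed = max(1.0, params.walk_speed + params.walk_speed_sd * speed_eta[i])
            gt_labels[i] = LABEL_CODES["walk"]
            if head_d[pass_patch] < 2.0 or i >= pass_until:
                if pass_patch == target:
                    target = pick_target(pass_patch, allow_same=False)
                    gt.targets.append((i, int(patch_ids[target])))
                mode = _WALK
        else:  # _WALK or _EXCURSION
            if mode == _EXCURSION:
                d_ref = math.hypot(x - excursion_ref[0], y - excursion_ref[1])
                if d_ref >= excursion_goal:
                    mode = _WALK
                    excursion_goal = 0.0
                bearing = math.atan2(y - excursion_ref[1], x - excursion_ref[0])
            else:
                bearing = math.atan2(centers[target, 1] - y, centers[target, 0] - x)
            err = (bearing - th + math.pi) % (2 * math.pi) - math.pi
            th += max(-0.4, min(0.4, params.steer_gain * err))
            th += params.turn_noise_rad * turn_eta[i]
            speed = max(1.0, params.walk_speed + params.walk_speed_sd * speed_eta[i])
            gt_labels[i] = LABEL_CODES["walk"]

            # encounter: head crosses 3 mm of an unblocked patch
            near = np.nonzero((head_d <= 3.0) & ~blocked)[0]
            if near.size:
                k = int(near[np.argmin(head_d[near])])
                stop = unif[i] < p_stop[k]
                gt.encounters.append((i, int(patch_ids[k]), bool(stop)))
                if stop:
                    mode = _VISIT
                    visit_patch = k
                    visit_start = i
                    gt_labels[i] = LABEL_CODES["micromovement"]
                    speed = params.micro_speed
                else:
                    blocked[k] = True
                    mode = _PASS
                    pass_patch = k
                    pass_until = i + int(0.5 * fps)
            elif mode == _WALK and unif[i] < p_rest and np.all(head_d > 5.0):
                mode = _REST
                rest_until = i + max(
                    1, int(rng.exponential(params.rest_mean_s) * fps)
                )

        # wall avoidance: steer back toward the arena center
        r = math.hypot(x, y)
        if r > wall - 1.5:
            inward = math.atan2(-y, -x)
            err = (inward - th + math.pi) % (2 * math.pi) - math.pi
            th += 0.5 * err
        x += speed * dt * math.cos(th)
        y += speed * dt * math.sin(th)
        r = math.hypot(x, y)
        if r > wall:  # hard clamp at the wall
            x *= wall / r
            y *= wall / r
        body[i, 0] = x
        body[i, 1] = y
        heading[i] = th

    if mode == _VISIT:
        gt.visits.append((int(patch_ids[visit_patch]), visit_start, n))

    u = np.column_stack([np.cos(heading), np.sin(heading)])
    head = body + HEAD_OFFSET_MM * u
    tail = body - HEAD_OFFSET_MM * u
    frames = np.arange(n)
    track = RawTrack(
        frame=frames, time=frames / fps, body=body, head=head, tail=tail, fps=fps
    )
    return track, gt


@dataclass(frozen=True)
class ConditionPreset:
    """Named parameter bundle for one internal-state condition."""

    name: str
    params: ForagerParams


def make_presets() -> dict[str, ConditionPreset]:
    """Five internal-state presets (mating x diet).

    Numeric values are documented constants chosen so that exploitation
    rises and global exploration falls with amino-acid challenge: deprived
    presets have higher stop probability, lower leaving rate, higher revisit
    bias, and a smaller targeting range.  Only these orderings are claimed.
    """
    base = ForagerParams()
    table = {
        "virgin_rich": dict(
            p_stop_yeast=0.15, leave_rate=0.15, revisit_bias=0.05,
            local_range=50.0, yeast_pref=0.35,
        ),
        "virgin_suboptimal": dict(
            p_stop_yeast=0.30, leave_rate=0.08, revisit_bias=0.10,
            local_range=40.0, yeast_pref=0.45,
        ),
        "mated_rich": dict(
            p_stop_yeast=0.35, leave_rate=0.07, revisit_bias=0.08,
            local_range=45.0, yeast_pref=0.45,
        ),
        "mated_suboptimal": dict(
            p_stop_yeast=0.60, leave_rate=0.025, revisit_bias=0.25,
            local_range=11.0, yeast_pref=0.60,
        ),
        "mated_aa_deprived": dict(
            p_stop_yeast=0.85, leave_rate=0.008, revisit_bias=0.50,
            local_range=7.0, yeast_pref=0.75,
        ),
    }
    return {
        name: ConditionPreset(name=name, params=replace(base, **kw))
        for name, kw in table.items()
    }


# --------------------------------------------------------------------------
# Handcrafted fixtures with hand-derived expected event tables
# --------------------------------------------------------------------------


def _segments_to_track(segments: list[np.ndarray], fps: float = 50.0) -> RawTrack:
    head = np.vstack(segments)
    frames = np.arange(len(head))
    return RawTrack(
        frame=frames, time=frames / fps, body=head.copy(), head=head.copy(), fps=fps
    )


def _drift(p0, p1, speed: float, fps: float = 50.0) -> np.ndarray:
    """Straight-line motion from p0 to p1 at constant speed."""
    p0, p1 = np.asarray(p0, float), np.asarray(p1, float)
    dist = np.linalg.norm(p1 - p0)
    steps = max(int(round(dist / speed * fps)), 1)
    t = np.linspace(0, 1, steps, endpoint=False)[:, None]
    return p0 + t * (p1 - p0)


def _orbit(
    center, radius: float, speed: float, duration_s: float,
    start_angle: float = 0.0, fps: float = 50.0,
) -> np.ndarray:
    """Circular micromovement-speed orbit around a patch center."""
    nf = int(round(duration_s * fps))
    omega = speed / radius  # rad/s
    t = np.arange(nf) / fps
    ang = start_angle + omega * t
    c = np.asarray(center, float)
    return c + radius * np.column_stack([np.cos(ang), np.sin(ang)])


def fixture_arena() -> Arena:
    """Two-patch arena used by the handcrafted fixtures."""
    from .arena import FoodPatch

    return Arena(
        patches=[
            FoodPatch(id=0, center=(0.0, 0.0), substrate="yeast"),
            FoodPatch(id=1, center=(0.0, 12.0), substrate="sucrose"),
        ]
    )


def fixture_suite() -> dict[str, tuple[RawTrack, Arena, dict]]:
    """Deterministic tracks encoding each rule's edge cases, each with a
    hand-derived expected outcome dict."""
    arena = fixture_arena()
    fps = 50.0
    far = np.array([20.0, 0.0])
    fixtures: dict[str, tuple[RawTrack, Arena, dict]] = {}

    # jitter: slow radial oscillation across the 3 mm threshold -> merge
    # rules keep it one encounter
    t = np.arange(int(20 * fps)) / fps
    rad = 3.0 + 0.15 * np.sin(2 * np.pi * t / 2.0)
    jitter = np.column_stack([rad, np.zeros_like(rad)])
    segs = [
        _drift(far, [3.15, 0.0], 10.0),
        jitter,
        _drift([jitter[-1, 0], 0.0], far, 10.0),
    ]
    fixtures["jitter"] = (
        _segments_to_track(segs),
        arena,
        {"n_encounters": 1},
    )

    # merge-4mm: two 3 mm crossings separated by an excursion to only 4 mm
    # -> merged by the 5 mm rule
    segs = [
        _drift(far, [2.0, 0.0], 10.0),
        _orbit([0, 0], 1.8, 1.0, 6.0),
        _drift([1.8, 0.0], [4.0, 0.0], 10.0),
        _drift([4.0, 0.0], [1.8, 0.0], 10.0),
        _orbit([0, 0], 1.8, 1.0, 6.0),
        _drift([1.8, 0.0], far, 10.0),
    ]
    fixtures["merge-4mm"] = (
        _segments_to_track(segs),
        arena,
        {"n_encounters": 1, "n_visits": 1},
    )

    # split-6mm: same shape but the excursion reaches 6 mm -> two
    # encounters, two visits, and a 'same' transition (excursion <= 16 mm)
    segs = [
        _drift(far, [2.0, 0.0], 10.0),
        _orbit([0, 0], 1.5, 1.0, 12.0),
        _drift([1.5, 0.0], [6.2, 0.0], 10.0),
        _drift([6.2, 0.0], [1.5, 0.0], 10.0),
        _orbit([0, 0], 1.5, 1.0, 12.0),
        _drift([1.5, 0.0], far, 10.0),
    ]
    fixtures["split-6mm"] = (
        _segments_to_track(segs),
        arena,
        {"n_encounters": 2, "n_visits": 2, "transition": "same"},
    )

    # excursion-17mm: revisit after wandering 17 mm from the center
    # -> transition classified distant
    segs = [
        _drift(far, [2.0, 0.0], 10.0),
        _orbit([0, 0], 1.5, 1.0, 12.0),
        _drift([1.5, 0.0], [17.2, 0.0], 10.0),
        _drift([17.2, 0.0], [1.5, 0.0], 10.0),
        _orbit([0, 0], 1.5, 1.0, 12.0),
        _drift([1.5, 0.0], far, 10.0),
    ]
    fixtures["excursion-17mm"] = (
        _segments_to_track(segs),
        arena,
        {"n_visits": 2, "transition": "distant"},
    )

    # latency-30s: a 10 s visit at ~50 s, then a 40 s visit starting near
    # 600 s -> the latency lands at the second visit's start
    hold0 = np.tile(far, (int(46 * fps), 1))
    approach1 = _drift(far, [1.5, 0.0], 10.0)  # ~1.85 s
    v1 = _orbit([0, 0], 1.5, 1.0, 10.0)
    leave1 = _drift([1.5, 0.0], far, 10.0)
    t_used = (len(hold0) + len(approach1) + len(v1) + len(leave1)) / fps
    hold1 = np.tile(far, (int((598.0 - t_used) * fps), 1))
    approach2 = _drift(far, [1.5, 0.0], 10.0)
    v2 = _orbit([0, 0], 1.5, 1.0, 40.0)
    leave2 = _drift([1.5, 0.0], far, 10.0)
    segs = [hold0, approach1, v1, leave1, hold1, approach2, v2, leave2]
    fixtures["latency-30s"] = (
        _segments_to_track(segs),
        arena,
        {"n_visits": 2, "latency_s_range": (595.0, 605.0)},
    )
    return fixtures
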