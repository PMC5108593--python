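"""Trajectory loading, head/tail disambiguation, smoothing, and the speed
channels consumed by the classifier.

Filter widths follow the convention that "width" is the total kernel support
in frames (16, 60, 120 frames at 50 fps for 0.32 / 1.2 / 2.4 s), with
sigma = width / 6 and the kernel truncated to that support and renormalized.
Near the track ends the kernel is renormalized over the available samples, so
constant series map to themselves everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Position smoothing width (s) applied to head/body/tail centroids.
POSITION_SMOOTH_S = 0.32
#: Extra smoothing (s) of head speed for the walk threshold.
WALK_SMOOTH_S = 1.2
#: Extra smoothing (s) of head speed for the rest threshold.
REST_SMOOTH_S = 2.4
#: Body-speed smoothing (s) used for the in-visit body speed channel.
BODY_SMOOTH_S = 1.2
#: QC: tracks with more than this fraction of lost frames are excluded.
MAX_LOST_FRACTION = 0.10
#: Gaps up to this long (s) are linearly interpolated; longer gaps split
#: the track into independently analyzed segments.
MAX_INTERP_GAP_S = 0.5
#: Frame-to-frame body displacement above this (mm) is treated as a jump.
JUMP_MM = 5.0


@dataclass
class RawTrack:
    """Per-frame raw tracking table in mm (convert px inputs at load)."""

    frame: np.ndarray  # (n,) int, strictly increasing, 0-based
    time: np.ndarray  # (n,) s
    body: np.ndarray  # (n, 2) mm; NaN rows = lost frames
    head: np.ndarray | None = None  # (n, 2) mm or None
    tail: np.ndarray | None = None  # (n, 2) mm or None
    fps: float = 50.0

    def __post_init__(self) -> None:
        self.frame = np.asarray(self.frame, dtype=int)
        self.time = np.asarray(self.time, dtype=float)
        self.body = np.asarray(self.body, dtype=float).reshape(-1, 2)
        if self.head is not None:
            self.head = np.asarray(self.head, dtype=float).reshape(-1, 2)
        if self.tail is not None:
            self.tail = np.asarray(self.tail, dtype=float).reshape(-1, 2)
        if len(self.frame) and np.any(np.diff(self.frame) <= 0):
            raise ValueError("frame indices must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def lost_mask(self) -> np.ndarray:
        return ~np.all(np.isfinite(self.body), axis=1)


@dataclass
class QCResult:
    lost_fraction: float
    passed: bool


@dataclass
class SmoothTrack:
    """Smoothed positions plus every derived speed channel (lengths equal)."""

    fps: float
    head: np.ndarray  # (n, 2) mm, 0.32 s smoothed
    body: np.ndarray
    tail: np.ndarray
    head_speed: np.ndarray  # mm/s from smoothed head
    body_speed: np.ndarray  # mm/s from smoothed body
    body_speed_smooth: np.ndarray  # body speed, extra 1.2 s filter
    angular_speed: np.ndarray  # deg/s, signed, from smoothed head/tail
    head_speed_walk: np.ndarray  # head speed, extra 1.2 s filter
    head_speed_rest: np.ndarray  # head speed, extra 2.4 s filter
    tail_reconstructed: bool = False
    segments: list[tuple[int, int]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.head)


def gaussian_kernel(width_s: float, fps: float) -> np.ndarray:
    """Truncated, renormalized Gaussian kernel of total support
    ``round(width_s * fps)`` frames with sigma = support / 6."""
    if width_s <= 0:
        raise ValueError("width_s must be > 0")
    support = max(int(round(width_s * fps)), 1)
    sigma = support / 6.0
    half = (support - 1) / 2.0
    x = np.arange(support) - half
    k = np.exp(-0.5 * (x / sigma) ** 2)
    return k / k.sum()


def gaussian_smooth(series: np.ndarray, width_s: float, fps: float) -> np.ndarray:
    """Gaussian-filter a 1-D series or an (n, d) array column-wise.

    NaN samples carry zero weight; the kernel is renormalized over the
    finite samples under it (edges included).  Output is NaN only where no
    finite sample falls under the kernel.
    """
    arr = np.asarray(series, dtype=float)
    if arr.size == 0:
        raise ValueError("cannot smooth an empty series")
    k = gaussian_kernel(width_s, fps)
    if arr.ndim == 1:
        return _smooth_1d(arr, k)
    return np.column_stack([_smooth_1d(arr[:, j], k) for j in range(arr.shape[1])])


def _smooth_1d(x: np.ndarray, k: np.ndarray) -> np.ndarray:
    finite = np.isfinite(x)
    filled = np.where(finite, x, 0.0)
    num = np.convolve(filled, k, mode="same")
    den = np.convolve(finite.astype(float), k, mode="same")
    with np.errstate(invalid="ignore", divide="ignore"):
        out = num / den
    out[den <= 1e-12] = np.nan
    return out


def compute_speed(positions: np.ndarray, fps: float) -> np.ndarray:
    """Speed per frame: |p[i+1] - p[i]| * fps; the last frame replicates the
    penultimate value so the channel is full length."""
    pos = np.asarray(positions, dtype=float).reshape(-1, 2)
    if len(pos) < 2:
        raise ValueError("need at least 2 frames to compute speed")
    step = np.linalg.norm(np.diff(pos, axis=0), axis=1) * fps
    return np.append(step, step[-1])


def heading_angles(head: np.ndarray, tail: np.ndarray) -> np.ndarray:
    """Heading (deg) of the head-minus-tail vector per frame.  Frames where
    head and tail coincide carry the previous frame's heading forward."""
    v = np.asarray(head, float) - np.asarray(tail, float)
    ang = np.degrees(np.arctan2(v[:, 1], v[:, 0]))
    bad = np.hypot(v[:, 0], v[:, 1]) < 1e-12
    bad |= ~np.isfinite(ang)
    if bad.any():
        ang = ang.copy()
        last = 0.0
        for i in range(len(ang)):
            if bad[i]:
                ang[i] = last
            else:
                last = ang[i]
    return ang


def compute_angular_speed(
    head: np.ndarray, tail: np.ndarray, fps: float
) -> np.ndarray:
    """Signed angular speed (deg/s) of the heading, shortest-arc differenced.

    Per-frame difference is wrapped into (-180, 180] before scaling by fps;
    the last frame replicates the penultimate value.
    """
    ang = heading_angles(head, tail)
    if len(ang) < 2:
        raise ValueError("need at least 2 frames")
    d = np.diff(ang)
    d = (d + 180.0) % 360.0 - 180.0  # wrap to (-180, 180]
    d[d == -180.0] = 180.0
    out = d * fps
    return np.append(out, out[-1])


def qc_track(raw: RawTrack) -> QCResult:
    """Lost-frame QC: pass iff the lost fraction is <= 0.10 (exactly 10%
    passes — the exclusion rule is 'more than 10%')."""
    n = len(raw)
    lost = float(raw.lost_mask.sum()) / n if n else 1.0
    return QCResult(lost_fraction=lost, passed=lost <= MAX_LOST_FRACTION)


def assign_head(
    endpoints_a: np.ndarray,
    endpoints_b: np.ndarray,
    body: np.ndarray,
    jump_frames: set[int] | None = None,
    first_head: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Disambiguate head vs tail from unlabeled body-axis endpoints.

    Within each interval between jumps, the per-frame identity follows a
    proximity rule (the endpoint nearest the previous head is the head);
    the interval labeling is then kept or globally flipped to maximize
    agreement between heading and displacement direction, since flies walk
    forward most of the time.

    Returns (head, tail) arrays.  Intervals with zero net displacement keep
    the proximity labeling.
    """
    a = np.asarray(endpoints_a, float).reshape(-1, 2)
    b = np.asarray(endpoints_b, float).reshape(-1, 2)
    body = np.asarray(body, float).reshape(-1, 2)
    n = len(a)
    jump_frames = jump_frames or set()

    head = np.empty_like(a)
    tail = np.empty_like(a)

    # interval boundaries: a jump at frame i breaks continuity between i-1 and i
    starts = [0] + sorted(f for f in jump_frames if 0 < f < n)
    bounds = list(zip(starts, starts[1:] + [n]))

    for s, e in bounds:
        # proximity propagation within the interval
        if first_head is not None and s == 0:
            prev = np.asarray(first_head, float)
        else:
            prev = a[s]
        choose_a = np.empty(e - s, dtype=bool)
        for i in range(s, e):
            da = np.linalg.norm(a[i] - prev)
            db = np.linalg.norm(b[i] - prev)
            take_a = da <= db
            choose_a[i - s] = take_a
            prev = a[i] if take_a else b[i]
        h = np.where(choose_a[:, None], a[s:e], b[s:e])
        t = np.where(choose_a[:, None], b[s:e], a[s:e])

        # forward-walking correction: flip interval if heading anti-aligns
        # with displacement on the majority of moving frames
        if e - s >= 2:
            disp = np.diff(body[s:e], axis=0)
            moving = np.linalg.norm(disp, axis=1) > 1e-9
            if moving.any():
                hv = (h - t)[:-1]
                dots = np.einsum("ij,ij->i", hv[moving], disp[moving])
                if np.sum(dots > 0) < np.sum(dots < 0):
                    h, t = t, h
        head[s:e], tail[s:e] = h, t
    return head, tail


def detect_jumps(body: np.ndarray, fps: float, jump_mm: float = JUMP_MM) -> set[int]:
    """Frames whose body displacement from the previous frame exceeds
    ``jump_mm`` (about one body length or more)."""
    step = np.linalg.norm(np.diff(np.asarray(body, float), axis=0), axis=1)
    return set((np.nonzero(step > jump_mm)[0] + 1).tolist())


def interpolate_gaps(
    raw: RawTrack, max_gap_s: float = MAX_INTERP_GAP_S
) -> tuple[RawTrack, list[tuple[int, int]]]:
    """Fill lost frames by linear interpolation when the gap is short.

    Gaps no longer than ``max_gap_s`` are interpolated; longer gaps are left
    as NaN and split the track into segments returned as half-open
    (start, end) frame spans to be analyzed independently.
    """
    n = len(raw)
    max_gap = int(round(max_gap_s * raw.fps))
    lost = raw.lost_mask

    def fill(arr: np.ndarray | None) -> np.ndarray | None:
        if arr is None:
            return None
        out = arr.copy()
        idx = np.arange(n)
        for j in range(2):
            col = out[:, j]
            ok = np.isfinite(col)
            if ok.sum() >= 2:
                out[:, j] = np.interp(idx, idx[ok], col[ok])
        return out

    # locate gap runs in the lost mask
    long_gap = np.zeros(n, dtype=bool)
    i = 0
    while i < n:
        if lost[i]:
            j = i
            while j < n and lost[j]:
                j += 1
            if (j - i) > max_gap or i == 0 or j == n:
                long_gap[i:j] = True
            i = j
        else:
            i += 1

    body = fill(raw.body)
    head = fill(raw.head)
    tail = fill(raw.tail)
    for arr in (body, head, tail):
        if arr is not None:
            arr[long_gap] = np.nan

    segments: list[tuple[int, int]] = []
    i = 0
    while i < n:
        if not long_gap[i]:
            j = i
            while j < n and not long_gap[j]:
                j += 1
            segments.append((i, j))
            i = j
        else:
            i += 1

    filled = RawTrack(
        frame=raw.frame, time=raw.time, body=body, head=head, tail=tail, fps=raw.fps
    )
    return filled, segments


def smooth_track(raw: RawTrack) -> SmoothTrack:
    """Build every smoothed channel from a raw track.

    A missing tail is reconstructed by reflecting the head through the body
    (tail = 2*body - head) and flagged in the result.
    """
    if raw.head is None:
        raise ValueError("head channel is required")
    filled, segments = interpolate_gaps(raw)
    fps = raw.fps

    tail_reconstructed = False
    tail_raw = filled.tail
    if tail_raw is None:
        tail_raw = 2.0 * filled.body - filled.head
        tail_reconstructed = True

    head_s = gaussian_smooth(filled.head, POSITION_SMOOTH_S, fps)
    body_s = gaussian_smooth(filled.body, POSITION_SMOOTH_S, fps)
    tail_s = gaussian_smooth(tail_raw, POSITION_SMOOTH_S, fps)

    head_speed = compute_speed(head_s, fps)
    body_speed = compute_speed(body_s, fps)
    angular_speed = compute_angular_speed(head_s, tail_s, fps)

    return SmoothTrack(
        fps=fps,
        head=head_s,
        body=body_s,
        tail=tail_s,
        head_speed=head_speed,
        body_speed=body_speed,
        body_speed_smooth=gaussian_smooth(body_speed, BODY_SMOOTH_S, fps),
        angular_speed=angular_speed,
        head_speed_walk=gaussian_smooth(head_speed, WALK_SMOOTH_S, fps),
        head_speed_rest=gaussian_smooth(head_speed, REST_SMOOTH_S, fps),
        tail_reconstructed=tail_reconstructed,
        segments=segments,
    )
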