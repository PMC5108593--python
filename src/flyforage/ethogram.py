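"""Frame-by-frame activity classification (rest / micromovement / walk)
plus the sharp-turn overlay.

Walk is decided first on the 1.2 s-filtered head speed (> 2 mm/s); among the
remaining non-walking frames, rest uses the 2.4 s-filtered head speed
(<= 0.2 mm/s) and everything else is a micromovement.  Sharp turns are an
overlay flag, not a fourth exclusive label, so the three activity labels
always partition the track.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .kinematics import SmoothTrack

REST = "rest"
MICROMOVEMENT = "micromovement"
WALK = "walk"
LABELS = (REST, MICROMOVEMENT, WALK)

# integer codes used in the label array
LABEL_CODES = {REST: 0, MICROMOVEMENT: 1, WALK: 2}
CODE_LABELS = {v: k for k, v in LABEL_CODES.items()}


@dataclass(frozen=True)
class Thresholds:
    """Speed thresholds for the activity classes and sharp turns.

    ``sharpturn_body_speed_min`` defaults to None (no lower bound) per the
    operational definition; a 2 mm/s lower bound can be switched on.
    """

    rest_max: float = 0.2  # mm/s
    walk_min: float = 2.0  # mm/s
    sharpturn_angular_min: float = 125.0  # deg/s
    sharpturn_body_speed_max: float = 4.0  # mm/s
    sharpturn_body_speed_min: float | None = None  # mm/s, optional gate
    sharpturn_release_frac: float = 0.5  # hysteresis: extent ends below this * min

    def __post_init__(self) -> None:
        if not (self.rest_max < self.walk_min < self.sharpturn_body_speed_max):
            raise ValueError("need rest_max < walk_min < sharpturn_body_speed_max")


@dataclass
class EthogramLabels:
    """Per-frame labels, sharp-turn flag, and the bout table."""

    labels: np.ndarray  # (n,) int codes, see LABEL_CODES
    sharp_turn: np.ndarray  # (n,) bool overlay
    bouts: list[tuple[str, int, int]] = field(default_factory=list)  # half-open

    def __len__(self) -> int:
        return len(self.labels)

    def label_names(self) -> np.ndarray:
        return np.array([CODE_LABELS[c] for c in self.labels])

    def frames_of(self, label: str) -> np.ndarray:
        return self.labels == LABEL_CODES[label]


def runs_of(values: np.ndarray) -> list[tuple[int, int, int]]:
    """Run-length encode an int array into (value, start, end) half-open runs."""
    v = np.asarray(values)
    if len(v) == 0:
        return []
    change = np.nonzero(np.diff(v))[0] + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [len(v)]))
    return [(int(v[s]), int(s), int(e)) for s, e in zip(starts, ends)]


def classify_activity(
    track: SmoothTrack, th: Thresholds | None = None
) -> EthogramLabels:
    """Classify every frame as rest / micromovement / walk and flag sharp
    turns.  Returns labels partitioning the track plus the bout table."""
    th = th or Thresholds()
    walk = track.head_speed_walk > th.walk_min
    rest = ~walk & (track.head_speed_rest <= th.rest_max)
    labels = np.full(len(track), LABEL_CODES[MICROMOVEMENT], dtype=int)
    labels[walk] = LABEL_CODES[WALK]
    labels[rest] = LABEL_CODES[REST]

    _, flag = detect_sharp_turns(
        track.angular_speed, track.body_speed, th
    )
    bouts = [(CODE_LABELS[c], s, e) for c, s, e in runs_of(labels)]
    return EthogramLabels(labels=labels, sharp_turn=flag, bouts=bouts)


def detect_sharp_turns(
    angular_speed: np.ndarray,
    body_speed: np.ndarray,
    th: Thresholds | None = None,
) -> tuple[list[tuple[int, int]], np.ndarray]:
    """Sharp-turn events: strict local maxima of |angular speed| above
    125 deg/s while the body centroid speed is below 4 mm/s at the peak.

    The event extent grows from each peak until |angular speed| falls below
    half the threshold (hysteresis); overlapping extents are merged.
    Returns (events, per-frame flag), events as half-open frame intervals.
    """
    th = th or Thresholds()
    a = np.abs(np.asarray(angular_speed, float))
    b = np.asarray(body_speed, float)
    n = len(a)
    if n == 0:
        return [], np.zeros(0, dtype=bool)

    # strict local maxima (plateau-free; interior frames only)
    peaks = []
    for i in range(1, n - 1):
        if a[i] > a[i - 1] and a[i] > a[i + 1] and a[i] > th.sharpturn_angular_min:
            if b[i] < th.sharpturn_body_speed_max and (
                th.sharpturn_body_speed_min is None
                or b[i] > th.sharpturn_body_speed_min
            ):
                peaks.append(i)

    release = th.sharpturn_release_frac * th.sharpturn_angular_min
    events: list[tuple[int, int]] = []
    for p in peaks:
        s = p
        while s > 0 and a[s - 1] >= release:
            s -= 1
        e = p + 1
        while e < n and a[e] >= release:
            e += 1
        if events and s <= events[-1][1]:
            events[-1] = (events[-1][0], max(events[-1][1], e))
        else:
            events.append((s, e))

    flag = np.zeros(n, dtype=bool)
    for s, e in events:
        flag[s:e] = True
    return events, flag


def bouts_to_labels(bouts: list[tuple[str, int, int]], n: int) -> np.ndarray:
    """Rebuild the per-frame label array from a bout table (round trip)."""
    labels = np.full(n, -1, dtype=int)
    for name, s, e in bouts:
        labels[s:e] = LABEL_CODES[name]
    if np.any(labels < 0):
        raise ValueError("bout table does not tile the track")
    return labels
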