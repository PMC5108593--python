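"""Independent brute-force reimplementations of the classification and
event-segmentation rules, written as literal frame-by-frame walks.  These
stay deliberately naive (python loops, no shared code with the package) so
they can serve as oracles."""

from __future__ import annotations

import numpy as np


def oracle_classify(head_speed_walk, head_speed_rest, rest_max=0.2, walk_min=2.0):
    """Literal per-frame threshold application: walk first, then rest among
    non-walk frames, micromovement otherwise.  Returns string labels."""
    out = []
    for w, r in zip(head_speed_walk, head_speed_rest):
        if w > walk_min:
            out.append("walk")
        elif r <= rest_max:
            out.append("rest")
        else:
            out.append("micromovement")
    return np.array(out)


def _frame_intervals(flags):
    """Scan frames one by one collecting half-open True runs."""
    ivals = []
    start = None
    for i, f in enumerate(flags):
        if f and start is None:
            start = i
        elif not f and start is not None:
            ivals.append((start, i))
            start = None
    if start is not None:
        ivals.append((start, len(flags)))
    return ivals


def _displacement_rule(head, lo, hi, tol):
    """True if every head position in [lo, hi) stays within tol of the
    first head position of the gap."""
    if hi <= lo:
        return True
    ref = head[lo]
    for i in range(lo, hi):
        d = ((head[i, 0] - ref[0]) ** 2 + (head[i, 1] - ref[1]) ** 2) ** 0.5
        if not d <= tol:
            return False
    return True


def _proximity_rule(dist, lo, hi, radius):
    for i in range(lo, hi):
        if not dist[i] <= radius:
            return False
    return True


def oracle_encounters(head, centers, enc_r=3.0, disp=0.31, merge_r=5.0):
    """Per-patch 3 mm crossings merged by the 2-px and 5 mm rules."""
    out = []
    for k in range(len(centers)):
        dist = np.sqrt(((head - centers[k]) ** 2).sum(axis=1))
        ivals = _frame_intervals([d <= enc_r for d in dist])
        merged = []
        for s, e in ivals:
            if merged and (
                _displacement_rule(head, merged[-1][1], s, disp)
                or _proximity_rule(dist, merged[-1][1], s, merge_r)
            ):
                merged[-1] = (merged[-1][0], e)
            else:
                merged.append((s, e))
        out.extend((k, s, e) for s, e in merged)
    return sorted(out, key=lambda t: (t[1], t[0]))


def oracle_food_micromovements(labels, head, centers, micro_r=2.5, disp=0.31):
    """Micromovement-labeled frames within 2.5 mm of a patch, merged by the
    2-px rule."""
    out = []
    micro = labels == "micromovement"
    for k in range(len(centers)):
        dist = np.sqrt(((head - centers[k]) ** 2).sum(axis=1))
        flags = [bool(micro[i]) and dist[i] <= micro_r for i in range(len(head))]
        ivals = _frame_intervals(flags)
        merged = []
        for s, e in ivals:
            if merged and _displacement_rule(head, merged[-1][1], s, disp):
                merged[-1] = (merged[-1][0], e)
            else:
                merged.append((s, e))
        out.extend((k, s, e) for s, e in merged)
    return sorted(out, key=lambda t: (t[1], t[0]))


def oracle_visits(micromovements, head, centers, merge_r=5.0):
    """Consecutive same-patch micromovements merged while the head stays
    within 5 mm of the patch center during each gap."""
    visits = []
    for k, s, e in sorted(micromovements, key=lambda t: t[1]):
        dist = np.sqrt(((head - centers[k]) ** 2).sum(axis=1))
        if (
            visits
            and visits[-1][0] == k
            and _proximity_rule(dist, visits[-1][2], s, merge_r)
        ):
            visits[-1] = (k, visits[-1][1], e)
        else:
            visits.append((k, s, e))
    return visits
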