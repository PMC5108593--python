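import numpy as np
import pandas as pd
import pytest

from conftest import labels_all, labels_from_codes, make_smooth_track

from flyforage.arena import Arena, FoodPatch
from flyforage.ethogram import LABEL_CODES
from flyforage.events import FoodMicromovement, Visit
from flyforage.metrics import (
    ADJACENT,
    DISTANT,
    SAME,
    classify_transitions,
    compute_fly_metrics,
    distance_to_next_yeast_visit,
    encounter_metrics,
    micromovement_metrics,
    population_metrics,
    quartile_metrics,
    scale_probs_to_100,
    sliding_window_visit_duration,
    speed_outside_visits,
    visit_metrics,
    yeast_quartiles,
)

FPS = 50.0


def sec(lo, hi):
    return int(lo * FPS), int(hi * FPS)


def mm_event(patch, substrate, lo_s, hi_s):
    s, e = sec(lo_s, hi_s)
    return FoodMicromovement(patch, substrate, s, e)


def visit(patch, substrate, lo_s, hi_s, min_dist=1.0, area=10):
    s, e = sec(lo_s, hi_s)
    return Visit(patch, substrate, s, e, min_dist_mm=min_dist, area_cells=area)


@pytest.fixture()
def three_patch_arena():
    # yeast 0 and 1 are adjacent (10 mm), yeast 2 is distant (>16 mm)
    return Arena(
        patches=[
            FoodPatch(0, (0.0, 0.0), substrate="yeast"),
            FoodPatch(1, (10.0, 0.0), substrate="yeast"),
            FoodPatch(2, (-20.0, 0.0), substrate="yeast"),
        ]
    )


# -- micromovement metrics -------------------------------------------------


def test_micromovement_totals():
    mms = [mm_event(0, "yeast", 10, 40), mm_event(0, "yeast", 100, 190)]
    out = micromovement_metrics(mms, "yeast", FPS, int(300 * FPS))
    assert out["total_min"] == pytest.approx(2.0)  # 30 s + 90 s
    assert out["count"] == 2
    assert out["cumulative_min"][-1] == pytest.approx(2.0)  # conservation


def test_micromovement_empty():
    out = micromovement_metrics([], "yeast", FPS, 1000)
    assert out["total_min"] == 0.0
    assert np.all(out["cumulative_min"] == 0.0)


# -- encounter metrics -----------------------------------------------------


def _encounters(n, patch=0):
    from flyforage.events import Encounter

    return [
        Encounter(patch, "yeast", int(i * 100), int(i * 100 + 50)) for i in range(n)
    ]


def _walking_track(arena, minutes, n_extra=0):
    """All-walk track far from the patches for a given number of minutes."""
    n = int(minutes * 60 * FPS) + n_extra
    head = np.tile([40.0, 40.0], (n, 1))
    return make_smooth_track(head), labels_all("walk", n)


def test_p_stop(two_patch_arena):
    encs = _encounters(10)
    mms = [
        FoodMicromovement(0, "yeast", e.start + 5, e.start + 10) for e in encs[:4]
    ]
    track, labels = _walking_track(two_patch_arena, 1)
    out = encounter_metrics(encs, mms, labels, track, two_patch_arena)
    assert out["p_stop"] == pytest.approx(0.4)
    assert out["n_encounters"] == 10


def test_encounter_rate(two_patch_arena):
    track, labels = _walking_track(two_patch_arena, 6)
    out = encounter_metrics(_encounters(12), [], labels, track, two_patch_arena)
    assert out["rate_per_min"] == pytest.approx(2.0)


def test_zero_encounters(two_patch_arena):
    track, labels = _walking_track(two_patch_arena, 1)
    out = encounter_metrics([], [], labels, track, two_patch_arena)
    assert out["n_encounters"] == 0
    assert out["rate_per_min"] == 0.0
    assert np.isnan(out["p_stop"])  # missing, not zero


# -- visit metrics ---------------------------------------------------------


def test_visit_metrics_basic():
    visits = [
        visit(0, "yeast", 0, 60, min_dist=1.0, area=1),
        visit(0, "yeast", 100, 220, min_dist=1.0, area=3),
        visit(0, "yeast", 300, 480, min_dist=1.0, area=5),
    ]
    n = int(500 * FPS)
    track = make_smooth_track(np.zeros((n, 2)))
    out = visit_metrics(visits, track)
    assert out["total_min"] == pytest.approx(6.0)  # 1 + 2 + 3 min
    assert out["avg_min"] == pytest.approx(2.0)
    assert out["avg_min_dist_mm"] == pytest.approx(1.0)
    assert out["avg_area_cells"] == pytest.approx(3.0)


def test_visit_metrics_empty():
    track = make_smooth_track(np.zeros((100, 2)))
    out = visit_metrics([], track)
    assert out["n_visits"] == 0
    assert out["total_min"] == 0.0
    assert np.isnan(out["avg_min"])


def test_speed_outside_visits():
    n = 1000
    track = make_smooth_track(np.zeros((n, 2)))
    track.body_speed_smooth = np.full(n, 3.0)
    track.body_speed_smooth[:500] = 7.0
    visits = [Visit(0, "yeast", 0, 500)]
    assert speed_outside_visits(visits, track) == pytest.approx(3.0)


# -- sliding window --------------------------------------------------------


def test_sliding_window_exact_fill():
    visits = [visit(0, "yeast", 0, 300)]
    df = sliding_window_visit_duration(visits, FPS, 1200)
    assert df.loc[0, "visit_s"] == pytest.approx(300.0)
    assert df.loc[2, "visit_s"] == pytest.approx(0.0)


def test_sliding_window_no_visits():
    df = sliding_window_visit_duration([], FPS, 1200)
    assert np.all(df["visit_s"] == 0.0)


def test_sliding_window_overlap_split():
    # one 6-min visit [120, 480): window 0 [0,300) overlaps 180 s,
    # window 1 [240,540) overlaps 240 s, window 2 [480,780) gets nothing
    visits = [visit(0, "yeast", 120, 480)]
    df = sliding_window_visit_duration(visits, FPS, 1200)
    assert df.loc[0, "visit_s"] == pytest.approx(180.0)
    assert df.loc[1, "visit_s"] == pytest.approx(240.0)
    assert df.loc[2, "visit_s"] == pytest.approx(0.0)


# -- transitions -----------------------------------------------------------


def _track_with_excursion(max_dist):
    """Head parked at patch 0, excursion along +y to max_dist, back."""
    n = int(40 * FPS)
    head = np.zeros((n, 2))
    lo, hi = sec(10, 30)
    m = hi - lo
    up = np.linspace(0, max_dist, m // 2)
    head[lo : lo + m // 2, 1] = up
    head[lo + m // 2 : hi, 1] = up[::-1][: m - m // 2]
    return make_smooth_track(head)


def test_transition_same(three_patch_arena):
    visits = [visit(0, "yeast", 0, 10), visit(0, "yeast", 30, 40)]
    track = _track_with_excursion(12.0)
    recs, probs = classify_transitions(visits, track, three_patch_arena)
    assert [r.kind for r in recs] == [SAME]
    assert probs[SAME] == 1.0


def test_transition_distant_by_excursion(three_patch_arena):
    visits = [visit(0, "yeast", 0, 10), visit(0, "yeast", 30, 40)]
    track = _track_with_excursion(17.0)
    recs, _ = classify_transitions(visits, track, three_patch_arena)
    assert [r.kind for r in recs] == [DISTANT]
    assert recs[0].max_excursion_mm == pytest.approx(17.0, abs=0.1)


def test_transition_adjacent(three_patch_arena):
    n = int(40 * FPS)
    head = np.zeros((n, 2))
    lo, hi = sec(10, 30)
    head[lo:hi, 0] = np.linspace(0, 10, hi - lo)  # straight to patch 1
    head[hi:, 0] = 10.0
    track = make_smooth_track(head)
    visits = [visit(0, "yeast", 0, 10), visit(1, "yeast", 30, 40)]
    recs, probs = classify_transitions(visits, track, three_patch_arena)
    assert [r.kind for r in recs] == [ADJACENT]
    assert probs[ADJACENT] == 1.0


def test_transition_distant_by_center_distance(three_patch_arena):
    n = int(40 * FPS)
    head = np.zeros((n, 2))
    lo, hi = sec(10, 30)
    head[lo:hi, 0] = np.linspace(0, -20, hi - lo)
    head[hi:, 0] = -20.0
    track = make_smooth_track(head)
    visits = [visit(0, "yeast", 0, 10), visit(2, "yeast", 30, 40)]
    recs, _ = classify_transitions(visits, track, three_patch_arena)
    assert [r.kind for r in recs] == [DISTANT]


def test_transition_probabilities_sum_to_one(three_patch_arena):
    visits = [
        visit(0, "yeast", 0, 10),
        visit(0, "yeast", 30, 40),
        visit(1, "yeast", 60, 70),
        visit(2, "yeast", 100, 110),
    ]
    n = int(120 * FPS)
    track = make_smooth_track(np.zeros((n, 2)))
    _, probs = classify_transitions(visits, track, three_patch_arena)
    assert probs[SAME] + probs[ADJACENT] + probs[DISTANT] == pytest.approx(1.0)


def test_too_few_visits(three_patch_arena):
    track = make_smooth_track(np.zeros((100, 2)))
    recs, probs = classify_transitions(
        [visit(0, "yeast", 0, 1)], track, three_patch_arena
    )
    assert recs == []
    assert np.isnan(probs[SAME])


def test_scale_probs_to_100():
    out = scale_probs_to_100({SAME: 0.1, ADJACENT: 0.1, DISTANT: 0.6})
    assert out[DISTANT] == pytest.approx(75.0)
    assert sum(out.values()) == pytest.approx(100.0)


# -- distance to next yeast visit ------------------------------------------


def test_distance_straight_dash():
    n = int(30 * FPS)
    head = np.zeros((n, 2))
    lo, hi = sec(10, 20)
    head[lo:hi, 0] = np.linspace(0, 20, hi - lo)
    head[hi:, 0] = 20.0
    track = make_smooth_track(head)
    visits = [visit(0, "yeast", 0, 10), visit(1, "yeast", 20, 30)]
    d = distance_to_next_yeast_visit(visits, track)
    assert d == pytest.approx(20.0, rel=0.01)


def test_distance_abutting_visits_zero():
    track = make_smooth_track(np.zeros((int(20 * FPS), 2)))
    visits = [visit(0, "yeast", 0, 10), visit(0, "yeast", 10, 20)]
    assert distance_to_next_yeast_visit(visits, track) == pytest.approx(0.0)


def test_distance_semicircle():
    r = 8.0
    n_gap = int(10 * FPS)
    theta = np.linspace(0, np.pi, n_gap)
    arc = np.column_stack([r * np.cos(theta), r * np.sin(theta)])
    head = np.vstack(
        [np.tile(arc[0], (100, 1)), arc, np.tile(arc[-1], (100, 1))]
    )
    track = make_smooth_track(head)
    visits = [
        Visit(0, "yeast", 0, 100),
        Visit(1, "yeast", 100 + n_gap, 200 + n_gap),
    ]
    d = distance_to_next_yeast_visit(visits, track)
    assert d == pytest.approx(np.pi * r, rel=0.02)


# -- quartiles -------------------------------------------------------------


def test_quartiles_uniform():
    # 40 min of continuous yeast micromovement after a 10 min latency
    n = int(3600 * FPS)
    track = make_smooth_track(np.zeros((n, 2)))
    mms = [mm_event(0, "yeast", 600, 3000)]
    bounds = yeast_quartiles(mms, 600.0, track)
    spans = [(e - s) / FPS for s, e in bounds]
    for span in spans:
        assert span == pytest.approx(600.0, abs=0.1)  # 10 yeast-min each


def test_quartiles_conservation():
    rng = np.random.default_rng(4)
    n = int(1200 * FPS)
    track = make_smooth_track(np.zeros((n, 2)))
    mms = []
    t = 100.0
    while t < 1100:
        dur = rng.uniform(5, 40)
        mms.append(mm_event(0, "yeast", t, min(t + dur, 1100)))
        t += dur + rng.uniform(5, 50)
    bounds = yeast_quartiles(mms, 60.0, track)
    mask = np.zeros(n, bool)
    for m in mms:
        mask[m.start : m.end] = True
    mask[: int(60 * FPS)] = False
    total = mask.sum()
    for s, e in bounds:
        q = mask[s:e].sum()
        assert abs(q - total / 4) <= 1  # 25% +/- one frame
    assert sum(mask[s:e].sum() for s, e in bounds) == total


def test_quartiles_end_before_assay_end():
    n = int(1200 * FPS)
    track = make_smooth_track(np.zeros((n, 2)))
    mms = [mm_event(0, "yeast", 100, 500)]  # all yeast time in first half
    bounds = yeast_quartiles(mms, 60.0, track)
    assert bounds.windows[-1][1] <= int(510 * FPS)


def test_quartiles_require_latency():
    track = make_smooth_track(np.zeros((1000, 2)))
    with pytest.raises(ValueError):
        yeast_quartiles([], 0.0, track)


def test_quartile_metrics_frame(three_patch_arena):
    n = int(1200 * FPS)
    track = make_smooth_track(np.zeros((n, 2)))
    visits = [visit(0, "yeast", 100 + 200 * i, 200 + 200 * i) for i in range(5)]
    mms = [mm_event(0, "yeast", 100 + 200 * i, 200 + 200 * i) for i in range(5)]
    bounds = yeast_quartiles(mms, 0.0, track)
    df = quartile_metrics(bounds, visits, track, three_patch_arena)
    assert list(df["quartile"]) == [1, 2, 3, 4]
    assert df["total_visit_min"].sum() == pytest.approx(500 / 60, abs=0.05)


# -- population ------------------------------------------------------------


def test_population_metrics():
    df = pd.DataFrame(
        {
            "condition": ["a"] * 10,
            "yeast_total_visit_min": [0.5] * 3 + [5.0] * 7,
            "yeast_total_micromove_min": [1.0, 2.0, 3.0] + [2.0] * 7,
        }
    )
    out = population_metrics(df).set_index("condition")
    assert out.loc["a", "fraction_non_eaters"] == pytest.approx(0.3)


def test_population_cv_definition():
    totals = [1.0, 2.0, 3.0]
    df = pd.DataFrame(
        {
            "condition": ["c"] * 3,
            "yeast_total_visit_min": [2.0] * 3,
            "yeast_total_micromove_min": totals,
        }
    )
    out = population_metrics(df)
    expect = np.std(totals, ddof=1) / np.mean(totals)
    assert out.loc[0, "cv_micromovement_total"] == pytest.approx(expect)


def test_population_cv_zero_for_identical():
    df = pd.DataFrame(
        {
            "condition": ["c"] * 4,
            "yeast_total_visit_min": [2.0] * 4,
            "yeast_total_micromove_min": [3.0] * 4,
        }
    )
    out = population_metrics(df)
    assert out.loc[0, "cv_micromovement_total"] == pytest.approx(0.0)


# -- full row --------------------------------------------------------------


def test_compute_fly_metrics_smoke(two_patch_arena):
    n = int(60 * FPS)
    track = make_smooth_track(np.zeros((n, 2)))
    labels = labels_all("walk", n)
    row = compute_fly_metrics(track, labels, [], [], [], two_patch_arena)
    assert row["yeast_n_encounters"] == 0
    assert np.isnan(row["yeast_p_stop"])
    assert row["latency_censored"]
    assert np.isnan(row["p_same"])
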