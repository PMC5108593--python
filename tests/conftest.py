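import numpy as np
import pytest

from flyforage.arena import Arena, FoodPatch, build_standard_arena
from flyforage.ethogram import EthogramLabels, LABEL_CODES, runs_of, CODE_LABELS
from flyforage.kinematics import SmoothTrack


@pytest.fixture(scope="session")
def standard_arena():
    return build_standard_arena()


@pytest.fixture()
def two_patch_arena():
    return Arena(
        patches=[
            FoodPatch(id=0, center=(0.0, 0.0), substrate="yeast"),
            FoodPatch(id=1, center=(0.0, 12.0), substrate="sucrose"),
        ]
    )


def make_smooth_track(
    head: np.ndarray,
    fps: float = 50.0,
    head_speed_walk: np.ndarray | None = None,
    head_speed_rest: np.ndarray | None = None,
    angular_speed: np.ndarray | None = None,
    body_speed: np.ndarray | None = None,
) -> SmoothTrack:
    """Hand-build a SmoothTrack with explicit channels (tests bypass
    smoothing when they want to pin exact channel values)."""
    head = np.asarray(head, float).reshape(-1, 2)
    n = len(head)
    z = np.zeros(n)
    speed = np.append(np.linalg.norm(np.diff(head, axis=0), axis=1) * fps, 0.0) if n > 1 else z
    hw = speed if head_speed_walk is None else np.asarray(head_speed_walk, float)
    hr = speed if head_speed_rest is None else np.asarray(head_speed_rest, float)
    bs = speed if body_speed is None else np.asarray(body_speed, float)
    return SmoothTrack(
        fps=fps,
        head=head,
        body=head.copy(),
        tail=head.copy(),
        head_speed=speed,
        body_speed=bs,
        body_speed_smooth=bs,
        angular_speed=z if angular_speed is None else np.asarray(angular_speed, float),
        head_speed_walk=hw,
        head_speed_rest=hr,
    )


def labels_from_codes(codes: np.ndarray) -> EthogramLabels:
    codes = np.asarray(codes, int)
    bouts = [(CODE_LABELS[c], s, e) for c, s, e in runs_of(codes)]
    return EthogramLabels(
        labels=codes, sharp_turn=np.zeros(len(codes), bool), bouts=bouts
    )


def labels_all(label: str, n: int) -> EthogramLabels:
    return labels_from_codes(np.full(n, LABEL_CODES[label]))
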