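"""Foraging arena geometry: food patches, distances, adjacency.

All coordinates are millimetres in an arena-centered, y-up frame.  Pixel
inputs are converted once at load time using ``mm_per_px``; nothing in this
module ever sees pixels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

#: Patch centers closer than this are considered adjacent (mm).
ADJACENCY_MM = 16.0

#: Minimum allowed distance between patch centers (mm).
MIN_PATCH_SPACING_MM = 10.0

SUBSTRATES = ("yeast", "sucrose")


class ArenaConfigError(ValueError):
    """Raised when an arena layout violates its geometric invariants."""


@dataclass(frozen=True)
class FoodPatch:
    """A circular food patch."""

    id: int
    center: tuple[float, float]
    radius: float = 1.5
    substrate: str = "yeast"

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ArenaConfigError(f"patch {self.id}: radius must be > 0")
        if self.substrate not in SUBSTRATES:
            raise ArenaConfigError(
                f"patch {self.id}: substrate {self.substrate!r} not in {SUBSTRATES}"
            )


@dataclass
class Arena:
    """Circular arena with a set of food patches.

    Parameters
    ----------
    inner_radius : float
        Radius of the flat inner area holding the patches, mm.
    patches : list of FoodPatch
    mm_per_px : float
        Pixel pitch of the source video, mm per pixel.
    fps : float
        Video frame rate, frames per second.
    """

    inner_radius: float = 25.0
    patches: list[FoodPatch] = field(default_factory=list)
    mm_per_px: float = 0.155
    fps: float = 50.0

    def __post_init__(self) -> None:
        self.validate()

    # -- derived views -----------------------------------------------------

    @property
    def centers(self) -> np.ndarray:
        """(n_patches, 2) array of patch centers, mm."""
        return np.array([p.center for p in self.patches], dtype=float).reshape(-1, 2)

    @property
    def substrates(self) -> np.ndarray:
        return np.array([p.substrate for p in self.patches])

    def patch_ids(self, substrate: str | None = None) -> list[int]:
        return [
            p.id for p in self.patches if substrate is None or p.substrate == substrate
        ]

    # -- invariants --------------------------------------------------------

    def validate(self) -> None:
        if not self.patches:
            return
        centers = self.centers
        r = np.linalg.norm(centers, axis=1)
        if np.any(r > self.inner_radius + 1e-9):
            raise ArenaConfigError("patch center outside inner arena radius")
        n = len(self.patches)
        if n > 1:
            d = np.linalg.norm(centers[:, None] - centers[None, :], axis=-1)
            off = d[~np.eye(n, dtype=bool)]
            if off.min() < MIN_PATCH_SPACING_MM - 1e-9:
                raise ArenaConfigError(
                    f"patch centers closer than {MIN_PATCH_SPACING_MM} mm "
                    f"(min {off.min():.2f} mm)"
                )

    def check_standard(self) -> None:
        """Check the invariants of the standard 9+9 layout (raises on failure)."""
        subs = self.substrates
        n_yeast = int(np.sum(subs == "yeast"))
        n_suc = int(np.sum(subs == "sucrose"))
        if n_yeast != 9 or n_suc != 9:
            raise ArenaConfigError(
                f"standard arena needs 9 yeast + 9 sucrose patches, "
                f"got {n_yeast}+{n_suc}"
            )
        adj = adjacency(self)
        for i in range(len(self.patches)):
            neigh = subs[adj[i]]
            if "yeast" not in neigh or "sucrose" not in neigh:
                raise ArenaConfigError(
                    f"patch {self.patches[i].id} lacks an adjacent yeast or "
                    "sucrose patch"
                )

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "mm_per_px": self.mm_per_px,
            "fps": self.fps,
            "inner_radius_mm": self.inner_radius,
            "patches": [
                {
                    "id": p.id,
                    "x_mm": float(p.center[0]),
                    "y_mm": float(p.center[1]),
                    "radius_mm": p.radius,
                    "substrate": p.substrate,
                }
                for p in self.patches
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Arena":
        patches = [
            FoodPatch(
                id=int(p["id"]),
                center=(float(p["x_mm"]), float(p["y_mm"])),
                radius=float(p.get("radius_mm", 1.5)),
                substrate=p["substrate"],
            )
            for p in d.get("patches", [])
        ]
        return cls(
            inner_radius=float(d.get("inner_radius_mm", 25.0)),
            patches=patches,
            mm_per_px=float(d.get("mm_per_px", 0.155)),
            fps=float(d.get("fps", 50.0)),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "Arena":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def build_standard_arena(seed: int | None = None) -> Arena:
    """Build the standard 18-patch arena: two concentric rings, substrates
    alternating within each ring.

    The outer ring carries 12 patches at 20 mm, the inner ring 6 patches at
    10 mm; the ring split is an implementation choice (flagged in config) —
    only the spacing, counts, and substrate-adjacency constraints are fixed.
    ``seed`` rotates the whole layout by a random phase; the geometry and
    invariants are identical for every seed.
    """
    rng = np.random.default_rng(seed)
    phase = float(rng.uniform(0, 2 * np.pi)) if seed is not None else 0.0

    patches: list[FoodPatch] = []
    pid = 0
    # inner ring offset by half an outer-ring spacing so every patch ends up
    # with at least one adjacent yeast and one adjacent sucrose patch
    for ring_r, n_ring, offset in ((20.0, 12, 0.0), (10.0, 6, np.pi / 12)):
        for k in range(n_ring):
            theta = phase + offset + 2 * np.pi * k / n_ring
            sub = SUBSTRATES[k % 2]
            patches.append(
                FoodPatch(
                    id=pid,
                    center=(ring_r * np.cos(theta), ring_r * np.sin(theta)),
                    radius=1.5,
                    substrate=sub,
                )
            )
            pid += 1
    arena = Arena(patches=patches)
    arena.check_standard()
    return arena


def distances_to_patches(point, arena: Arena) -> np.ndarray:
    """Euclidean distance (mm) from ``point`` — a 2-vector or an (n, 2)
    array — to every patch center.  Returns (n_patches,) or (n, n_patches)."""
    pt = np.asarray(point, dtype=float)
    if not np.all(np.isfinite(pt)):
        raise ValueError("point coordinates must be finite")
    single = pt.ndim == 1
    pts = pt.reshape(-1, 2)
    d = np.linalg.norm(pts[:, None, :] - arena.centers[None, :, :], axis=-1)
    return d[0] if single else d


def adjacency(arena: Arena) -> np.ndarray:
    """Boolean patch×patch matrix: True iff center distance ≤ 16 mm.

    Symmetric with a False diagonal.
    """
    centers = arena.centers
    d = np.linalg.norm(centers[:, None] - centers[None, :], axis=-1)
    adj = d <= ADJACENCY_MM
    np.fill_diagonal(adj, False)
    return adj
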