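"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from bahd import BinaryVolume


def volume_from_points(points, shape=(12, 12, 12), spacing=(1.0, 1.0, 1.0)) -> BinaryVolume:
    """Build a binary volume whose foreground is exactly ``points``."""
    mask = np.zeros(shape, dtype=bool)
    for p in points:
        mask[tuple(int(c) for c in p)] = True
    return BinaryVolume(mask, spacing)


def brute_force_sums(gt: BinaryVolume, seg: BinaryVolume, units: str = "voxel"):
    """Exhaustive pairwise-minimum oracle for (GtoS, StoG).

    Independent of the distance-transform production path: scales indices,
    forms the full pairwise Euclidean distance matrix, and sums per-point
    minima.
    """
    g = gt.foreground_indices().astype(float)
    s = seg.foreground_indices().astype(float)
    if units == "mm":
        g = g * np.asarray(gt.spacing)
        s = s * np.asarray(seg.spacing)
    d = cdist(g, s)
    return float(d.min(axis=1).sum()), float(d.min(axis=0).sum())


def brute_force_ahd(gt: BinaryVolume, seg: BinaryVolume, units: str = "voxel") -> float:
    gs, sg = brute_force_sums(gt, seg, units)
    return (gs / gt.n_foreground + sg / seg.n_foreground) / 2.0


def brute_force_bahd(gt: BinaryVolume, seg: BinaryVolume, units: str = "voxel") -> float:
    gs, sg = brute_force_sums(gt, seg, units)
    return (gs + sg) / (2.0 * gt.n_foreground)


def random_volume_pair(rng: np.random.Generator, max_edge: int = 20, max_fg: int = 200):
    """A random geometry-compatible (gt, seg) pair with non-empty masks."""
    shape = tuple(int(rng.integers(4, max_edge + 1)) for _ in range(3))
    spacing = tuple(float(s) for s in rng.uniform(0.4, 2.5, size=3))
    vols = []
    for _ in range(2):
        n = int(rng.integers(1, max_fg + 1))
        mask = np.zeros(shape, dtype=bool)
        idx = rng.integers(0, shape, size=(n, 3))
        mask[idx[:, 0], idx[:, 1], idx[:, 2]] = True
        vols.append(BinaryVolume(mask, spacing))
    return vols[0], vols[1]


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


@pytest.fixture
def small_phantom():
    """A small deterministic phantom shared across simulation tests."""
    from bahd import generate_phantom

    return generate_phantom(
        size=(48, 48, 48), n_branches=5, radius_range=(1.5, 2.5), seed=7
    )
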