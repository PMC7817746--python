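"""Average and balanced average Hausdorff distances between binary masks.

For two finite point sets ``X`` (ground truth, size ``G``) and ``Y``
(segmentation, size ``S``), let ``GtoS`` be the sum over ground-truth points
of the minimum Euclidean distance to the segmentation, and ``StoG`` the sum
in the opposite direction.  The two metrics implemented here are

* average Hausdorff distance (AHD)::

      AHD = (GtoS / G + StoG / S) / 2

* balanced average Hausdorff distance (bAHD), in which both directed sums
  are normalised by the ground-truth count, which is constant across all
  segmentations of the same reference::

      bAHD = (GtoS / G + StoG / G) / 2

The division by ``S`` makes AHD unreliable for ranking: adding false
positives whose mean distance to the ground truth is below the current mean
``StoG / S`` *lowers* AHD even though the segmentation got strictly worse.
bAHD removes the segmentation-size-dependent denominator and is therefore
monotone under pure false-positive growth.

Distances are computed either in voxel units (on integer indices) or in
millimetres (indices scaled componentwise by the voxel spacing, voxel-centre
convention, exact anisotropic Euclidean).  The production path uses an exact
Euclidean distance transform of each mask's complement sampled at the other
mask's foreground voxels; it is contractually equivalent (1e-9 relative) to
the brute-force pairwise minimum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import distance_transform_edt
from scipy.spatial import cKDTree

from .exceptions import EmptyMaskError, GeometryMismatchError, UnitMismatchError

VOXEL = "voxel"
MM = "mm"
_UNITS = (VOXEL, MM)


def _check_units(units: str) -> str:
    if units not in _UNITS:
        raise ValueError(f"units must be one of {_UNITS}, got {units!r}")
    return units


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BinaryVolume:
    """A 3D binary mask together with its voxel spacing (mm per voxel).

    The mask is stored as a boolean array; foreground voxels are the point
    set the metrics operate on.
    """

    mask: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        mask = np.asarray(self.mask, dtype=bool)
        if mask.ndim != 3:
            raise ValueError(f"mask must be 3D, got ndim={mask.ndim}")
        spacing = tuple(float(s) for s in self.spacing)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValueError(f"spacing must be three positive reals, got {self.spacing}")
        object.__setattr__(self, "mask", mask)
        object.__setattr__(self, "spacing", spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.mask.shape  # type: ignore[return-value]

    @property
    def n_foreground(self) -> int:
        return int(self.mask.sum())

    def foreground_indices(self) -> np.ndarray:
        """Foreground voxel indices as an (N, 3) integer array."""
        return np.argwhere(self.mask)

    def foreground_set(self) -> set[tuple[int, int, int]]:
        return {tuple(int(i) for i in idx) for idx in self.foreground_indices()}

    def with_mask(self, mask: np.ndarray) -> "BinaryVolume":
        return BinaryVolume(mask, self.spacing)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BinaryVolume):
            return NotImplemented
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing)
            and bool(np.array_equal(self.mask, other.mask))
        )

    def __hash__(self) -> int:  # frozen dataclass with array field
        return hash((self.shape, self.spacing, int(self.mask.sum())))


@dataclass(frozen=True)
class PointSet:
    """A finite set of 3D coordinates, in voxel or millimetre units."""

    points: np.ndarray
    units: str = VOXEL

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.size == 0:
            pts = pts.reshape(0, 3)
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise ValueError(f"points must be an (N, 3) array, got shape {pts.shape}")
        if len(pts) and len(np.unique(pts, axis=0)) != len(pts):
            raise ValueError("point set contains duplicate coordinates")
        _check_units(self.units)
        object.__setattr__(self, "points", pts)

    def __len__(self) -> int:
        return len(self.points)

    def as_set(self) -> set[tuple[float, float, float]]:
        return {tuple(p) for p in self.points}


@dataclass(frozen=True)
class DistanceSummary:
    """All ingredients of the AHD/bAHD formulas for one (gt, seg) pair.

    ``sum_g_to_s`` and ``sum_s_to_g`` are the directed *sums* of minimum
    distances (GtoS, StoG); ``n_g`` and ``n_s`` are the foreground counts
    G and S.
    """

    sum_g_to_s: float
    sum_s_to_g: float
    n_g: int
    n_s: int
    units: str = VOXEL
    ahd: float = field(init=False)
    bahd: float = field(init=False)

    def __post_init__(self) -> None:
        if self.n_g <= 0 or self.n_s <= 0:
            raise EmptyMaskError("point counts must be positive")
        if self.sum_g_to_s < 0 or self.sum_s_to_g < 0:
            raise ValueError("distance sums must be nonnegative")
        _check_units(self.units)
        object.__setattr__(
            self, "ahd", (self.sum_g_to_s / self.n_g + self.sum_s_to_g / self.n_s) / 2.0
        )
        object.__setattr__(
            self, "bahd", (self.sum_g_to_s + self.sum_s_to_g) / (2.0 * self.n_g)
        )


# ---------------------------------------------------------------------------
# Point-set operations
# ---------------------------------------------------------------------------


def extract_point_set(volume: BinaryVolume, units: str = VOXEL) -> PointSet:
    """Foreground voxels of ``volume`` as a point set.

    In ``mm`` mode each voxel index is scaled componentwise by the spacing
    (voxel-centre convention).
    """
    _check_units(units)
    idx = volume.foreground_indices()
    if len(idx) == 0:
        raise EmptyMaskError("volume has no foreground voxels")
    pts = idx.astype(float)
    if units == MM:
        pts = pts * np.asarray(volume.spacing)
    return PointSet(pts, units)


def directed_min_distance_sum(a: PointSet, b: PointSet) -> float:
    """Sum over points of ``a`` of the minimum Euclidean distance to ``b``.

    Zero exactly when every point of ``a`` also lies in ``b``.
    """
    if len(a) == 0 or len(b) == 0:
        raise EmptyMaskError("directed distance requires two non-empty point sets")
    if a.units != b.units:
        raise UnitMismatchError(f"unit mismatch: {a.units} vs {b.units}")
    dists, _ = cKDTree(b.points).query(a.points)
    return float(np.sum(dists))


def average_hausdorff(gt: PointSet, seg: PointSet) -> float:
    """AHD between two point sets; symmetric in its arguments."""
    s_gs = directed_min_distance_sum(gt, seg)
    s_sg = directed_min_distance_sum(seg, gt)
    return (s_gs / len(gt) + s_sg / len(seg)) / 2.0


def balanced_average_hausdorff(gt: PointSet, seg: PointSet) -> float:
    """bAHD between ground truth and segmentation.

    Both directed sums are divided by the ground-truth count, so the first
    argument must be the ground truth; the measure is not symmetric.
    """
    s_gs = directed_min_distance_sum(gt, seg)
    s_sg = directed_min_distance_sum(seg, gt)
    return (s_gs + s_sg) / (2.0 * len(gt))


# ---------------------------------------------------------------------------
# Volume-level operations (distance-transform fast path)
# ---------------------------------------------------------------------------


def distance_to_foreground(volume: BinaryVolume, units: str = VOXEL) -> np.ndarray:
    """Exact Euclidean distance from every voxel to the nearest foreground voxel.

    Used as a reusable ingredient when one reference mask is compared against
    many segmentations.
    """
    _check_units(units)
    if volume.n_foreground == 0:
        raise EmptyMaskError("volume has no foreground voxels")
    sampling = volume.spacing if units == MM else None
    return distance_transform_edt(~volume.mask, sampling=sampling)


def compare_volumes(
    gt: BinaryVolume,
    seg: BinaryVolume,
    units: str = VOXEL,
    *,
    dist_to_gt: np.ndarray | None = None,
) -> DistanceSummary:
    """Full distance summary (GtoS, StoG, G, S, AHD, bAHD) for a volume pair.

    Parameters
    ----------
    gt, seg
        Geometry-compatible binary volumes (same shape and spacing).
    units
        ``"voxel"`` for index-space distances, ``"mm"`` for anisotropic
        physical distances.
    dist_to_gt
        Optional precomputed :func:`distance_to_foreground` of ``gt`` in the
        same units, reused across many segmentations of one reference.
    """
    _check_units(units)
    if gt.shape != seg.shape or not np.allclose(gt.spacing, seg.spacing):
        raise GeometryMismatchError(
            f"geometry mismatch: {gt.shape}/{gt.spacing} vs {seg.shape}/{seg.spacing}"
        )
    n_g = gt.n_foreground
    n_s = seg.n_foreground
    if n_g == 0 or n_s == 0:
        raise EmptyMaskError("both volumes must have non-empty foreground")
    dist_to_seg = distance_to_foreground(seg, units)
    if dist_to_gt is None:
        dist_to_gt = distance_to_foreground(gt, units)
    sum_g_to_s = float(dist_to_seg[gt.mask].sum())
    sum_s_to_g = float(dist_to_gt[seg.mask].sum())
    return DistanceSummary(sum_g_to_s, sum_s_to_g, n_g, n_s, units)
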