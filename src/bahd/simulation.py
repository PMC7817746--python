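"""Synthetic vessel phantoms and simulated segmentation errors.

This module generates everything the ranking study needs without patient
data: a tubular, tree-shaped binary ground truth; a library of
non-overlapping false-positive (FP) and false-negative (FN) error patches
mimicking the error taxonomy of cerebrovascular segmentation (distant FP
blobs near the skull, vessel-radius dilation, scattered single FP voxels,
missing vessel segments, missing small vessels, vessel thinning); and
chains of simulated segmentations built by adding one randomly drawn,
not-yet-used patch at a time.

Severity levels (subtle / moderate / severe) scale each class's base patch
size by 1x / 3x / 9x.  All randomness is driven by explicit integer seeds;
the whole simulation is a pure function of its parameters and seed.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy.ndimage import binary_erosion, distance_transform_edt, maximum_filter

from .exceptions import ParameterError, PatchConflictError, PlacementError
from .metrics import BinaryVolume


class Polarity(str, Enum):
    FALSE_POSITIVE = "false_positive"
    FALSE_NEGATIVE = "false_negative"


class ErrorClass(str, Enum):
    BLOB_FP = "blob_fp"
    RADIUS_DILATION_FP = "radius_dilation_fp"
    SCATTERED_FP = "scattered_fp"
    MISSING_SEGMENT_FN = "missing_segment_fn"
    SMALL_VESSEL_FN = "small_vessel_fn"
    THINNING_FN = "thinning_fn"


class Severity(str, Enum):
    SUBTLE = "subtle"
    MODERATE = "moderate"
    SEVERE = "severe"


_SEVERITY_MULTIPLIER = {Severity.SUBTLE: 1, Severity.MODERATE: 3, Severity.SEVERE: 9}
_SEVERITY_DIGIT = {Severity.SUBTLE: 1, Severity.MODERATE: 2, Severity.SEVERE: 3}

_CLASS_POLARITY = {
    ErrorClass.BLOB_FP: Polarity.FALSE_POSITIVE,
    ErrorClass.RADIUS_DILATION_FP: Polarity.FALSE_POSITIVE,
    ErrorClass.SCATTERED_FP: Polarity.FALSE_POSITIVE,
    ErrorClass.MISSING_SEGMENT_FN: Polarity.FALSE_NEGATIVE,
    ErrorClass.SMALL_VESSEL_FN: Polarity.FALSE_NEGATIVE,
    ErrorClass.THINNING_FN: Polarity.FALSE_NEGATIVE,
}

# Single-letter taxonomy codes, in the style of hand-labelled error ids
# (K = skull-area blob, C = carotid-style dilation, R = random scattered,
#  M = missing segment, V = small vessels, T = thinning).
_CLASS_LETTER = {
    ErrorClass.BLOB_FP: "K",
    ErrorClass.RADIUS_DILATION_FP: "C",
    ErrorClass.SCATTERED_FP: "R",
    ErrorClass.MISSING_SEGMENT_FN: "M",
    ErrorClass.SMALL_VESSEL_FN: "V",
    ErrorClass.THINNING_FN: "T",
}

# Base patch sizes in voxels, scaled by the severity multiplier.  FP blobs
# are deliberately large and distant (skull-scale oversegmentation of other
# anatomical structures): they dominate the StoG sum at moderate
# segmentation size, which is the regime where AHD's division by S produces
# ranking reversals.
_CLASS_BASE_SIZE = {
    ErrorClass.BLOB_FP: 100,
    ErrorClass.RADIUS_DILATION_FP: 30,
    ErrorClass.SCATTERED_FP: 8,
    ErrorClass.MISSING_SEGMENT_FN: 12,
    ErrorClass.SMALL_VESSEL_FN: 6,
    ErrorClass.THINNING_FN: 8,
}

# Library composition, cycled.  The mix mirrors the error taxonomy of a
# cerebrovascular segmentation task: falsely segmented distant anatomical
# structures (skull, meninges, sinus, optic nerve, meningeal artery) are
# the most common error type, followed by vessel-radius oversegmentation,
# with scattered voxels and the three false-negative kinds rounding out
# the set.  All six classes appear whenever the library has >= 11 patches
# (and by construction of the cycle, whenever it has >= 6).
_CLASS_CYCLE = (
    ErrorClass.BLOB_FP,
    ErrorClass.RADIUS_DILATION_FP,
    ErrorClass.MISSING_SEGMENT_FN,
    ErrorClass.SCATTERED_FP,
    ErrorClass.SMALL_VESSEL_FN,
    ErrorClass.THINNING_FN,
    ErrorClass.BLOB_FP,
    ErrorClass.BLOB_FP,
    ErrorClass.RADIUS_DILATION_FP,
    ErrorClass.BLOB_FP,
    ErrorClass.BLOB_FP,
)

_NEIGHBORS_26 = np.array(
    [
        (i, j, k)
        for i in (-1, 0, 1)
        for j in (-1, 0, 1)
        for k in (-1, 0, 1)
        if (i, j, k) != (0, 0, 0)
    ]
)


@dataclass(frozen=True)
class ErrorPatch:
    """One labelled, signed, non-overlapping segmentation error."""

    label: str
    polarity: Polarity
    voxels: frozenset[tuple[int, int, int]]
    error_class: ErrorClass
    severity: Severity

    def __post_init__(self) -> None:
        if not self.voxels:
            raise ValueError("an error patch must contain at least one voxel")

    def __len__(self) -> int:
        return len(self.voxels)

    def index_array(self) -> np.ndarray:
        return np.array(sorted(self.voxels), dtype=int)


@dataclass(frozen=True)
class SimulationSet:
    """One chain of simulated segmentations with 1..n cumulative errors."""

    ground_truth: BinaryVolume
    chain: tuple[tuple[BinaryVolume, int, tuple[str, ...]], ...]
    seed: int

    @property
    def segmentations(self) -> list[BinaryVolume]:
        return [seg for seg, _, _ in self.chain]

    @property
    def error_counts(self) -> list[int]:
        return [k for _, k, _ in self.chain]

    @property
    def applied_labels(self) -> list[tuple[str, ...]]:
        return [labels for _, _, labels in self.chain]


# ---------------------------------------------------------------------------
# Phantom generation
# ---------------------------------------------------------------------------


def _unit_vector(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _ball_offsets(radius: float) -> np.ndarray:
    r = int(np.ceil(radius))
    ax = np.arange(-r, r + 1)
    ii, jj, kk = np.meshgrid(ax, ax, ax, indexing="ij")
    inside = ii**2 + jj**2 + kk**2 <= radius**2
    return np.stack([ii[inside], jj[inside], kk[inside]], axis=1)


def _grow_centerline(
    start: np.ndarray,
    direction: np.ndarray,
    length: int,
    bounds: np.ndarray,
    margin: float,
    straightness: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Persistent random walk of unit steps, reflected off the volume margins."""
    pts = [start.copy()]
    d = direction.copy()
    for _ in range(length):
        d = straightness * d + (1.0 - straightness) * rng.normal(size=3)
        d /= np.linalg.norm(d)
        p = pts[-1] + d
        for ax in range(3):
            if p[ax] < margin or p[ax] > bounds[ax] - 1 - margin:
                d[ax] = -d[ax]
                p[ax] = pts[-1][ax] + d[ax]
        p = np.clip(p, margin, bounds - 1 - margin)
        pts.append(p)
    return np.array(pts)


def generate_phantom(
    size: tuple[int, int, int] = (64, 64, 64),
    n_branches: int = 7,
    radius_range: tuple[float, float] = (1.5, 3.0),
    seed: int = 0,
    *,
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
    branch_length: int | None = None,
    straightness: float = 0.85,
) -> BinaryVolume:
    """Generate a connected, tree-shaped tubular phantom.

    Branch centerlines are persistent random walks of unit steps; each
    branch is dilated to a per-branch radius drawn from ``radius_range``.
    Side branches start on a point of an existing centerline, so the
    foreground is a single 26-connected component.  The result is
    deterministic for a fixed seed and its foreground fraction lies in
    [0.1%, 5%] of the volume.

    ``branch_length`` fixes the root centerline arc length in voxels
    (defaults to 70% of the smallest volume edge); ``straightness`` in
    (0, 1] controls directional persistence (1.0 gives a straight tube).
    """
    size = tuple(int(s) for s in size)
    if len(size) != 3 or any(s < 32 for s in size):
        raise ParameterError(f"size must be at least (32, 32, 32), got {size}")
    if n_branches < 1:
        raise ParameterError("n_branches must be >= 1")
    r_lo, r_hi = float(radius_range[0]), float(radius_range[1])
    if not (0 < r_lo <= r_hi):
        raise ParameterError(f"invalid radius_range {radius_range}")
    if r_hi >= min(size) / 4:
        raise ParameterError(
            f"maximum radius {r_hi} too large for volume of size {size}"
        )
    rng = np.random.default_rng(seed)
    bounds = np.array(size, dtype=float)
    margin = r_hi + 1.5
    root_len = int(branch_length) if branch_length is not None else int(0.7 * min(size))

    centerlines: list[np.ndarray] = []
    start = bounds / 2 + rng.uniform(-0.08, 0.08, size=3) * bounds
    centerlines.append(
        _grow_centerline(start, _unit_vector(rng), root_len, bounds, margin, straightness, rng)
    )
    for _ in range(n_branches - 1):
        parent = centerlines[rng.integers(len(centerlines))]
        anchor = parent[rng.integers(len(parent))]
        length = max(4, int(root_len * rng.uniform(0.35, 0.6)))
        centerlines.append(
            _grow_centerline(anchor, _unit_vector(rng), length, bounds, margin, straightness, rng)
        )

    mask = np.zeros(size, dtype=bool)
    for line in centerlines:
        radius = rng.uniform(r_lo, r_hi)
        offsets = _ball_offsets(radius)
        centres = np.round(line).astype(int)
        coords = (centres[:, None, :] + offsets[None, :, :]).reshape(-1, 3)
        coords = np.clip(coords, 0, np.array(size) - 1)
        mask[coords[:, 0], coords[:, 1], coords[:, 2]] = True

    fraction = mask.mean()
    if not (0.001 <= fraction <= 0.05):
        raise ParameterError(
            f"phantom foreground fraction {fraction:.4%} outside [0.1%, 5%]; "
            "adjust n_branches, branch_length or radius_range"
        )
    return BinaryVolume(mask, spacing)


# ---------------------------------------------------------------------------
# Error patch library
# ---------------------------------------------------------------------------


def _grow_region(
    candidate: np.ndarray,
    seed_voxel: tuple[int, int, int],
    target: int,
    rng: np.random.Generator,
) -> list[tuple[int, int, int]]:
    """Collect up to ``target`` 26-connected voxels of ``candidate`` by BFS."""
    shape = candidate.shape
    seen = {seed_voxel}
    queue: deque[tuple[int, int, int]] = deque([seed_voxel])
    collected: list[tuple[int, int, int]] = []
    while queue and len(collected) < target:
        v = queue.popleft()
        collected.append(v)
        nbrs = _NEIGHBORS_26 + np.array(v)
        order = rng.permutation(len(nbrs))
        for n in nbrs[order]:
            t = (int(n[0]), int(n[1]), int(n[2]))
            if t in seen:
                continue
            if not all(0 <= t[ax] < shape[ax] for ax in range(3)):
                continue
            if candidate[t]:
                seen.add(t)
                queue.append(t)
    return collected


def _random_true_index(
    mask: np.ndarray, rng: np.random.Generator
) -> tuple[int, int, int] | None:
    idx = np.argwhere(mask)
    if len(idx) == 0:
        return None
    v = idx[rng.integers(len(idx))]
    return (int(v[0]), int(v[1]), int(v[2]))


class _PatchFactory:
    """Stateless geometry context shared by all patch constructors."""

    def __init__(self, gt: BinaryVolume):
        self.gt_mask = gt.mask
        self.shape = np.array(gt.shape)
        # distance from every voxel to the nearest vessel voxel
        self.dist_out = distance_transform_edt(~gt.mask)
        # interior half-thickness of the vessel tree
        dist_in = distance_transform_edt(gt.mask)
        local_thickness = maximum_filter(dist_in, size=3)
        thin_cut = max(1.5, float(np.percentile(local_thickness[gt.mask], 30)))
        self.thin_mask = gt.mask & (local_thickness <= thin_cut)
        self.surface_mask = gt.mask & ~binary_erosion(gt.mask)
        self.shell_mask = ~gt.mask & (self.dist_out <= 1.8)

    def make(
        self,
        cls: ErrorClass,
        target: int,
        claimed: np.ndarray,
        rng: np.random.Generator,
    ) -> list[tuple[int, int, int]]:
        free_bg = ~self.gt_mask & ~claimed
        free_fg = self.gt_mask & ~claimed
        if cls is ErrorClass.BLOB_FP:
            radius = max(1.0, (3.0 * target / (4.0 * np.pi)) ** (1.0 / 3.0))
            centre_ok = free_bg & (self.dist_out >= radius + 4.0) & (self.dist_out <= 28.0)
            centre = _random_true_index(centre_ok, rng)
            if centre is None:
                return []
            coords = _ball_offsets(radius) + np.array(centre)
            inb = np.all((coords >= 0) & (coords < self.shape), axis=1)
            coords = coords[inb]
            ok = free_bg[coords[:, 0], coords[:, 1], coords[:, 2]]
            return [tuple(int(x) for x in c) for c in coords[ok]]
        if cls is ErrorClass.RADIUS_DILATION_FP:
            candidate = self.shell_mask & ~claimed
            seed_voxel = _random_true_index(candidate, rng)
            if seed_voxel is None:
                return []
            return _grow_region(candidate, seed_voxel, target, rng)
        if cls is ErrorClass.SCATTERED_FP:
            candidate = free_bg & (self.dist_out > 3.0)
            idx = np.argwhere(candidate)
            if len(idx) < target:
                return []
            pick = idx[rng.choice(len(idx), size=target, replace=False)]
            return [tuple(int(x) for x in v) for v in pick]
        if cls is ErrorClass.MISSING_SEGMENT_FN:
            seed_voxel = _random_true_index(free_fg, rng)
            if seed_voxel is None:
                return []
            return _grow_region(free_fg, seed_voxel, target, rng)
        if cls is ErrorClass.SMALL_VESSEL_FN:
            candidate = self.thin_mask & ~claimed
            seed_voxel = _random_true_index(candidate, rng)
            if seed_voxel is None:
                return []
            return _grow_region(candidate, seed_voxel, target, rng)
        if cls is ErrorClass.THINNING_FN:
            candidate = self.surface_mask & ~claimed
            seed_voxel = _random_true_index(candidate, rng)
            if seed_voxel is None:
                return []
            return _grow_region(candidate, seed_voxel, target, rng)
        raise ParameterError(f"unknown error class {cls}")


def generate_error_library(
    gt: BinaryVolume,
    n_errors: int = 55,
    seed: int = 0,
    *,
    max_attempts: int = 60,
) -> list[ErrorPatch]:
    """Generate ``n_errors`` pairwise-disjoint FP/FN error patches on ``gt``.

    Classes and severities are cycled so every class appears when
    ``n_errors >= 6``.  FP patches never touch the ground truth; FN patches
    are subsets of it; no voxel belongs to two patches.  Each patch is
    retried (with a progressively reduced size target) up to
    ``max_attempts`` times before a :class:`PlacementError` is raised.
    """
    if n_errors < 1:
        raise ParameterError("n_errors must be >= 1")
    if gt.n_foreground == 0:
        raise ParameterError("ground truth must be non-empty")
    rng = np.random.default_rng(seed)
    factory = _PatchFactory(gt)
    claimed = np.zeros(gt.shape, dtype=bool)
    severities = list(Severity)
    patches: list[ErrorPatch] = []
    for i in range(n_errors):
        cls = _CLASS_CYCLE[i % len(_CLASS_CYCLE)]
        sev = severities[i % len(severities)]
        target = _CLASS_BASE_SIZE[cls] * _SEVERITY_MULTIPLIER[sev]
        voxels: list[tuple[int, int, int]] = []
        for attempt in range(max_attempts):
            # relax the size target over the retry budget
            want = max(1, int(target * (0.5 ** (attempt // 15))))
            voxels = factory.make(cls, want, claimed, rng)
            if len(voxels) >= max(1, want // 2):
                break
            voxels = []
        if not voxels:
            raise PlacementError(
                f"could not place patch {i + 1}/{n_errors} of class {cls.value} "
                f"after {max_attempts} attempts"
            )
        vox = np.array(voxels)
        claimed[vox[:, 0], vox[:, 1], vox[:, 2]] = True
        label = f"{_CLASS_LETTER[cls]}{_SEVERITY_DIGIT[sev]}-{i:02d}"
        patches.append(
            ErrorPatch(
                label=label,
                polarity=_CLASS_POLARITY[cls],
                voxels=frozenset(tuple(int(x) for x in v) for v in voxels),
                error_class=cls,
                severity=sev,
            )
        )
    return patches


# ---------------------------------------------------------------------------
# Simulated segmentation chains
# ---------------------------------------------------------------------------


def apply_patch(volume: BinaryVolume, patch: ErrorPatch) -> BinaryVolume:
    """Return a new volume with the patch applied (FP adds, FN removes voxels)."""
    idx = patch.index_array()
    if np.any(idx < 0) or np.any(idx >= np.array(volume.shape)):
        raise PatchConflictError(f"patch {patch.label} exceeds the volume bounds")
    mask = volume.mask.copy()
    sel = (idx[:, 0], idx[:, 1], idx[:, 2])
    if patch.polarity is Polarity.FALSE_NEGATIVE:
        if not np.all(mask[sel]):
            raise PatchConflictError(
                f"false-negative patch {patch.label} is not fully inside the foreground"
            )
        mask[sel] = False
    else:
        mask[sel] = True
    return volume.with_mask(mask)


def build_simulation_set(
    gt: BinaryVolume,
    library: list[ErrorPatch],
    chain_length: int = 10,
    seed: int = 0,
) -> SimulationSet:
    """Build one chain of ``chain_length`` segmentations with cumulative errors.

    Each step draws one not-yet-used patch uniformly at random and applies
    it to the previous segmentation, so segmentation ``k`` carries exactly
    ``k`` errors.
    """
    if chain_length < 1 or chain_length > len(library):
        raise ParameterError(
            f"chain_length must be in [1, {len(library)}], got {chain_length}"
        )
    rng = np.random.default_rng(seed)
    order = rng.choice(len(library), size=chain_length, replace=False)
    chain: list[tuple[BinaryVolume, int, tuple[str, ...]]] = []
    current = gt
    labels: list[str] = []
    for k, patch_idx in enumerate(order, start=1):
        patch = library[int(patch_idx)]
        current = apply_patch(current, patch)
        labels.append(patch.label)
        chain.append((current, k, tuple(labels)))
    return SimulationSet(ground_truth=gt, chain=tuple(chain), seed=seed)
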