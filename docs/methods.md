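# Methods

## Metrics

For finite point sets `X` (ground truth, `G = |X|`) and `Y` (segmentation,
`S = |Y|`), define the directed sum of minimum Euclidean distances
`d(X→Y) = Σ_{x∈X} min_{y∈Y} ‖x − y‖`. Writing `GtoS = d(X→Y)` and
`StoG = d(Y→X)`:

- `AHD  = (GtoS/G + StoG/S) / 2` — symmetric in its arguments;
- `bAHD = (GtoS/G + StoG/G) / 2 = (GtoS + StoG) / (2G)` — not symmetric;
  the first argument must be the ground truth.

Both operate on *all* foreground voxels (no surface extraction), between
voxel centres, with 0-based integer indices. In `voxel` units distances are
taken on raw indices; in `mm` units indices are scaled componentwise by the
voxel spacing first, giving exact Euclidean distances in anisotropic space
rather than a chamfer approximation. Empty ground truth or segmentation is
an error (`EmptyMaskError`); the metrics are not defined for empty sets and
no sentinel value is substituted. Loaded images are binarised at 0.5.

The production path computes, for each mask, the exact Euclidean distance
transform of its complement (`scipy.ndimage.distance_transform_edt`) and
sums it over the other mask's foreground. This is bit-equivalent (tested to
1e-9 relative) to the exhaustive pairwise minimum, but costs
O(volume) instead of O(G·S). The point-set functions
(`average_hausdorff`, `balanced_average_hausdorff`) use a KD-tree instead
and serve small or irregular point sets.

### Why AHD misranks

Adding a false-positive patch with voxel count `p` and distance sum `D`
changes `StoG/S` to `(StoG + D)/(S + p)`, which *decreases* whenever the
patch's mean distance `D/p` is below the current mean `StoG/S`. `GtoS` can
only decrease under added false positives. Hence a segmentation with
strictly more errors can have strictly lower AHD — typically after a large,
distant false-positive structure has inflated `StoG/S`, any
near-the-vessel oversegmentation lowers it again. bAHD's denominator is
constant, so pure false-positive growth strictly increases it
(superset monotonicity; property-tested).

### Known limitation of bAHD

bAHD is not fully monotone either: when the segmentation misses part of the
ground truth (`GtoS > 0`), a false positive that lands *near the missing
part* can lower `GtoS` by more than it raises `StoG`, so bAHD drops despite
the extra error. The test suite encodes this as expected behaviour
(a scattered false positive next to a removed vessel segment). In the
full-scale synthetic study this configuration is rare enough that every
bAHD ranking was perfect.

## Synthetic phantoms

`generate_phantom` builds a connected tree of tubular branches in a volume
of at least 32³ voxels (default 64³, isotropic unit spacing). Centerlines
are persistent random walks of unit steps (`straightness` = 0.85 by
default; 1.0 gives a straight tube) reflected off the volume margins; side
branches start on a point of an existing centerline, so the union is one
26-connected component. Each branch is dilated to a radius drawn uniformly
from `radius_range` (default 1.5–3.0 voxels, mimicking vessel calibres at
~0.5 mm resolution). Default: 7 branches, root length 70 % of the smallest
edge, giving a foreground fraction around 1 % (enforced to lie in
[0.1 %, 5 %]). Everything is a pure function of the seed.

The phantom emulates the geometry that matters for the metrics — a thin,
branching, connected foreground embedded in a much larger background — but
not MRA intensities, imaging noise, or anatomical realism; conclusions
about the *metrics'* ranking behaviour transfer, statements about any
particular anatomy or scanner do not.

## Error simulation

`generate_error_library` produces `n_errors` (default 55) pairwise
voxel-disjoint patches; false positives never touch the ground truth,
false negatives are subsets of it. Six classes model the common failure
modes of vessel segmentation:

| class | polarity | base size (voxels) | construction |
|---|---|---|---|
| `blob_fp` | FP | 100 | ball in the background, 4–28 voxels away from the vessel tree (falsely segmented distant anatomy: skull, meninges, sinus) |
| `radius_dilation_fp` | FP | 30 | region grown inside the 1-voxel shell around the vessels (oversegmented radius) |
| `scattered_fp` | FP | 8 | isolated random background voxels, > 3 voxels from the tree |
| `missing_segment_fn` | FN | 12 | connected chunk of the tree removed |
| `small_vessel_fn` | FN | 6 | removal restricted to locally thin branches |
| `thinning_fn` | FN | 8 | removal restricted to surface voxels |

Severities subtle/moderate/severe multiply the base size by 1×/3×/9×
(the taxonomy names three intensity levels without quantifying them; the
geometric progression spans an order of magnitude). The library cycles an
11-slot class pattern containing five `blob_fp` slots, two
`radius_dilation_fp` slots and one slot for each remaining class —
mirroring the composition of hand-drawn error sets for cerebrovascular
segmentation, where falsely segmented distant structures are the most
common error type. All six classes are present whenever the library has at
least six patches. Placement retries with a progressively relaxed size
target; exhausting the budget raises `PlacementError`.

`build_simulation_set` draws patches without replacement, uniformly at
random, applying one per step: segmentation *k* carries exactly the first
*k* sampled errors (chain length 10 by default). Per-set seeds are derived
from the master seed and the (phantom, set) index via
`numpy.random.SeedSequence`, so the whole study is reproducible and
trivially parallelisable.

## Ranking statistics

Each chain is ranked by each metric (rank 1 = smallest value; ties share
the average rank). Agreement with the injected-error count is measured by
Kendall's tau-b (tie-aware; computed between metric values and error
counts, which is equivalent to correlating ranks and avoids an arbitrary
tie-break). A set is *misranked* (counted in `Er`) when its tau differs
from 1 by more than 1e-12.

Per phantom, the two metrics' per-set taus are compared with a two-sided
paired Wilcoxon signed-rank test: zero differences are discarded; with at
most 20 nonzero differences the p-value comes from the exact null
distribution over all 2ⁿ sign assignments (computed by convolution, with
midranks for tied magnitudes), otherwise from a normal approximation with
tie correction. The pooled p-value applies the same test to all
`n_phantoms × n_sets` tau pairs; pooled medians and misranking totals
aggregate over the same pool. (How to pool is a design choice of this
package — the per-phantom tests are the primary statistic.)

## Study scale and runtimes

The default configuration is 10 phantoms × 20 sets × 10-error chains from
55-patch libraries, i.e. 200 ranked sets and 2,000 metric evaluations at
64³; it completes in about a minute on one CPU. Under these conditions
bAHD's pooled median tau is 1.00 with zero misranked sets, while AHD's
pooled median falls to ≈ 0.91 with roughly three-quarters of the sets
misranked, and the pooled Wilcoxon p is far below 0.05 — the directional
result is stable across master seeds. All counts, sizes and seeds are
configurable through `ExperimentConfig`.

## Numerical choices

- Distance transforms are exact Euclidean; agreement with the brute-force
  pairwise oracle is asserted to 1e-9 relative in the tests.
- `DistanceSummary` recomputes AHD/bAHD from its stored sums; the identity
  holds to 1e-12 relative by construction.
- Geometry compatibility requires identical shapes and spacings
  (`numpy.allclose`); mismatches raise `GeometryMismatchError` rather than
  resampling.
- Saved masks are uint8 NIfTI with a diagonal affine; oblique input
  affines contribute only their voxel sizes (logged warning). DICOM and
  orientation resampling are out of scope.
- Surface-based distances (HD95, average surface distance), Dice/Jaccard
  and the maximum Hausdorff distance are deliberately not implemented; the
  package is about the ranking behaviour of the two averaged measures.
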