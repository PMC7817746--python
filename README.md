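# bahd — balanced average Hausdorff distance for segmentation ranking

Quality assessment of 3D medical image segmentations — cerebrovascular
segmentation from MR angiography in particular — routinely uses the
**average Hausdorff distance (AHD)** to compare a binary segmentation *S*
against a ground truth *G*:

```
AHD  = (GtoS / G + StoG / S) / 2
```

where `GtoS` is the sum over ground-truth voxels of the minimum Euclidean
distance to the segmentation, `StoG` the sum in the opposite direction, and
`G`, `S` the foreground voxel counts. AHD has a hidden **ranking error**:
because `StoG` is divided by the segmentation's own size `S`, adding false
positives whose mean distance to the ground truth lies below the current
`StoG / S` *decreases* AHD — a strictly worse segmentation can outrank a
better one. The **balanced average Hausdorff distance (bAHD)** removes the
size-dependent denominator by normalising both directed sums with the
constant ground-truth count:

```
bAHD = (GtoS / G + StoG / G) / 2
```

which makes the measure strictly monotone under pure false-positive growth
and far more reliable for ranking candidate segmentations.

This package provides:

- the metric core (`bahd.metrics`): exact Euclidean distance-transform
  implementation of AHD and bAHD in voxel or millimetre units, for
  anisotropic voxel grids;
- NIfTI I/O for binary masks (`bahd.volume_io`);
- a synthetic validation study (`bahd.simulation`, `bahd.stats`): tubular
  vessel-tree phantoms, libraries of 55 non-overlapping false-positive /
  false-negative error patches across six error classes and three severity
  levels, chains of 10 simulated segmentations with cumulatively injected
  errors, metric-based ranking, Kendall tau-b correlation of ranks with
  error counts, and paired two-sided Wilcoxon signed-rank comparison of the
  two metrics;
- a CLI (`bahd compare | simulate | rank | run-all`).

It is aimed at researchers evaluating segmentation algorithms for thin,
complex structures (brain, liver or cardiac vessel trees), where the AHD
ranking error is most pronounced.

## Worked example

The ranking error in four lines. The ground truth is a single voxel; `S1`
adds one distant false positive; `S2` adds three *more* false positives
close to the ground truth:

```python
from bahd import PointSet, average_hausdorff, balanced_average_hausdorff

gt = PointSet([(0, 0, 0)])
s1 = PointSet([(0, 0, 0), (0, 0, 10)])
s2 = PointSet([(0, 0, 0), (0, 0, 10), (0, 0, 1), (0, 1, 0), (1, 0, 0)])

print("AHD(gt,S1)  =", average_hausdorff(gt, s1))
print("AHD(gt,S2)  =", average_hausdorff(gt, s2))
print("bAHD(gt,S1) =", balanced_average_hausdorff(gt, s1))
print("bAHD(gt,S2) =", balanced_average_hausdorff(gt, s2))
```

```
AHD(gt,S1)  = 2.5
AHD(gt,S2)  = 1.3
bAHD(gt,S1) = 5.0
bAHD(gt,S2) = 6.5
```

`S2` contains every error of `S1` plus three new ones, yet its AHD is
*lower* (1.3 < 2.5): the three added voxels grow `S` from 2 to 5 while
adding only 3.0 to `StoG`, so `StoG/S` falls from 5.0 to 2.6. bAHD rises
from 5.0 to 6.5 and ranks the pair correctly.

The same comparison at study scale — phantoms, error libraries and ranked
chains — runs in a few lines:

```python
from bahd import ExperimentConfig, run_experiment

cfg = ExperimentConfig(n_phantoms=2, n_sets_per_phantom=5, master_seed=7)
report = run_experiment(cfg)
print(report.pooled)
```

```
{'median_tau': {'AHD': 0.9555555555555554, 'bAHD': 0.9999999999999999},
 'total_misranked_sets': {'AHD': 7, 'bAHD': 0},
 'n_sets_total': 10, 'pooled_p': 0.015625}
```

Here bAHD ranked every one of the 10 simulated chains perfectly
(tau = 1), while AHD misranked at least one segmentation in 7 of them; the
paired Wilcoxon test over the 10 tau pairs gives p = 0.016.

From the shell, two masks are compared directly:

```sh
bahd compare ground_truth.nii.gz segmentation.nii.gz --units mm --json
```

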