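# perafkit

Percent amplitude of fluctuation (PerAF) analysis for resting-state fMRI,
built for case-control studies that ask three questions: *where* does
spontaneous BOLD fluctuation amplitude differ between patients and
controls, *how well* do those regional amplitudes separate the groups, and
*do they track* behavioral or ocular measurements.  The package bundles a
synthetic cohort generator with planted regional effects, so the whole
chain — preprocessing, PerAF mapping, cluster-corrected group inference,
ROC and brain-behavior correlation — can be validated end to end against
known ground truth without access to patient scans.

## The statistic

For a voxel time series $x_1, \dots, x_n$ with temporal mean
$\mu = \frac{1}{n}\sum_i x_i$,

$$\mathrm{PerAF} = \frac{1}{n}\sum_{i=1}^{n}\left|\frac{x_i-\mu}{\mu}\right|\times 100\\%$$

— the mean absolute deviation of the BOLD signal from its own mean, as a
percentage of that mean.  Unlike ALFF it carries no arbitrary scanner
units, and it is invariant to per-voxel gain.  The mPerAF variant divides
each subject's map by its within-brain mean to remove global amplitude
differences before group statistics (the pipeline default).

Group differences are assessed with a voxel-wise pooled two-sample t-test
at a cluster-forming threshold of two-tailed p < 0.005, and clusters are
screened by a minimum extent calibrated with a Monte-Carlo simulation of
smooth Gaussian null fields (the AlphaSim procedure), at family-wise
α = 0.05.  Regional means feed a Mann-Whitney/rank AUC with bootstrap or
DeLong confidence intervals, and Pearson correlations against phenotypes.

## Worked example

```python
import perafkit as pk

# a 17-vs-17 cohort with a 50% amplitude increase in a 27-voxel ROI,
# and an anxiety score anti-correlated (r = -0.8) with that amplitude
roi = pk.cube_roi((10, 10, 7), 3)
cohort_cfg = pk.SyntheticCohortConfig(
    effects=(pk.EffectSpec(roi_id=1, roi_voxels=roi, group="patient",
                           amplitude_multiplier=1.5),),
    phenotype_models=(pk.PhenotypeModel(name="anxiety_score", linked_roi_id=1,
                                        target_r=-0.8, mean=8.0, sd=2.0),),
    seed=1,
)
result = pk.run_pipeline(cohort_cfg, pk.PipelineConfig(n_iter=1000, seed=1))
print(result.cluster_report)
print(result.roi_report)
```

prints (seed 1):

```
   cluster_id  peak_x_mm  peak_y_mm  peak_z_mm  n_voxels     peak_t  corrected_p direction
0           1       -1.5       -1.5       -1.5       122  80.755859          0.0  increase

   roi_id                  measure     value  ci_low  ci_high         p   n
0       1                      auc  1.000000     1.0      1.0       NaN  34
1       1  pearson_r:anxiety_score -0.684067       NaN      NaN  0.000008  34
```

The planted ROI is centered at voxel (11, 11, 8), i.e. (−1.5, −1.5, −1.5)
mm in the cohort's world coordinates: the surviving cluster peaks inside
the planted region and spreads beyond its 27 voxels because the data are
smoothed at 6 mm FWHM.  The regional mean separates the two groups
perfectly (AUC 1.0), and the generated anxiety score recovers the planted
negative correlation with regional amplitude (r = −0.68 for this seed at a
target of −0.8; n = 34 sampling variability).  The very large peak t is a
property of the synthetic noise model: mPerAF standardization cancels the
generator's subject-global amplitude jitter almost exactly, leaving only
measurement noise in the contrast (see docs/methods.md).

The same analysis is available from the shell:

```sh
perafkit simulate --config cohort.yaml --out cohort/ --seed 1
perafkit run-all --cohort-config cohort.yaml --out results/ --seed 1
```

Demographic-table statistics can be recomputed directly from published
mean ± SD summaries:

```python
>>> pk.summary_t(117.06, 17.35, 17, 138.76, 12.07, 17)   # RNFLT, right eye
(4.233237367733395, 32, 0.00018109099960714133)
```

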