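# Methods

## Scope and model

perafkit implements an amplitude-of-fluctuation analysis for two-group
resting-state fMRI studies.  The subject-level statistic is PerAF: the mean
absolute deviation of a voxel's BOLD time series from its temporal mean,
expressed as a percentage of that mean.  Voxels whose temporal mean is not
positive have no meaningful PerAF; they are flagged undefined and excluded,
never imputed.  Because PerAF is invariant to per-voxel gain but not to a
subject-global amplitude offset, group statistics default to mPerAF — each
map divided by its within-mask mean, making the in-mask mean exactly 1 —
with raw PerAF available alongside (`PipelineConfig.mperaf = False`).

## Preprocessing

The chain is fixed: discard the first `discard_k` volumes (default 10, for
signal equilibration), screen subjects by maximum head displacement
(default threshold 3 mm), remove a per-voxel linear trend, smooth
spatially with a Gaussian kernel (default 6 mm FWHM).  Choices that were
genuinely open:

- **Mean-preserving detrend.** The least-squares slope is removed but the
  original temporal mean is retained.  A zero-mean residual series would
  make the PerAF denominator meaningless; keeping the raw mean matches the
  established PerAF toolchain behavior.
- **Strict motion rule.** A subject is excluded only when the maximum
  displacement exceeds the threshold ("over 3 mm"); exactly 3.0 mm is
  retained.  The boundary reading is asserted by a dedicated test so the
  convention is explicit rather than accidental.
- **Smoothing target.** Smoothing is applied to the 4D data before PerAF
  by default; `smooth_target="peraf"` instead smooths the finished map with
  mask-normalized convolution.  Pre-PerAF smoothing is the default because
  amplitude is a nonlinear functional of the time series, so the two orders
  are not equivalent.
- **Boundary handling.** Reflect padding, which conserves per-frame flux
  to well under 0.1%.
- Realignment, slice-timing correction and spatial normalization are out
  of scope: synthetic cohorts are generated motion-free in a common grid,
  and motion enters only as a per-subject scalar trace for the exclusion
  rule.

## Group inference

The voxel-wise contrast is a pooled-variance two-sample t (patients minus
controls; df = n1 + n2 − 2), optionally a least-squares group contrast
with covariate columns (df reduced accordingly).  Cluster correction is
Monte-Carlo (AlphaSim-style):

1. Spatial smoothness of the statistical field is estimated from
   standardized within-group residual maps by the first-differences
   estimator `FWHM = voxel * sqrt(-2 ln 2 / ln(1 - var(diff)/(2 var)))`,
   averaged over maps, per axis.  Estimates are floored at one voxel:
   smoothness below the sampling lattice is unresolvable and
   unrepresentable in the null simulation, and white-noise residuals
   otherwise drive the raw formula toward zero.
2. Null fields are drawn as in-grid Gaussian white noise, smoothed to the
   estimated FWHM, re-standardized within the mask, thresholded two-tailed
   at the cluster-forming p (default 0.005), and the maximum connected
   component extent over both signs is recorded per iteration (default
   1000 iterations, seeded).
3. The extent threshold at family-wise α is the smallest integer s whose
   null exceedance fraction P(max extent ≥ s) is at most α.  This
   definition is exact at the edge cases (α = 1 gives threshold 1) and
   non-increasing in α.  Surviving clusters carry a corrected p equal to
   their null exceedance fraction.  A null computed at a different
   cluster-forming threshold or connectivity than the clusters is refused.

Connectivity defaults to 18-neighbor (the REST/AlphaSim family
convention), configurable to 6 or 26.  Cluster peaks are reported in mm
through the affine, never as raw indices.

## ROI statistics

Regional means are arithmetic means of defined in-mask voxels per label.
The AUC is the rank (Mann-Whitney) statistic with ties counted half —
identical to the trapezoidal area under the empirical ROC curve, which is
asserted exactly in tests.  Scores are auto-oriented so the reported AUC
is ≥ 0.5 (the flip is recorded), since regions with reduced and elevated
amplitude are reported on a common discriminability scale.  The 95% CI is
a stratified bootstrap percentile interval (default 2000 resamples,
seeded); DeLong's asymptotic interval is available as an alternative.
Pearson correlations use the two-tailed t-transform p on n − 2 df, with
pairwise deletion of missing values.  Summary-statistics t-tests
(`summary_t`) use the pooled form, which is the convention that reproduces
published demographic-table t values from printed mean ± SD rows.

## Synthetic cohorts

The generator emulates the study design the pipeline targets: two groups
of 17, 240 volumes at TR 2 s, 3 mm isotropic voxels on a 24×24×18 grid
(an ellipsoidal "brain" of ~5400 voxels), baseline intensity 1000, a
0.01–0.08 Hz band-limited oscillation with amplitude 3% of baseline, AR(1)
Gaussian noise with stationary SD 1% of baseline and lag-1 coefficient
0.3.  In-mask voxels follow `baseline * (1 + a_v * s_t) + eps_t`;
out-of-mask voxels are zero-mean noise.  Effects are amplitude multipliers
on labelled ROIs for one group; a per-subject lognormal factor
(sigma = 0.1) jitters every amplitude so that group discrimination and
correlation recovery are non-degenerate.  Note an interaction: because the
jitter is subject-global and multiplicative, mPerAF standardization
cancels it almost exactly, so under the pipeline default the voxel-level
contrast is nearly noise-limited (planted-effect t values are much larger
than on real data) and ROI-mean AUCs saturate at 1.0; raw PerAF
(`mperaf=False`) retains the between-subject overlap.  The jitter still
drives the phenotype linkage, which targets the true amplitude.  Phenotypes with a target
correlation r against a region's true amplitude are drawn as
`y = mean + sd * (r z + sqrt(1-r^2) eta)` where z is the amplitude
standardized across the whole cohort (n = 34); recovery checks correlate
over the same population.  Rounding and bounds (e.g. integer 0–21 scores)
are applied last and slightly attenuate the realized correlation, as for
any discretized instrument.

The oscillation is a sum of five equal-amplitude random-phase sinusoids
with frequencies uniform in the band, renormalized to unit peak amplitude;
`single_frequency_hz` replaces it with one pure sinusoid, which gives the
analytic check: a noise-free sinusoidal voxel with amplitude fraction a
has PerAF = 100·a·2/π (the mean absolute value of a sinusoid), e.g.
1.910% at a = 0.03.  The discrete-time average converges to 2/π as the
sampling gets finer; validation uses 40 samples per cycle over 10 cycles,
where the deviation is about 0.2%.

What the generator does *not* emulate: hemodynamic response shape,
cardiac/respiratory physiological noise, motion artifacts inside volumes,
scanner drift beyond a linear trend, spatial normalization error, and
anatomically realistic geometry.  Passing recovery tests therefore shows
the pipeline's statistics behave correctly under the stated noise model,
not that the effect sizes or AUCs transfer to real patient data — on real
cohorts AUC near 1.0 for a 50% planted amplitude change is expected to be
optimistic.

## Validation design and problem sizes

- Unit oracles: a literal term-by-term transcription of the PerAF formula
  (1e-12 relative agreement), exhaustive pair-counting and trapezoidal
  forms of the AUC, a BFS flood-fill labelling oracle for clusters, and the
  scalar pooled-t as the per-voxel oracle for the t map.
- Family-wise error calibration: 200 synthetic null cohorts at the default
  geometry, each analyzed by the full chain with a 1000-iteration
  Monte-Carlo null; nulls are cached per quarter-millimetre bin of the
  estimated smoothness, since the null distribution depends only on mask,
  smoothness, threshold and connectivity.  The observed rate is required
  to fall in the Monte-Carlo band [0.01, 0.12] around the nominal 0.05.
- Effect recovery: a 1.5× amplitude multiplier on a 27-voxel ROI, 17 vs 17
  subjects, 20 seeds; a corrected cluster peaking inside the ROI is
  required in at least 90% of seeds.  Phenotype linkage at target
  r = −0.8 must be recovered within ±0.25 in at least 95% of 100 seeds.
- Volumes are simulated in float32 (an intensity resolution far below the
  noise floor); all statistics are computed in float64.

## Known limitations

- The Monte-Carlo null assumes Gaussian fields; the t map with df = 32 has
  slightly heavier tails, which the matched per-voxel exceedance
  probability absorbs at the voxel level but not exactly at the cluster
  level.  The calibration test bounds the practical consequence.
- The smoothness estimator assumes a stationary Gaussian autocorrelation;
  it is biased near mask edges and floored at one voxel.
- Atlas-based anatomical labelling of clusters is not bundled; a
  user-supplied label volume is used when given.
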