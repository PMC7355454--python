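# Methods

This document describes the models implemented in `tissuefate`, the
parameters and their defaults, the synthetic phantom that stands in for
patient data, and the numerical conventions the code commits to. Nothing
here is an empirical claim beyond what the package itself computes; the
cohort-level numbers live in `results/acceptance.json` and are regenerated by
`scripts/acceptance.py`.

## 1. Problem statement

Acute ischemic stroke imaging yields, per patient, a diffusion map (ADC) that
marks the irreversibly injured core and a dynamic susceptibility-contrast
(DSC) perfusion series from which bolus-delay maps are derived. Tissue with
delayed perfusion but preserved diffusion (the penumbra) may either infarct or
be salvaged, depending chiefly on whether the occluded vessel is recanalized.
The package predicts the *fate of each voxel* — infarcted or salvaged on the
day-7 image — under two counterfactual treatment scenarios:

- **SR** — successful recanalization: most penumbra is salvaged.
- **UR** — unsuccessful recanalization: most penumbra infarcts.

Two random-forest classifiers (one per scenario) are trained on voxel-level
features from ADC and relative time-to-peak (rTTP) maps. Predicted infarct
volumes feed a clinical layer: target-mismatch classification, predicted
infarct growth, growth tertiles, and 90-day functional-outcome summaries.

## 2. Perfusion processing (`perfusion`)

**Signal to concentration.** With `S0` the per-voxel mean of the first
`n_baseline = 8` pre-bolus frames and `TE = 35 ms`,

```
C(t) = -ln(S(t) / S0) / TE .
```

Non-positive signal samples are clamped to a small positive floor
(`floor_fraction = 1e-3` of `S0`) before the logarithm so transient noise
cannot produce infinities; voxels whose baseline itself is non-positive are
flagged invalid and carry NaN concentration. The conversion is performed in
the input dtype (float32 series stay float32) with in-place ufuncs, because
the time series is by far the largest array in the pipeline.

**TTP.** Time-to-peak is `argmax` over frames times `TR = 1.5 s`. No
interpolation is applied; ties take the earliest frame. TTP is therefore
quantized to the frame grid, which bounds the achievable rTTP accuracy at one
TR.

**rTTP.** The hemisphere with the *lower* median TTP is taken as
contralateral (normal), and `rTTP = TTP − median TTP(contralateral)`. On
quantized TTP maps exact median ties between hemispheres are common; the API
accepts a `lesion_hint` and warns on ties (defaulting to the left hemisphere
as contralateral if no hint is given). The pipeline supplies the hint from
the hemisphere with the higher *mean* TTP, which is robust to median ties
because the delayed lesion tail always raises the mean.

**Threshold lesions.** Three standard masks within the brain mask:

| mask | rule | default |
| --- | --- | --- |
| core | `ADC < 600` (10⁻⁶ mm²/s) | `ADC_CORE_THRESHOLD = 600` |
| perfusion lesion | `rTTP > 4.5 s` | `RTTP_PERFUSION_THRESHOLD_S = 4.5` |
| severe delay | `rTTP > 8 s` | `RTTP_SEVERE_THRESHOLD_S = 8.0`, configurable |

rTTP is used as the delay measure throughout (no arterial-input-function
deconvolution is performed), so the perfusion-lesion and severe-delay
thresholds are rTTP surrogates for the Tmax > 6 s and Tmax > 10 s definitions
used with deconvolved maps. The severe threshold is exposed as a parameter
(`severe_threshold_s`) precisely because this surrogate mapping is
protocol-dependent. Volumes are voxel count × voxel volume / 1000 (mL).

## 3. Midsagittal plane (`geometry`)

The midline is modelled as an in-plane rotation (degrees) plus a lateral
translation (mm) of the centred vertical plane — two parameters shared by all
slices. It is estimated by maximizing a reflection-symmetry score: sample
points are reflected through the candidate plane and the normalized
cross-correlation (NCC) between original and reflected intensities
(trilinear interpolation) is the objective.

Design choices:

- **Scoring support.** Points are sampled (up to `max_points = 20 000`,
  seeded) from the brain mask *dilated* by the search range plus margin, not
  from the brain interior alone. The brain/background boundary is the
  dominant symmetry cue; interior tissue can be locally structureless, in
  which case an interior-only NCC carries almost no gradient in the
  transform parameters.
- **Optimizer.** Exhaustive coarse grid (step 1.5° / 1.5 mm over
  ±12° / ±12 mm), a fine grid (step 0.25) around the coarse optimum, then
  three-point parabolic refinement per axis. A grid search was chosen over a
  local optimizer because the NCC surface has ridge-like local optima at
  coarse voxelizations; the two-parameter grid is cheap and global.
- Angle identifiability degrades with pixel size (the boundary is the cue
  and it is voxelized); sub-0.5° recovery is expected at acquisition
  resolution (0.9375 mm pixels) but not at the coarse grids used in fast
  unit tests.

`contralateral_voxel` reflects a voxel index through the plane and rounds to
the nearest voxel, reporting whether the mirrored location falls inside the
grid; `hemisphere_masks` partitions the brain by the sign of the signed
plane distance (voxels within half a pixel of the plane belong to neither).

## 4. Voxel features (`features`)

For every candidate voxel, a 5 × 5 in-plane × 3-slice neighborhood (clipped
at volume borders) is summarized by 12 statistics — range, mean, median, min,
max, SD (n−1), skewness, excess kurtosis (population moments; defined as 0
for zero-variance neighborhoods), and the 10th/25th/75th/90th percentiles
(linear interpolation) — separately for the ADC and rTTP maps, at the voxel
itself and at its mirrored (contralateral) location. This yields the fixed
48-feature schema `12 stats × {ADC, rTTP} × {ipsilateral, contralateral}`,
ordered `adc_ipsi, rttp_ipsi, adc_contra, rttp_contra`.

NaNs (border padding, mirrored points off-grid) are excluded per
neighborhood. Feature extraction is vectorized per slice with
`sliding_window_view` over NaN-padded maps; a scalar reference path
(`neighborhood_stats`) exists and the two are cross-checked in tests.

Candidate voxels are restricted to the lesion hemisphere within a 7-slice
window centred on the slices with the most perfusion-lesion voxels (shrunk
with a warning for thinner volumes), mirroring how raters read a lesion
around its epicentre and keeping per-case matrices tractable.

**Labels and balancing.** Labels come from the day-7 infarct mask. Training
uses *per-case class balancing*: all infarcted candidate voxels plus an
equal-size seeded random subsample of non-infarcted ones. This makes voxel
accuracy interpretable against a 50 % chance level and prevents large cases
from dominating, at a known cost discussed in §8.

## 5. Models (`model`)

One `RandomForestClassifier` per scenario (default 300 trees, unlimited
depth, `sqrt` features; a small random-search tuner over a fixed space is
provided). A voxel is predicted to infarct when the forest's probability is
**≥ 0.5** (inclusive). Predicted volume is the count of predicted voxels
times the voxel volume.

Cross-validation is **patient-level** k-fold (default k = 5): cases, never
voxels, are partitioned, so no voxel from a test patient can appear in
training. Each fold trains and evaluates on balanced matrices; the report
gives per-fold accuracy, mean, SD and a normal-approximation 95 % CI.
Because test folds are also balanced, the chance level is 0.5 and a
label-shuffle control should sit at 50 %.

## 6. Clinical layer (`clinical`)

**Target mismatch** (all four required): perfusion/core volume ratio ≥ 1.8,
absolute difference ≥ 15 mL, core < 70 mL, severe-delay lesion < 100 mL.
With an empty core the ratio is undefined; it is deemed satisfied iff the
perfusion lesion is non-empty (the limit of the ratio criterion).

**Growth.** Predicted infarct growth = scenario-matched predicted final
volume − measured core volume. Tertile labels use either empirical 1/3 and
2/3 quantile cutoffs (values equal to a cutoff go to the lower group) or
fixed cutoffs (default 15 / 35 mL when fixed mode is requested:
`< low`, `[low, high)`, `≥ high`).

**Outcomes.** Favorable outcome is mRS ≤ 1 at 90 days. Summaries per group
(mismatch present/absent, growth tertiles) give n, favorable count/percent,
and the full mRS 0–6 histogram with missing values counted separately.

## 7. Agreement statistics (`evaluation`)

- **Dice** between predicted and reference masks. Two empty masks are in
  perfect agreement, so Dice is defined as 1 there (with a warning, since it
  usually indicates an upstream problem).
- **ICC(2,1)** — two-way random effects, absolute agreement, single
  measures — for predicted vs. reference volumes, computed via `pingouin`
  and cross-checked in tests against a hand-written ANOVA implementation to
  1 × 10⁻⁹. ICC(2,1) is chosen because method and reference are the same
  two "raters" for every case and *absolute* agreement (not mere
  consistency) is what volume substitution requires.
- **Bland–Altman**: mean difference (bias) and limits of agreement
  `bias ± 1.96 · SD(differences)` with SD using ddof = 1.

## 8. Synthetic phantom (`phantom`)

No patient data ships with the package; a parametric digital phantom with
known ground truth replaces it.

**Geometry.** An ellipsoidal brain on a 22 × 256 × 256 grid (0.9375 mm
pixels, 6.5 mm slices) split by a configurable midsagittal plane
(`midline_angle_deg`, `midline_shift_mm`). One hemisphere carries an
ellipsoidal hypoperfused lesion (default 90 mL) containing an ellipsoidal
low-ADC core (default 15 mL). ADC is Gaussian per compartment:
core 450 ± 50, penumbra 750 ± 50, normal 900 ± 60 (10⁻⁶ mm²/s).

**Dynamics.** The DSC signal is `S(t) = S0 · exp(−TE · C(t))` with a
gamma-variate bolus

```
C(t) = A · ((t − ta)/tp)^α · exp(α (1 − (t − ta)/tp)),   t > ta,
```

α = 3, tp = 6 s, A = 17 s⁻¹, S0 = 100, additive Gaussian signal noise
(SD 2.0). Arrival is `ta = t0·TR + delay`; normal tissue has delay 0 and
hypoperfused tissue a nominal delay of 6 s plus a *smooth* spatial jitter
field (SD 1.5 s, in-plane correlation length 7.5 mm). The jitter SD is set
at one TR so that fate differences are resolvable despite TTP quantization,
and its correlation length is specified in millimetres so phantom behaviour
is resolution-independent.

**Tissue fate.** Fate is a deterministic function of the voxel's true delay:
the final infarct under salvage fraction `f` is

```
core ∪ { penumbra : delay > ref + Φ⁻¹(f) · jitter_sd } ,
```

where `ref` is `fate_delay_ref_s` (the cohort-wide nominal delay; defaults to
the case's own `delay_s`). Thus `f` is the *expected* salvaged fraction of
penumbra, fates nest (`final_SR ⊆ final_UR` whenever `f_UR ≤ f_SR`), and —
crucially — the mapping from delay to fate is one global threshold across a
cohort, so cross-case volume prediction from rTTP features is well-posed. A
per-case quantile rule (salvaging exactly `f` of each case's penumbra) was
rejected: it makes the delay-to-fate mapping case-dependent, so no
voxel-feature classifier, however good, could recover per-case volumes.

Defaults `f_SR = 0.95` and `f_UR = 0.3` encode near-complete penumbra
salvage with recanalization and roughly 30 % salvage without, consistent
with typical clinical cohort medians (day-7 volume ≈ baseline core after
successful recanalization; most penumbra lost otherwise).

**Cohorts.** `generate_cohort` draws per-case lesion sizes log-normally
(hypoperfusion `90·LogNormal(0, 0.45)` mL clipped to [35, 220]; core
`15·LogNormal(0, 1.0)` mL clipped to [3, 70] and capped at 0.45 × the
hypoperfusion volume), varies the nominal delay by ±5 % uniformly, anchors
`fate_delay_ref_s` to the cohort nominal so the fate threshold is global,
alternates SR/UR scenario assignment, and derives per-case seeds from a
`SeedSequence` so the cohort is a pure function of one seed. The 90-day mRS
is drawn from a noisy logistic in final volume (midpoint 60 mL, scale 30 mL,
latent noise 0.7); only its monotone association with volume is meaningful.

**What the phantom does not emulate:** realistic anatomy and tissue texture,
arterial input functions and recirculation, partial-volume and susceptibility
artefacts, motion, white/grey-matter ADC structure, multifocal or cortical
lesion shapes, and any treatment-selection process linking scenario to lesion
size. Conclusions about absolute clinical performance do not transfer;
the phantom's role is to make every pipeline stage verifiable against known
truth.

## 9. Numerical conventions

- Array layout is `(frame, slice, row, col)` for dynamic series and
  `(slice, row, col)` for maps; NIfTI I/O (via `nibabel`) transposes to and
  from the on-disk `(col, row, slice[, frame])` order.
- All stochastic steps (phantom, subsampling, forests, CV partitions,
  point sampling) take explicit integer seeds; cohort generation derives
  per-case seeds with `numpy.random.SeedSequence`. Seeds are kept below
  2³¹ for portability.
- Percentiles use sorted-sample linear interpolation; SD uses ddof = 1;
  skewness/kurtosis use population moments with a relative-epsilon
  zero-variance guard.
- Fast test and script configurations use a 128 × 128 in-plane grid with
  1.875 mm pixels — the same 240 mm field of view at half resolution — so the
  full pipeline runs in minutes on one CPU; geometry accuracy checks that
  need sub-pixel identifiability run at the full 256 × 256 grid.

## 10. Known limitations

- **SR volume bias.** Balanced per-case training combined with the fixed
  p ≥ 0.5 decision threshold systematically over-includes salvaged penumbra:
  the balanced prior inflates the infarct class, and the effect scales with
  the amount of penumbra at risk. It is mild for UR (most penumbra really
  does infarct) but material for SR, where the true final lesion is small
  and the at-risk region large. Consequently volume agreement is
  systematically weaker for the SR model than the UR model (see
  `results/acceptance.json`), with a positive SR volume bias. Recalibrating
  the threshold or training unbalanced would reduce this bias but would
  change the method; the package keeps the method fixed and reports the
  bias.
- TTP quantization at TR = 1.5 s bounds rTTP accuracy and creates a
  confusion band of width ≈ one TR around the fate threshold.
- rTTP is a non-deconvolved delay measure; threshold values are not
  numerically interchangeable with Tmax-based ones.
- The mRS model in the phantom supports only monotone association checks,
  not calibration of outcome probabilities.
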