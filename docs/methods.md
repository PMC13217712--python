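# Methods

This note documents the models, the generative assumptions behind the
synthetic cohorts, the numerical choices, and the limits of what the
test suite demonstrates.

## 1. The idiosyncrasy metric

Participant *i* is summarized by an activation vector `v_i ∈ R^K`
(per-parcel means of a contrast statistic map). The correlational
distance `d_ij = 1 − r(v_i, v_j)` uses the sample Pearson correlation
(the n−1 convention; the normalization cancels in r). Distances are
computed for all pairs at once via the correlation matrix, symmetrized,
and the diagonal forced to zero; a brute-force double-loop oracle is
kept in the tests and agreement is asserted to 1e−12 up to n = 50,
K = 300.

Variability scores are means of `d_ij` over a reference set with the
self-distance excluded in every scheme, including the control-referenced
score for control participants (whether the original analyses included
self there is ambiguous; exclusion is the consistent choice and is what
this package does everywhere). Vectors enter raw — no row z-scoring or
parcel-wise standardization — since the correlation is already
location/scale free per participant (affine invariance `v → a·v + b`,
a > 0, is a tested property).

Empty reference sets (e.g. a singleton group under the within scheme)
are hard errors, as are zero-variance vectors and NaN cells; upstream
stages must resolve empty parcels first.

## 2. Synthetic cohort generator

The generator exists so that every downstream stage has data with the
statistical structure the analysis assumes. Its model:

```
v_i = a_i · T + e_i,   e_i ~ N(0, σ_i² I_K)
σ_i = σ_group(i) · exp(β_age · (age_i − age_mid)) · ε_i,
ε_i ~ LogNormal(0, τ)
```

* `T` — canonical contrast template, drawn once per cohort,
  `N(0, 1)` per parcel.
* `a_i` — template weight, `N(1, 0.1)`.
* `σ_group` — the group deviation scale; the default three-group preset
  uses 1 : 1.1 : 2 (controls : intellectually able : intellectually
  impaired), putting the amplification in the impaired group.
* `β_age = −0.02 / year` — older participants deviate less (the
  direction of the reported age effect); the slope is constrained ≤ 0.
* `τ = 0.25` — individual heterogeneity of the deviation scale. Without
  it, variability scores (means over ~80 pairwise distances) have
  unrealistically small within-group spread and group effect sizes
  explode (d ≈ 5 instead of the 1–3 regime typical of such studies).

Mean framewise displacement is log-normal (median per group ≈ 0.065–
0.087 mm, log-sd 0.3): positive and right-skewed, as FD distributions
are. Ages are truncated-normal (mean 17, sd 6) on 8–30 years. The
"table1" preset reproduces the reference cohort's composition: group
sizes 33/28/19, male:female 25:8 / 25:3 / 19:0 (the impaired group
all-male in that preset only; the balanced preset mixes sexes), and
ADHD co-occurrence in the autistic groups only.

Behavioural scores are generated from the *latent deviation scale* σ_i
through linear, quadratic or null links plus noise. Intercepts and
slopes are set so group means track the reference cohort's demographics
(e.g. adaptive-function composite ≈ 113/91/67 across the three groups).
Two distributional constraints are deliberate, because the downstream
battery keys on them: the four measures modelled as linear terms
(ADHD symptoms, executive function, adaptive function, observational
severity) get Gaussian noise with a signal/noise ratio that keeps their
marginals near-normal, while the four smooth-term measures (social
responsiveness, repetitive behaviour, sensory profile, non-verbal IQ)
get quadratic links and centered log-normal (skewed) noise so a KS gate
reliably routes them to splines. The gate is a level-0.05 test, so any
single cohort can misroute a measure; tests assert the classification as
a majority across replicate cohorts.

Scores are *not* clamped to instrument ranges — they are continuous
stand-ins, not simulated questionnaires.

What the generator does **not** emulate: spatial autocorrelation within
parcels (signal is parcel-constant), serial correlation in BOLD noise,
scanner drift, physiological noise, distance-dependent motion artefacts,
or any multi-echo structure. Passing tests therefore demonstrate the
*statistical machinery* (estimators, error calibration, power under the
assumed generative model), not robustness to real-data artefacts.

## 3. First-level GLM

Block timeline: 20-s fixation, twelve 24-s alternating condition blocks
with no inter-stimulus interval, 20-s fixation (328 s total). With
TR = 1.32 s, 248 whole frames fit the timeline; the acquired frame
count for the original task is not public, so synthetic runs use
`floor(total / TR)`.

Condition boxcars are convolved with a canonical double-gamma HRF on a
0.1-s grid and sampled at frame times. The HRF is the difference of two
gamma densities scaled to peak amplitude 1, with the lobes parameterized
by their *mode* (response peak 6 s, undershoot trough ≈ 16 s,
undershoot ratio 1/6, unit dispersions). Parameterizing by mode rather
than by the gamma shape parameter pins the peak exactly at 6 s; the
shape correlates > 0.9 with the SPM-convention HRF and either choice is
"canonical" in the field's usage.

Estimation is ordinary least squares per unit with i.i.d. errors: no
AR(1) prewhitening and no high-pass filter (an optional linear drift
column exists, off by default). This is deliberate — the package's
validation targets structural correctness on synthetic data, where the
noise *is* white; serial-correlation correction would add machinery
that nothing downstream exercises. Rank-deficient designs are rejected
with the collinear columns named. t-contrasts use
`t = c'β̂ / sqrt(σ̂² · c'(X'X)⁻¹c)` with dof = frames − rank(X).

A per-run mean-FD regressor is accepted but off by default: it is
constant within a run and therefore exactly collinear with the
intercept. Mean FD instead enters the group-level models as a
covariate, which is where it is statistically identifiable.

Condition order (which condition opens the run) is configurable; the
default starts with the biological-motion block.

## 4. Parcellation and motion exclusion

The parcel summary is the arithmetic mean of map voxels per label (the
field convention for "summarizing" a statistic map over an ROI).
Composite atlases offset each component's labels by the cumulative
prior count (cortical 1–200, subcortical 201–250, cerebellar 251–284).
Labels must be the contiguous range 1..K; gaps are an error unless
`relabel=True`. Background (label 0) never contributes. Grids are
assumed voxel-aligned — no resampling is implemented, since spatial
normalization is upstream of this package.

The motion-exclusion rule removes participants whose mean FD exceeds
mean + 2 SD of the *retained* sample, recomputing after each pass until
stable ("iterative" read as repeat-until-stable). On a log-normal FD
sample this trims ~8–13% regardless of scale — a property of iterative
trimming on skewed data, not a bug; the pipeline applies it before all
statistics.

## 5. Group inference

The ANCOVA is the linear model `score ~ group + age + sex + FD` with
Type-II sums of squares (identical to Type III here: one factor, no
interactions). Sex enters as a male indicator; covariates that are
constant in a subset (e.g. sex in a male-only run) are dropped
automatically. η_p² = SS_effect / (SS_effect + SS_residual) holds by
construction and is cross-checked against an independent ANCOVA
implementation (pingouin) in the tests. Adjusted group means are model
predictions at sample-mean covariate values.

Post-hoc tests refit each pair as a two-group ANCOVA; corrected
p = min(1, raw p × m) with m = 3 for the three-group analysis
(configurable); Cohen's d = adjusted mean difference / pooled residual
SD of the pairwise model — a definition chosen here because the source
analyses report d alongside ANCOVA without defining its computation.

ROI-level group contrasts use Freedman–Lane residual permutation:
covariate effects are estimated once, the reduced-model residuals are
shuffled and re-residualized, and the family-wise error p per ROI is
`(1 + #{max_b |t*| ≥ |t|}) / (B + 1)` — bounded in [1/(B+1), 1] and
exactly reproducible under a fixed seed. This is a deliberate
simplification of voxelwise nonparametric cluster inference (TFCE and
cluster-level machinery are out of scope); the one-sample analogue uses
sign flipping.

## 6. Brain–behaviour battery

Each measure predicts the variability score controlling for age
(linear), sex (indicator) and mean FD (penalized spline, df = 6 — FD
failed normality in the reference analysis and is always smooth).
The measure's own term kind comes from a Lilliefors-corrected KS test
at α = 0.05 (estimated mean/SD; table p-values): pass → linear,
fail → cubic B-spline with basis dimension 6. Penalty weights are
selected by AIC over the log-grid 10⁻³…10³ — a pragmatic stand-in for
REML-type smoothness selection that costs seven small fits per model.

Linear terms report the coefficient and its t-test from the penalized
fit; smooth terms report a Wald test of the spline block using
effective degrees of freedom (statistic scaled to an approximate F).
R² is reported as the adjusted proportion of variance explained, with
model degrees of freedom taken as the total effective dof of the
penalized fit. Complete cases are taken per measure (battery-wide
listwise deletion would discard controls lacking an observational
severity score). The battery is FDR-corrected per variability scheme
(whole/within/control-referenced are separate batteries), and
`force_linear=True` reproduces the all-linear sensitivity analysis.

BH-FDR itself is the standard step-up adjustment (via statsmodels),
verified against a brute-force implementation of the definition for
m ≤ 20.

## 7. Pipeline, seeding, reproducibility

A single global seed deterministically derives per-stage seeds by
hashing the stage name (CRC-32, reduced mod 2³¹), so any stage can be
rerun in isolation with identical results. All tables are TSV with
floats at 12 significant digits; the run manifest records config,
stage seeds and SHA-256 hashes of every table, and rerunning a config
reproduces every hash.

## 8. Problem sizes used in validation

Simulation-based checks use cohorts of 20–60 per group, 40–284 parcels,
100–1000 replicates, and 100–300 permutations — sizes at which the
Monte-Carlo error of the checked rates is small relative to their
acceptance margins while the whole suite runs in a couple of minutes.
Calibration assertions on empirical rates allow two Monte-Carlo
standard errors of the replicate count around the nominal level.

## 9. Known limitations

* OLS first level: no prewhitening; t-statistics from autocorrelated
  real BOLD would be mildly optimistic.
* The generative model is parcel-constant and spatially white; it
  cannot probe atlas misalignment, partial-volume effects, or
  smoothing choices.
* GAM smooth-term p-values are Wald approximations with effective dof —
  adequate for FDR screening, not exact small-sample inference.
* The observational severity score is modelled as a continuous linear
  term; an ordinal re-analysis is out of scope.
* Group labels, not individually estimated diagnoses, drive the
  stratified presets; misclassification effects are not modelled.
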