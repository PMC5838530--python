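# Methods

This note documents the models implemented in `rtnf`, the choices made
where the design was genuinely open, and what the synthetic-data tests do
and do not establish about real data.

## Hemodynamic model and baseline weighting

The impulse response is the canonical double gamma,
`h(t) = γ(t; a₁, b₁) − c·γ(t; a₂, b₂)` with shape/rate defaults
(6, 1) for the peak, (16, 1) for the undershoot and c = 1/6, giving a peak
near 5 s and an undershoot near 15 s. These are community-standard values;
all five parameters are configurable (`HrfParams`). Regressors are built by
discrete convolution of block boxcars with `h` sampled at TR resolution
(32 s kernel, no microtime upsampling) — adequate for 16–30 s blocks at
TR = 1 s.

The real-time baseline is a weighted average of the ROI signal over the
preceding 30 s baseline block. Weights are `h` sampled at times since block
onset, floored at zero and normalized to sum to 1, so the baseline is a
convex combination of observed samples that emphasizes the part of the
block where a response to the block itself would peak. Whether the original
system weighted by the response shape itself or by the block-convolved
response is unknowable from the protocol description; both are implemented
(`baseline_weights(..., mode="hrf" | "convolved")`) and "hrf" is the
default. Flooring the undershoot at zero keeps the estimate a convex
combination; the convolved alternative is essentially flat over a 30 s
block and behaves like an ordinary mean.

## The feedback loop

A neurofeedback run is baseline (30 s) → response (16 s) → upregulation
(30 s) repeated five times, closed by one more baseline + response pair:
6/6/5 blocks, 426 volumes. The protocol states the blocks are interleaved
and that response blocks let the hemodynamic response return to baseline
before upregulation; the repeating-triplet order is the one consistent with
both statements. A consequence worth knowing: each baseline block directly
follows an upregulation block, so with a strong planted amplitude the
baseline estimate carries the decaying response tail and displayed PSC
settles below the planted amplitude (≈0.79% for a planted 1% at the
defaults). The engine, the offline contrast GLM and the acceptance oracle
all share this geometry, so the attenuation cancels in comparisons.

Display cadence: volumes arrive every TR (1 s) but the bar updates on
average every 1.5 s; this is realized exactly as alternating 1 s/2 s gaps
(20 samples per 30 s block). Shaping: after each upregulation block the
full-scale value becomes `max(block max displayed PSC, ε)` with
ε = 0.1% — the floor, and the first-block scale S₀ = 1.0%, are
configuration values the protocol leaves unspecified; something positive
must be displayed before any history exists. The block maximum is taken
over *displayed* samples (the participant-visible quantity is what shaped
behaviour), and saturation is assumed when PSC exceeds the current scale
mid-block. No real-time motion correction or incremental GLM is modelled;
the engine consumes reconstructed volumes.

## ROI selection and group masks

The localizer GLM is voxelwise OLS with
`t = c'β̂ / √(σ̂² c'(X'X)⁻¹c)`; ROI selection keeps voxels with t
*strictly* above 3 ("greater than") inside an anatomical constraint, and an
empty selection warns rather than errors because per-visit redraws
legitimately vary in size. Group masks include a voxel present in ≥ k
per-visit/participant masks (k = 1, the inclusive-OR reading, by default).
Since all synthetic data share one grid, the original normalize-and-smooth
step before mask union reduces to the union itself; spatial smoothing is
available (`smooth_volume`, Gaussian FWHM in mm) and is never applied in
the real-time path. Spatial normalization/registration is out of scope.

## Offline statistics

*Scrubbing.* Scan-to-scan displacement is the maximum absolute parameter
change per volume, rotations converted to worst-case surface displacement
on a 50 mm sphere. This specific metric is a documented convention (the
original artifact-repair tool's formula is not published in the protocol);
thresholds are strict: spikes at > 1 mm, run exclusion at > 2 mm.

*Contrasts.* Each run's GLM holds intercept, centered linear drift,
plateau-scaled upregulate and response regressors, and nuisance columns
(six motion parameters + spike one-hots). The upregulate beta divided by
the voxel's intercept ×100 puts the contrast in PSC units; the ROI value is
the mean over masked voxels.

*Trend model.* Per-run ROI contrasts are fit with
`statsmodels` MixedLM: random intercept per participant, fixed visit + run
+ age + caudate %ICV, REML estimation. Wald tests use t with residual
degrees of freedom (observations − fixed-effect parameters); statsmodels
provides no Satterthwaite approximation, and the convention is recorded in
the result object (`dof_method`). Monte Carlo calibration at 10
participants × 4 visits × 4 runs: 95% CI coverage ≈ 0.96, type-I rate
≈ 0.056 at α = .05 (recomputed in the test suite). Constant-response input
short-circuits to an exact zero slope with a `singular` flag.
`random_intercept=False` gives the constrained OLS fit.

*PPI.* The interaction regressor is the elementwise product of the
mean-centered seed series and the centered HRF-convolved condition
regressor — no deconvolution, matching the described construction. The
first-level model is OLS on [1, seed, condition, interaction, nuisance];
second-level change is the same mixed trend model applied to PPI betas.

*Behaviour regression.* Voxelwise OLS of per-participant activation-change
maps on composite-score change plus confounds; voxels with one-sided
p < .001 for a positive effect form 26-connected clusters. Random-field
FWE inference is out of scope; an optional max-cluster-size permutation
null (permuting the composite change) provides a self-contained
cluster-level p.

## Clinical scores

CAP = 100·age·(CAG − 30)/627, exact internally, rounded for display.
Composite: the seven measures are harmonized so larger is better (annulus
length log-transformed; ITI, log SD IOI and log SD dMTI negated), z-scored
against reference norms, and averaged. The packaged default norms are a
**synthetic** stand-in for an independent early-HD normative sample —
plausible means/SDs on the harmonized scale, replaceable via JSON; only
relative composite statements should be read off them. The dMTI formula is
not fully specified by its originating battery description; it is
implemented as the SD of deviations of inter-tap midpoints from an
index-matched target-rhythm midpoint grid anchored at the first tap, and
the definition is isolated in one function so an alternative convention can
be swapped in. Perfectly periodic tapping has zero variance and raises
rather than returning −∞. Partial Spearman rank-transforms all three
variables, residualizes the x- and y-ranks on the control ranks by OLS and
correlates the residuals; a constant control reduces to plain Spearman.

## Synthetic data: what it emulates, and what it does not

Runs: baseline level fixed at 100 signal units so planted amplitudes are
PSC; active voxels get `100·(1 + amp/100·x(t))` with `x` the plateau-scaled
convolved regressor; all voxels get stationary AR(1) (φ = 0.3) driven by
white noise (σ = 1 signal unit, i.e. 1% of baseline), optional linear
drift, started from the stationary distribution. Motion is small Gaussian
noise on six parameters with step spikes planted on the first translation.
Cohorts: a Gaussian copula (Pearson r = 2·sin(πρ/6) to hit a target
Spearman ρ) links a disease-burden latent to caudate %ICV; sampled
(age, CAG) pairs are reordered so CAP is a monotone image of the burden
latent — guaranteeing the sign and size of the rank correlation without
distributional assumptions; the seven measures are linear in caudate volume
plus noise, with defaults (e.g. Stroop ≈ 85 ± 6 correct, speeded-tapping
ITI ≈ 0.28 s) chosen as plausible early-HD values. The default caudate–CAP
target correlation is −0.86.

Not emulated: anatomy and tissue contrast, susceptibility and slice-timing
effects, physiological (cardiac/respiratory) noise, spatially correlated
noise, registration error, practice effects. Passing tests therefore
establish the *computational* correctness and statistical calibration of
the pipeline under known generative conditions — not robustness to the
full noise structure of real fMRI.

## Study replay and problem sizes

`replay_study` runs cohort → per-visit localizer + ROI redraw → feedback
runs → scrubbing + contrasts → trend, PPI and behaviour regression →
composite change, all derived from one seed (per-stage sub-seeds via
SHA-256). The default desk scale is 5 participants × 3 visits × 3 runs on
a 12 × 12 × 8 grid — the smallest configuration consistent with the
protocol's visit/run structure that still exercises every stage, sized so
repeated power simulations (50 replicates ≈ 1 s each) remain routine.
Per-participant learning slopes are drawn N(mean, sd) *untruncated*
(sd = 0.1 by default), reflecting the observed between-participant
variability while keeping a zero-mean configuration symmetric. One caveat
the simulations expose: with between-participant slope *heterogeneity* and
no mean learning, the random-intercept-only trend model (the model the
protocol specifies) is anti-conservative, because slope variance is not in
the model; the no-learning null is therefore the configuration with all
slopes zero. A random-slope extension would address this and is a known
limitation, not implemented.

The replay's PPI stage reads coupling between the target ROI and a distant
control region; the default generator plants no coupling change, so this
stage demonstrates null behaviour unless the user supplies coupled series.

## Numerical conventions

Baseline weights renormalized to sum to 1 within 1e−12; engine arithmetic
in float64 even for float32 volumes (online and offline recomputations
agree to 1e−9); GLM via explicit normal equations with full-rank checks;
t = 0 returned where both effect and residual variance vanish (0/0);
strict inequalities at every threshold (t > 3, > 1 mm, > 2 mm); ties in
ranks handled by average ranks. Degenerate inputs (empty masks, constant
correlation inputs, zero tapping variance, missing conditions, rank
deficiency, dof ≤ 0) raise `ValueError` rather than propagating NaNs.
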