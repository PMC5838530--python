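# rtnf — real-time fMRI neurofeedback training and analysis

`rtnf` re-implements, as a tested Python library, the computational core of a
closed-loop real-time fMRI neurofeedback protocol for Huntington's disease
(HD) and its downstream analyses. Patients in such a protocol watch a
thermometer bar whose height tracks the BOLD percent signal change (PSC) of
their supplementary motor area (SMA) and learn, over repeated training
visits, to drive it up. The package is for methods researchers who want to
study, extend or stress-test the pieces of that loop — the feedback signal,
the operant shaping rule, the ROI definition, and the longitudinal
statistics — on synthetic data with known ground truth.

## What it computes

**Feedback signal.** During an upregulation block the displayed quantity is

    PSC(t) = 100 · (s(t) − b) / b

where `s(t)` is the mean signal over the target ROI and `b` is the activity
of the *preceding 30 s baseline block*, averaged with weights proportional
to the canonical double-gamma hemodynamic response
`h(t) = γ(t; a₁, b₁) − c·γ(t; a₂, b₂)` sampled across the block (negative
lobe floored at zero, normalized to sum to 1). Response blocks never enter
the baseline. The bar updates on average every 1.5 s (alternating 1 s/2 s
gaps at TR = 1 s); only increases are displayed:
`bar = clip(PSC, 0, S) / S`.

**Shaping.** After every upregulation block the thermometer full-scale value
is reset to that block's maximum displayed PSC, `S ← max(maxPSC, ε)`: weak
blocks make the next bar easier to fill, strong blocks make it harder.

**ROI definition.** A fist-clenching localizer is fit voxelwise by OLS and
the clench-versus-rest t-map is thresholded at t > 3 inside an anatomical
constraint; per-visit ROIs are combined by inclusive OR into a group mask;
6 mm sphere seeds support connectivity analyses.

**Offline statistics.** Scan-to-scan movement > 1 mm becomes one-hot spike
regressors (runs > 2 mm are excluded); per-run upregulate-versus-baseline
contrasts feed a linear mixed model (random intercept per participant,
fixed visit and run effects, age and caudate %ICV as confounds) testing for
learning across visits; PPI terms (centered seed × centered HRF-convolved
condition, no deconvolution) quantify condition-dependent coupling;
voxelwise regression relates activation change to clinical change.

**Clinical scores.** The CAP disease-burden index
`CAP = 100 · age · (CAG − 30) / 627`, Spearman and partial Spearman
correlations, Q-Motor tapping-variability measures, and a composite score:
the mean of seven direction-harmonized, reference-standardized
cognitive/motor measures.

**Synthetic data.** Block-design BOLD runs (AR(1) + drift + white noise,
planted upregulation amplitude growing across visits, motion spikes),
HD-like cohorts with a controlled caudate–CAP rank correlation, and paced
tap sequences — each paired with its ground truth, so every downstream
stage has exact oracles.

## Worked example

```python
from rtnf import (AcquisitionGrid, SimulationTruth, default_roi_voxels,
                  simulate_run, run_feedback)

grid = AcquisitionGrid(shape=(12, 12, 8))
truth = SimulationTruth(roi_voxels=default_roi_voxels(grid),
                        base_amplitude=1.0, learning_slope=0.0,
                        ar_coefficient=0.0, noise_sd=0.0)
run, motion = simulate_run(truth, grid=grid, seed=0)
trace = run_feedback(run, truth.roi_mask(grid))
print(trace.block_summary.round(3))
```

prints

```
 block_index  scale_used  max_psc  scale_next
           0       1.000    1.144       1.144
           1       1.144    0.789       0.789
           2       0.789    0.789       0.789
           3       0.789    0.789       0.789
           4       0.789    0.789       0.789
```

Reading: with a planted 1% amplitude and no noise, the first block's
maximum displayed PSC is 1.14% (the baseline preceding it is clean), so the
shaping rule raises the full-scale value from its initial 1.0 to 1.14.
Later baselines sit inside the decaying tail of the previous upregulation
block, so displayed PSC settles at 0.79% and the scale follows it — the
operant staircase at work. `examples/` contains five narrative scripts
(feedback loop, cohort/composite, localizer ROI, trend + PPI, full study
replay), each printing the numbers it computes and what they mean.

A thin CLI mirrors the library: `rtnf sim cohort|run|taps`, `rtnf feedback`,
`rtnf localize`, `rtnf analyze trend|scrub`, `rtnf composite`,
`rtnf correlate`, `rtnf replay`, `rtnf fixtures`.

## Layout

- `src/rtnf/hemodynamics.py` — double-gamma HRF, block designs, convolution, baseline weights
- `src/rtnf/realtime.py` — the closed feedback loop (PSC, shaping, display cadence)
- `src/rtnf/localizer.py` — voxelwise GLM, t-thresholded ROI selection, masks, sphere seeds
- `src/rtnf/offline.py` — scrubbing, contrasts, mixed-model trends, PPI, behaviour regression
- `src/rtnf/clinical.py` — CAP, composite, tapping measures, (partial) Spearman
- `src/rtnf/simulate.py` — synthetic cohorts, BOLD runs, tap sequences with ground truth
- `src/rtnf/study.py` — end-to-end study replay and fixture generation
- `docs/methods.md` — the model, its assumptions, parameter choices and limitations
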