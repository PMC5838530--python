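"""End-to-end study replay on synthetic data.

Runs the whole pipeline at desk scale — cohort, per-visit localizer and
ROI redraw, feedback runs, offline contrasts, mixed-model trend, PPI
trend, composite change and behaviour regression — and prints the
headline results.
"""

from rtnf import StudyConfig, replay_study

cfg = StudyConfig(seed=1)  # 5 participants x 3 visits x 3 runs, 12x12x8 grid
report = replay_study(cfg)

eff = report.trend.effect("visit")
print(f"Replayed study (seed {cfg.seed}, planted mean learning slope "
      f"{cfg.learning_slope_mean} PSC%/visit):")
print(f"  visit effect: {eff.estimate:.3f} PSC%/visit, "
      f"t({int(eff.df)}) = {eff.tvalue:.2f}, p = {eff.pvalue:.2g}")
print(f"  learning detected: {report.learning_detected()}")
print(f"  runs analysed: {len(report.contrasts)} "
      f"(excluded for motion: {len(report.excluded_runs)})")
print(f"  per-visit ROI sizes: {report.roi_sizes.n_voxels.tolist()}")

print("\nComposite score change (post - pre) per participant:")
print(report.composite_change.round(3).to_string(index=False))

p_eff = report.ppi_trend.effect("visit")
print(f"\nPPI connectivity visit trend: {p_eff.estimate:.4f}/visit, "
      f"p = {p_eff.pvalue:.2f} (no coupling change is planted here)")
print(f"behaviour-regression clusters above threshold: {len(report.behavior.clusters)}")
print(
    "\nEvery number above is reproducible from (config, seed); rerunning\n"
    "with the same seed yields an identical report."
)
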