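"""End-to-end study replay on synthetic data.

Wires every stage together the way the original protocol ran: simulate a
cohort, then per visit run a fist-clenching localizer, threshold its
t-map to draw the target ROI, replay the closed-loop feedback engine
over each training run, estimate offline upregulate-versus-baseline
contrasts with the group (union) mask, and finally fit the across-visit
mixed-model trend, the PPI connectivity trend, the composite-score
change and its voxelwise behaviour regression.  Everything is a pure
function of the configuration and a single seed.
"""

from __future__ import annotations

import json
import hashlib
from dataclasses import dataclass, field, replace, asdict

import numpy as np
import pandas as pd

from . import clinical
from .clinical import MeasurePanel, composite, default_reference_norms
from .hemodynamics import HrfParams, localizer_design, neurofeedback_design
from .localizer import RoiMask, RoiSelectConfig, fit_glm, select_roi, sphere_seed, union_mask
from .offline import (
    behavior_regression,
    block_contrast,
    connectivity_change,
    fit_ppi,
    ppi_terms,
    run_exceeds_motion,
    spike_regressors,
    visit_trend,
)
from .realtime import EngineConfig, run_feedback
from .simulate import (
    AcquisitionGrid,
    CohortSpec,
    SimulationTruth,
    cohort_panels,
    default_roi_voxels,
    simulate_cohort,
    simulate_run,
)

__all__ = ["StudyConfig", "StudyReport", "replay_study", "make_fixtures"]


@dataclass(frozen=True)
class StudyConfig:
    """Conditions of a replayed training study.

    Desk-scale defaults: 5 participants, 3 training visits of 3
    neurofeedback runs each on a 12 x 12 x 8 voxel grid — small enough
    for repeated power simulations while keeping the full run structure
    (426 volumes, 6/6/5 blocks) intact.  ``learning_slope_mean`` is the
    population mean growth of the planted upregulation amplitude in PSC
    % per visit; per-participant slopes vary with SD
    ``learning_slope_sd`` (learning ability differs between people).
    ``transfer_gain`` converts realized learning into improvement of the
    cognitive/motor measures after training.
    """

    n_participants: int = 5
    n_visits: int = 3
    n_runs: int = 3
    grid: AcquisitionGrid = field(
        default_factory=lambda: AcquisitionGrid(shape=(12, 12, 8))
    )
    base_amplitude: float = 0.5
    learning_slope_mean: float = 0.3
    learning_slope_sd: float = 0.1
    noise_sd: float = 1.0
    ar_coefficient: float = 0.3
    localizer_amplitude: float = 3.0
    transfer_gain: float = 0.5
    transfer_noise_sd: float = 0.15
    t_threshold: float = 3.0
    spike_threshold: float = 1.0
    run_exclusion_threshold: float = 2.0
    voxel_p: float = 0.001
    engine: EngineConfig = field(default_factory=EngineConfig)
    hrf: HrfParams = field(default_factory=HrfParams)
    cohort: CohortSpec | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not 3 <= self.n_visits <= 4:
            raise ValueError("n_visits must be 3 or 4")
        if not 3 <= self.n_runs <= 4:
            raise ValueError("n_runs must be 3 or 4")
        if self.n_participants < 3:
            raise ValueError("n_participants must be >= 3")


@dataclass
class StudyReport:
    """All stage outputs of one replayed study, plus provenance."""

    cohort: pd.DataFrame
    contrasts: pd.DataFrame  # subject, visit, run, roi_contrast, age, caudate_pct_icv
    trend: object  # TrendModelResult for the ROI contrasts
    ppi_betas: pd.DataFrame
    ppi_trend: object
    composite_change: pd.DataFrame  # subject, composite_pre, composite_post, change
    behavior: object  # ClusterTable
    excluded_runs: list
    roi_sizes: pd.DataFrame  # subject, visit, n_voxels
    feedback_summaries: pd.DataFrame
    config_hash: str
    seed: int

    def learning_detected(self, alpha: float = 0.05) -> bool:
        """Positive, significant visit effect on the target-ROI contrast."""
        eff = self.trend.effect("visit")
        return bool(eff["estimate"] > 0 and eff["pvalue"] < alpha)


def _subseed(seed: int, *tags) -> int:
    """Stable per-stage integer seed below 2**31."""
    h = hashlib.sha256(("/".join(map(str, (seed,) + tags))).encode()).digest()
    return int.from_bytes(h[:4], "little") % (2**31)


def _anatomical_prior(grid: AcquisitionGrid, half_width: int = 3) -> RoiMask:
    """Box around the grid center standing in for the anatomical SMA mask."""
    mask = np.zeros(grid.shape, dtype=bool)
    c = [s // 2 for s in grid.shape]
    sl = tuple(
        slice(max(0, ci - half_width), min(s, ci + half_width + 1))
        for ci, s in zip(c, grid.shape)
    )
    mask[sl] = True
    return RoiMask(mask, grid.voxel_size)


def _control_region(grid: AcquisitionGrid) -> np.ndarray:
    """A corner cube far from the planted target, for connectivity readout."""
    mask = np.zeros(grid.shape, dtype=bool)
    mask[1:3, 1:3, 1:3] = True
    return mask


def replay_study(cfg: StudyConfig | None = None) -> StudyReport:
    """Run the whole study pipeline on synthetic data.

    Deterministic in ``(cfg, cfg.seed)``; every stage derives its own
    sub-seed from the global one.
    """
    cfg = cfg or StudyConfig()
    grid = cfg.grid
    cohort_spec = cfg.cohort or CohortSpec(
        n_participants=cfg.n_participants, seed=_subseed(cfg.seed, "cohort")
    )
    cohort_spec = replace(cohort_spec, n_participants=cfg.n_participants)
    cohort = simulate_cohort(cohort_spec)
    subjects = list(cohort["participant"])
    rng = np.random.default_rng(_subseed(cfg.seed, "slopes"))
    slopes = rng.normal(cfg.learning_slope_mean, cfg.learning_slope_sd, len(subjects))

    roi_voxels = default_roi_voxels(grid)
    anat = _anatomical_prior(grid)
    control_mask = _control_region(grid)
    roi_cfg = RoiSelectConfig(t_threshold=cfg.t_threshold, anatomical_mask=anat)
    loc_design = localizer_design(tr=grid.tr)

    contrast_rows = []
    ppi_rows = []
    roi_size_rows = []
    fb_rows = []
    excluded = []
    subject_masks: dict[str, list[RoiMask]] = {s: [] for s in subjects}
    change_maps = {}

    for s_idx, subj in enumerate(subjects):
        truth = SimulationTruth(
            roi_voxels=roi_voxels,
            base_amplitude=cfg.base_amplitude,
            learning_slope=float(slopes[s_idx]),
            ar_coefficient=cfg.ar_coefficient,
            noise_sd=cfg.noise_sd,
        )
        age = float(cohort.loc[s_idx, "age"])
        caud = float(cohort.loc[s_idx, "caudate_pct_icv"])
        visit_mean_maps = {}

        for visit in range(1, cfg.n_visits + 1):
            # functional localizer and per-visit target ROI
            loc_truth = replace(
                truth,
                base_amplitude=cfg.localizer_amplitude,
                learning_slope=0.0,
            )
            loc_run, _ = simulate_run(
                loc_truth,
                design=loc_design,
                grid=grid,
                seed=_subseed(cfg.seed, subj, visit, "loc"),
                participant=subj,
                visit=visit,
                active_kind="clench",
            )
            loc_contrast = block_contrast(
                loc_run,
                np.ones(grid.shape, dtype=bool),
                hrf=cfg.hrf,
                active_kind="clench",
                rest_kind="rest",
                other_kinds=(),
            )
            tmap = loc_contrast.tmap.reshape(grid.shape)
            visit_mask = select_roi(tmap, roi_cfg)
            if visit_mask.n_voxels == 0:
                visit_mask = RoiMask(truth.roi_mask(grid), grid.voxel_size)
            subject_masks[subj].append(visit_mask)
            roi_size_rows.append(
                {"subject": subj, "visit": visit, "n_voxels": visit_mask.n_voxels}
            )

            run_maps = []
            for run_no in range(1, cfg.n_runs + 1):
                run, motion = simulate_run(
                    truth,
                    grid=grid,
                    seed=_subseed(cfg.seed, subj, visit, run_no),
                    participant=subj,
                    visit=visit,
                    run=run_no,
                )
                if run_exceeds_motion(motion, cfg.run_exclusion_threshold):
                    excluded.append((subj, visit, run_no))
                    continue
                spikes = spike_regressors(motion, cfg.spike_threshold)
                nuisance = np.column_stack([motion.to_numpy(), spikes.regressors]) \
                    if spikes.regressors.size else motion.to_numpy()

                trace = run_feedback(run, visit_mask, cfg.engine, cfg.hrf)
                fb = trace.block_summary
                fb.insert(0, "run", run_no)
                fb.insert(0, "visit", visit)
                fb.insert(0, "subject", subj)
                fb_rows.append(fb)

                bc = block_contrast(run, visit_mask, hrf=cfg.hrf, nuisance=nuisance)
                contrast_rows.append(
                    {
                        "subject": subj,
                        "visit": visit,
                        "run": run_no,
                        "roi_contrast": bc.roi_contrast,
                        "age": age,
                        "caudate_pct_icv": caud,
                    }
                )
                # voxelwise PSC map over the anatomical prior for change maps
                bc_map = block_contrast(run, anat, hrf=cfg.hrf, nuisance=nuisance)
                vol = np.zeros(grid.shape)
                vol[anat.data] = bc_map.voxel_contrast
                run_maps.append(vol)

                # condition-dependent coupling between target and control
                seed_series = run.data[visit_mask.data].mean(axis=0)
                target_series = run.data[control_mask].mean(axis=0)
                design = ppi_terms(
                    seed_series,
                    run.design.boxcar("upregulate"),
                    hrf=cfg.hrf,
                    tr=grid.tr,
                    nuisance=nuisance,
                )
                ppi = fit_ppi(target_series, design)
                ppi_rows.append(
                    {
                        "subject": subj,
                        "visit": visit,
                        "run": run_no,
                        "beta": ppi.beta,
                        "age": age,
                        "caudate_pct_icv": caud,
                    }
                )
            if run_maps:
                visit_mean_maps[visit] = np.mean(run_maps, axis=0)

        first, last = min(visit_mean_maps), max(visit_mean_maps)
        change_maps[subj] = visit_mean_maps[last] - visit_mean_maps[first]

    contrasts = pd.DataFrame(contrast_rows)
    ppi_betas = pd.DataFrame(ppi_rows)
    trend = visit_trend(contrasts)
    ppi_trend = connectivity_change(ppi_betas)

    # composite change: post-training measures improve with realized learning
    norms = default_reference_norms()
    panels = cohort_panels(cohort)
    rng_t = np.random.default_rng(_subseed(cfg.seed, "transfer"))
    comp_rows = []
    for s_idx, subj in enumerate(subjects):
        pre_panel = panels[subj]
        learn = float(slopes[s_idx]) * (cfg.n_visits - 1)
        gain = cfg.transfer_gain * learn + rng_t.normal(0.0, cfg.transfer_noise_sd)
        post_panel = _improved_panel(pre_panel, gain, norms)
        pre = composite(pre_panel, norms)
        post = composite(post_panel, norms)
        comp_rows.append(
            {
                "subject": subj,
                "composite_pre": pre,
                "composite_post": post,
                "change": post - pre,
            }
        )
    composite_change = pd.DataFrame(comp_rows)

    maps = np.stack([change_maps[s] for s in subjects])
    # with very small cohorts the confounds would exhaust the residual dof
    covs = cohort[["age", "caudate_pct_icv"]] if len(subjects) >= 5 else None
    behavior = behavior_regression(
        maps,
        composite_change["change"].to_numpy(),
        covs,
        p_threshold=cfg.voxel_p,
    )

    cfg_hash = hashlib.sha256(repr(cfg).encode()).hexdigest()[:16]
    return StudyReport(
        cohort=cohort,
        contrasts=contrasts,
        trend=trend,
        ppi_betas=ppi_betas,
        ppi_trend=ppi_trend,
        composite_change=composite_change,
        behavior=behavior,
        excluded_runs=excluded,
        roi_sizes=pd.DataFrame(roi_size_rows),
        feedback_summaries=pd.concat(fb_rows, ignore_index=True)
        if fb_rows
        else pd.DataFrame(),
        config_hash=cfg_hash,
        seed=cfg.seed,
    )


def _improved_panel(panel: MeasurePanel, gain: float, norms) -> MeasurePanel:
    """Shift a panel by ``gain`` reference SDs of overall performance.

    Synthetic transfer model: each measure moves in its better direction
    by ``gain`` times its reference SD (on the harmonized scale), mapped
    back to the raw scale.
    """
    g = gain
    return MeasurePanel(
        stroop_word_correct=max(
            0.0, panel.stroop_word_correct + g * norms.sds["stroop_word_correct"]
        ),
        sdmt_correct=max(0.0, panel.sdmt_correct + g * norms.sds["sdmt_correct"]),
        circle_annulus_length=panel.circle_annulus_length
        * float(np.exp(g * norms.sds["log_circle_annulus"])),
        emotion_recog_correct=max(
            0.0, panel.emotion_recog_correct + g * norms.sds["emotion_recog_correct"]
        ),
        iti=max(1e-3, panel.iti - g * norms.sds["neg_iti"]),
        sd_ioi=panel.sd_ioi * float(np.exp(-g * norms.sds["neg_log_sd_ioi"])),
        sd_dmti=panel.sd_dmti * float(np.exp(-g * norms.sds["neg_log_sd_dmti"])),
    )


def make_fixtures(out_dir, seed: int = 0):
    """Write a miniature canned dataset: one participant, 2 visits x 2 runs.

    Intended for fast smoke tests and examples: NIfTI runs + events TSV +
    motion TSV + truth JSON + a cohort CSV, all on a 12 x 12 x 8 grid.
    Returns the list of file paths written.
    """
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    grid = AcquisitionGrid(shape=(12, 12, 8))
    truth = SimulationTruth(
        roi_voxels=default_roi_voxels(grid),
        base_amplitude=1.0,
        learning_slope=0.4,
        spike_times=(40,),
    )
    paths = []
    truth_path = out / "truth.json"
    truth.to_json(truth_path)
    paths.append(truth_path)
    cohort = simulate_cohort(CohortSpec(n_participants=3, seed=_subseed(seed, "fx")))
    cohort_path = out / "cohort.csv"
    cohort.to_csv(cohort_path, index=False)
    paths.append(cohort_path)
    for visit in (1, 2):
        for run_no in (1, 2):
            run, motion = simulate_run(
                truth,
                grid=grid,
                seed=_subseed(seed, "fixture", visit, run_no),
                visit=visit,
                run=run_no,
            )
            stem = f"sub-01_visit-{visit}_run-{run_no}"
            nii = out / f"{stem}_bold.nii"
            ev = out / f"{stem}_events.tsv"
            mo = out / f"{stem}_motion.tsv"
            run.save(nii, ev)
            motion.to_csv(mo, sep="\t", index=False)
            paths += [nii, ev, mo]
    return paths
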