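"""Scrubbing, block contrasts, trend models, PPI and behaviour regression."""

import numpy as np
import pandas as pd
import pytest

from rtnf import (
    behavior_regression,
    block_contrast,
    connectivity_change,
    fit_ppi,
    ppi_terms,
    run_exceeds_motion,
    spike_regressors,
    tapping_contrast_comparison,
    visit_trend,
)
from rtnf.offline import scan_displacement
from rtnf.simulate import MOTION_COLUMNS


def motion_table(n=100):
    return pd.DataFrame(np.zeros((n, 6)), columns=MOTION_COLUMNS)


class TestSpikeRegressors:
    def test_zero_motion_yields_no_columns(self):
        res = spike_regressors(motion_table())
        assert res.flagged == []
        assert res.regressors.shape == (100, 0)

    def test_planted_jump_flagged_exactly_once(self):
        m = motion_table()
        m.loc[40:, "trans_x"] += 1.2  # step: single 1.2 mm scan-to-scan jump
        res = spike_regressors(m)
        assert res.flagged == [40]
        assert res.regressors[40, 0] == 1.0
        assert res.regressors.sum() == 1.0

    def test_exact_threshold_jump_not_flagged(self):
        m = motion_table()
        m.loc[40:, "trans_x"] += 1.0
        assert spike_regressors(m, threshold=1.0).flagged == []

    def test_rotations_converted_via_head_radius(self):
        m = motion_table()
        m.loc[30:, "rot_z"] += 0.03  # 0.03 rad * 50 mm = 1.5 mm surface motion
        assert spike_regressors(m).flagged == [30]

    def test_invariant_to_constant_offsets(self):
        rng = np.random.default_rng(0)
        m = motion_table()
        m.iloc[:, :] = rng.normal(0, 0.3, (100, 6))
        base = spike_regressors(m).flagged
        shifted = m + 5.0
        assert spike_regressors(shifted).flagged == base

    def test_run_exclusion_fires_above_two_mm(self):
        m = motion_table()
        m.loc[50:, "trans_y"] += 2.1
        assert run_exceeds_motion(m)
        m2 = motion_table()
        m2.loc[50:, "trans_y"] += 2.0
        assert not run_exceeds_motion(m2)

    def test_displacement_matches_hand_computation(self):
        m = motion_table(5)
        m.loc[2:, "trans_x"] = 0.7
        m.loc[3:, "rot_y"] = 0.02
        disp = scan_displacement(m)
        np.testing.assert_allclose(disp, [0.0, 0.0, 0.7, 1.0, 0.0], atol=1e-12)


class TestBlockContrast:
    def test_recovers_planted_amplitude_noise_free(self, noise_free_run):
        truth, run, _ = noise_free_run
        bc = block_contrast(run, truth.roi_mask(run.grid))
        assert bc.roi_contrast == pytest.approx(1.0, rel=0.02)

    def test_roi_contrast_is_mean_of_voxel_contrasts(self, noisy_run):
        truth, run, _ = noisy_run
        bc = block_contrast(run, truth.roi_mask(run.grid))
        assert bc.roi_contrast == pytest.approx(bc.voxel_contrast.mean(), abs=1e-12)

    def test_null_runs_centered_on_zero(self, small_grid):
        from rtnf import SimulationTruth, default_roi_voxels, simulate_run

        truth = SimulationTruth(
            roi_voxels=default_roi_voxels(small_grid),
            base_amplitude=0.0,
            learning_slope=0.0,
            noise_sd=1.0,
        )
        vals = []
        for seed in range(40):
            run, _ = simulate_run(truth, grid=small_grid, seed=100 + seed)
            vals.append(block_contrast(run, truth.roi_mask(small_grid)).roi_contrast)
        vals = np.asarray(vals)
        se = vals.std(ddof=1) / np.sqrt(vals.size)
        assert abs(vals.mean()) < 2 * se + 0.02

    def test_missing_block_kind_rejected(self, noise_free_run):
        truth, run, _ = noise_free_run
        with pytest.raises(ValueError):
            block_contrast(run, truth.roi_mask(run.grid), active_kind="clench")


def trend_table(slope, seed, n_subj=10, n_vis=4, n_run=4, tau=0.2, sigma=0.3):
    rng = np.random.default_rng(seed)
    ages = rng.uniform(40, 65, n_subj)
    caud = rng.uniform(0.3, 0.55, n_subj)
    rows = []
    for s in range(n_subj):
        b = rng.normal(0, tau)
        for v in range(1, n_vis + 1):
            for r in range(1, n_run + 1):
                rows.append(
                    dict(
                        subject=f"s{s}",
                        visit=v,
                        run=r,
                        roi_contrast=slope * v + b + rng.normal(0, sigma),
                        age=ages[s],
                        caudate_pct_icv=caud[s],
                    )
                )
    return pd.DataFrame(rows)


class TestVisitTrend:
    def test_recovers_planted_slope(self):
        res = visit_trend(trend_table(0.3, seed=1))
        eff = res.effect("visit")
        assert eff["estimate"] == pytest.approx(0.3, abs=3 * eff["se"])
        assert res.method == "mixed-reml"

    def test_identical_responses_give_zero_slope(self):
        df = trend_table(0.0, seed=2)
        df["roi_contrast"] = 1.5
        res = visit_trend(df)
        assert res.effect("visit")["estimate"] == 0.0
        assert res.singular

    def test_reduces_to_ols_without_random_intercept(self):
        df = trend_table(0.3, seed=3)
        res = visit_trend(df, random_intercept=False)
        X = np.column_stack(
            [
                np.ones(len(df)),
                df["visit"],
                df["run"],
                df["age"],
                df["caudate_pct_icv"],
            ]
        )
        beta = np.linalg.lstsq(X, df["roi_contrast"], rcond=None)[0]
        assert res.effect("visit")["estimate"] == pytest.approx(beta[1], abs=1e-6)

    def test_requires_multiple_subjects_and_visits(self):
        df = trend_table(0.3, seed=4)
        with pytest.raises(ValueError):
            visit_trend(df[df.subject == "s0"])
        with pytest.raises(ValueError):
            visit_trend(df[df.visit == 1])


class TestPpi:
    def test_constant_seed_gives_null_interaction(self):
        box = np.zeros(100)
        box[30:60] = 1
        d = ppi_terms(np.full(100, 5.0), box)
        np.testing.assert_allclose(d.interaction, 0.0, atol=1e-12)

    def test_interaction_equals_product_oracle(self):
        rng = np.random.default_rng(5)
        seed_series = rng.normal(0, 1, 120)
        box = np.zeros(120)
        box[20:50] = 1
        box[80:110] = 1
        d = ppi_terms(seed_series, box)
        oracle = (seed_series - seed_series.mean()) * d.condition
        np.testing.assert_allclose(d.interaction, oracle, atol=1e-12)

    def test_centering_is_idempotent(self):
        rng = np.random.default_rng(6)
        seed_series = rng.normal(0, 1, 100)
        box = np.zeros(100)
        box[40:70] = 1
        d1 = ppi_terms(seed_series, box)
        d2 = ppi_terms(d1.seed, box)  # already centered seed
        np.testing.assert_allclose(d1.interaction, d2.interaction, atol=1e-12)

    def test_planted_coupling_recovered(self):
        rng = np.random.default_rng(7)
        seed_series = rng.normal(0, 1, 200)
        box = np.zeros(200)
        box[50:80] = 1
        box[120:150] = 1
        d = ppi_terms(seed_series, box)
        target = 0.3 * d.seed + 0.5 * d.interaction
        fit = fit_ppi(target, d)
        assert fit.beta == pytest.approx(0.5, abs=1e-9)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ppi_terms(np.zeros(10), np.zeros(11))


class TestConnectivityChange:
    def test_planted_coupling_slope_recovered(self):
        df = trend_table(0.2, seed=8).rename(columns={"roi_contrast": "beta"})
        res = connectivity_change(df)
        eff = res.effect("visit")
        assert eff["estimate"] == pytest.approx(0.2, abs=3 * eff["se"])

    def test_single_visit_rejected(self):
        df = trend_table(0.2, seed=9).rename(columns={"roi_contrast": "beta"})
        with pytest.raises(ValueError):
            connectivity_change(df[df.visit == 1])


class TestBehaviorRegression:
    shape = (12, 12, 8)

    def _planted(self, seed, b=1.0):
        rng = np.random.default_rng(seed)
        n = 12
        comp = rng.normal(0, 1, n)
        cov = pd.DataFrame(
            {"age": rng.uniform(40, 65, n), "caudate_pct_icv": rng.uniform(0.3, 0.5, n)}
        )
        region = np.zeros(self.shape, bool)
        region[4:8, 4:8, 2:5] = True
        maps = rng.normal(0, 0.5, (n,) + self.shape)
        maps[:, region] += b * comp[:, None]
        return maps, comp, cov, region

    @staticmethod
    def _dice(res, region):
        above = res.tmap > res.threshold_t
        inter = (above & region).sum()
        denom = above.sum() + region.sum()
        return 2 * inter / denom if denom else 0.0

    def test_planted_region_recovered(self):
        dice_ok = 0
        for seed in range(20):
            maps, comp, cov, region = self._planted(seed)
            res = behavior_regression(maps, comp, cov)
            dice_ok += len(res.clusters) > 0 and self._dice(res, region) >= 0.5
        assert dice_ok >= 18

    def test_permuted_outcome_rarely_recovers(self):
        hits = 0
        for seed in range(20):
            maps, comp, cov, region = self._planted(seed)
            rng = np.random.default_rng(1000 + seed)
            res = behavior_regression(maps, rng.permutation(comp), cov)
            hits += len(res.clusters) > 0 and self._dice(res, region) >= 0.5
        assert hits <= 2

    def test_constant_maps_give_empty_cluster_list(self):
        rng = np.random.default_rng(11)
        maps = np.ones((8,) + self.shape)
        comp = rng.normal(0, 1, 8)
        cov = pd.DataFrame({"age": rng.uniform(40, 65, 8)})
        res = behavior_regression(maps, comp, cov)
        assert len(res.clusters) == 0

    def test_too_few_subjects_rejected(self):
        maps, comp, cov, _ = self._planted(0)
        with pytest.raises(ValueError):
            behavior_regression(maps[:4], comp[:4], cov.iloc[:4])


def tapping_table(rng, effect=0.0, n=8):
    ages = rng.uniform(40, 65, n)
    caud = rng.uniform(0.3, 0.55, n)
    rows = []
    for s in range(n):
        base = rng.normal(1.0, 0.3)
        for cond in ("pre", "post_without", "post_with"):
            extra = effect if cond == "post_with" else 0.0
            rows.append(
                dict(
                    subject=f"s{s}",
                    condition=cond,
                    contrast=base + extra + rng.normal(0, 0.15),
                    age=ages[s],
                    caudate_pct_icv=caud[s],
                )
            )
    return pd.DataFrame(rows)


class TestTappingComparison:
    def test_identical_conditions_give_zero_difference(self):
        rng = np.random.default_rng(12)
        df = tapping_table(rng)
        wide = df.pivot_table(index="subject", columns="condition", values="contrast")
        df.loc[df.condition == "post_with", "contrast"] = wide["post_without"].loc[
            df.loc[df.condition == "post_with", "subject"]
        ].to_numpy()
        res = tapping_contrast_comparison(df)
        assert res.difference_estimate == pytest.approx(0.0, abs=1e-12)

    def test_planted_upregulation_effect_detected(self):
        """Power at the planted effect/noise: detection in >= 80% of sims."""
        rng = np.random.default_rng(13)
        detected = 0
        n_sims = 100
        for _ in range(n_sims):
            res = tapping_contrast_comparison(tapping_table(rng, effect=0.4))
            detected += res.pvalue < 0.05 and res.difference_estimate > 0
        assert detected >= 0.8 * n_sims

    def test_missing_condition_rejected(self):
        rng = np.random.default_rng(14)
        df = tapping_table(rng)
        with pytest.raises(ValueError):
            tapping_contrast_comparison(df[df.condition != "pre"])

    def test_unmatched_subjects_rejected(self):
        rng = np.random.default_rng(15)
        df = tapping_table(rng)
        df = df.drop(df[(df.subject == "s0") & (df.condition == "post_with")].index)
        with pytest.raises(ValueError):
            tapping_contrast_comparison(df)
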