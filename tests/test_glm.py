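"""First-level fitting, prewhitening, contrasts and group analyses."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from foragebold import design_matrix as dm
from foragebold import glm
from foragebold import synth_bold as sb
from foragebold import task_schedule as ts


@pytest.fixture(scope="module")
def sim():
    ph = sb.build_phantom((6, 6, 6), 3.0, {"R": ((1, 4), (1, 4), (1, 4))})
    sched = ts.generate_schedule(ts.TaskConfig(seed=2))
    design = dm.build_block_design(sched, 2.46, 144)
    return ph, design


class TestFirstLevel:
    def test_zero_phi_equals_ols_exactly(self, sim):
        ph, design = sim
        series = sb.simulate_subject(ph, design, sb.NoiseSpec(sd=1.0,
                                                              ar1=0.0),
                                     {"R": {"cue_high": 1.0}}, seed=5)
        a = glm.fit_first_level(series, design, ar1=0.0)
        X = design.values
        Y = series.data.reshape(-1, design.n_scans).T
        ols = np.linalg.lstsq(X, Y, rcond=None)[0]
        np.testing.assert_array_equal(
            a.betas.reshape(len(design.names), -1), ols)

    def test_whitening_removes_lag_one_autocorrelation(self, sim):
        ph, design = sim
        series = sb.simulate_subject(ph, design,
                                     sb.NoiseSpec(sd=1.0, ar1=0.3), {},
                                     seed=6)
        fit = glm.fit_first_level(series, design)
        assert abs(fit.whitened_resid_ac1) < 0.05

    def test_length_mismatch_raises(self, sim):
        ph, design = sim
        with pytest.raises(ValueError, match="scans"):
            glm.fit_first_level(np.zeros((2, 2, 2, 10)), design)

    def test_rank_deficient_design_names_column(self, sim):
        _, design = sim
        frame = design.frame.copy()
        frame["dup"] = frame["cue_high"]
        bad = dm.DesignMatrix(frame, dict(design.kinds, dup="task"),
                              design.tr)
        with pytest.raises(ValueError, match="rank deficient"):
            glm.fit_first_level(np.zeros((2, 2, 2, 144)) + 1.0, bad)

    def test_t_map_variance_follows_student_law(self, sim):
        # pure noise: voxelwise one-column t values follow Student-t(dof),
        # whose variance is dof / (dof - 2)
        ph, design = sim
        series = sb.simulate_subject(
            ph, design, sb.NoiseSpec(sd=1.0, ar1=0.0), {}, seed=7)
        fit = glm.fit_first_level(series, design, ar1="none")
        con = glm.contrast_map(fit, {"cue_high": 1.0})
        t = con.t[np.isfinite(con.t)]
        want = fit.dof / (fit.dof - 2)
        assert t.var() == pytest.approx(want, rel=0.35)

    def test_dof_is_scans_minus_rank(self, sim):
        ph, design = sim
        series = sb.simulate_subject(ph, design, sb.NoiseSpec(), {}, seed=8)
        fit = glm.fit_first_level(series, design)
        assert fit.dof == 144 - len(design.names)


@pytest.fixture(scope="module")
def fit(sim):
    ph, design = sim
    series = sb.simulate_subject(ph, design, sb.NoiseSpec(sd=0.5, ar1=0.2),
                                 {"R": {"patch_high": 1.0,
                                        "patch_low": 0.3}}, seed=9)
    return glm.fit_first_level(series, design)


class TestContrast:
    def test_foraging_contrast_recovers_difference(self, sim, fit):
        ph, _ = sim
        con = glm.contrast_map(fit, {"patch_high": 1.0, "patch_low": -1.0})
        assert con.effect[ph.regions["R"]].mean() == pytest.approx(0.7,
                                                                   abs=0.1)

    def test_sign_flip_negates_exactly(self, fit):
        a = glm.contrast_map(fit, {"patch_high": 1.0, "patch_low": -1.0})
        b = glm.contrast_map(fit, {"patch_high": -1.0, "patch_low": 1.0})
        np.testing.assert_array_equal(a.effect, -b.effect)
        np.testing.assert_array_equal(a.t, -b.t)

    def test_unknown_column_raises(self, fit):
        with pytest.raises(ValueError, match="unknown design column"):
            glm.contrast_map(fit, {"nope": 1.0})

    def test_all_zero_weights_flagged(self, fit):
        con = glm.contrast_map(fit, {"patch_high": 0.0})
        assert np.all(con.effect == 0.0)
        assert con.zero_variance.all() and np.isnan(con.t).all()


class TestSecondLevel:
    def test_one_sample_matches_direct_formula(self):
        rng = np.random.default_rng(3)
        maps = rng.normal(size=(12, 5, 5, 5))
        got = glm.second_level(maps)
        want_t, _ = stats.ttest_1samp(maps, 0.0, axis=0)
        np.testing.assert_allclose(got.t, want_t, atol=1e-10)
        assert got.dof == 11

    def test_null_t_quantile_matches_student(self):
        rng = np.random.default_rng(4)
        maps = rng.normal(size=(35, 12, 12, 12))
        got = glm.second_level(maps)
        emp = np.quantile(got.t, 0.975)
        want = stats.t.ppf(0.975, 34)
        assert emp == pytest.approx(want, rel=0.08)

    def test_identical_maps_flagged_zero_variance(self):
        maps = np.full((35, 3, 3, 3), 2.5)
        got = glm.second_level(maps)
        assert got.zero_variance.all() and np.isnan(got.t).all()

    def test_two_sample_recovers_sign_of_planted_difference(self):
        rng = np.random.default_rng(5)
        d = 2.0  # twice the within-group sd of 1
        hits = 0
        for _ in range(200):
            a = rng.normal(0.0, 1.0, size=(10, 1))
            b = rng.normal(d, 1.0, size=(10, 1))
            got = glm.second_level(np.concatenate([a, b]), "two_sample",
                                   labels=[0] * 10 + [1] * 10)
            hits += got.t[0] > 0
        assert hits / 200 > 0.99

    def test_two_sample_dof(self):
        rng = np.random.default_rng(6)
        got = glm.second_level(rng.normal(size=(9, 2, 2, 2)), "two_sample",
                               labels=[0] * 4 + [1] * 5)
        assert got.dof == 7

    def test_too_few_maps_raise(self):
        with pytest.raises(ValueError):
            glm.second_level(np.zeros((1, 2, 2, 2)))


@pytest.fixture(scope="module")
def bank():
    return glm.single_trial_bank(ts.TaskConfig(), dt=0.2, degree=4)


class TestTimeCourse:
    def test_flat_patch_effect_gives_flat_plateau(self, bank):
        betas = [{"cue": 0.0, "patch": 1.0, "t1": 0.0, "t2": 0.0,
                  "t3": 0.0, "t4": 0.0} for _ in range(5)]
        fit = glm.fitted_time_course(betas, bank)
        # steady part of the patch response: the haemodynamic rise takes
        # ~10 s after patch onset (5 s), so the plateau sits at 16-19 s
        plateau = fit.mean[(fit.time >= 16.0) & (fit.time <= 19.0)]
        assert plateau.std() / plateau.mean() < 0.02
        assert plateau.min() > 0.95 * plateau.max()

    def test_zero_between_subject_variance_zero_band(self, bank):
        betas = [{"cue": 1.0, "patch": 0.5, "t1": 0.1, "t2": 0.0,
                  "t3": 0.0, "t4": 0.0}] * 4
        fit = glm.fitted_time_course(betas, bank)
        np.testing.assert_allclose(fit.upper, fit.lower, atol=1e-12)
        np.testing.assert_allclose(fit.mean, fit.upper, atol=1e-12)

    def test_band_contains_mean_and_has_nonneg_width(self, bank):
        rng = np.random.default_rng(7)
        betas = [{"cue": rng.normal(), "patch": rng.normal(),
                  "t1": rng.normal(), "t2": 0.0, "t3": 0.0, "t4": 0.0}
                 for _ in range(8)]
        fit = glm.fitted_time_course(betas, bank)
        assert (fit.upper >= fit.mean - 1e-12).all()
        assert (fit.lower <= fit.mean + 1e-12).all()

    def test_missing_polynomial_coefficient_raises(self, bank):
        with pytest.raises(ValueError, match="lacks coefficient"):
            glm.fitted_time_course([{"cue": 1.0, "patch": 1.0}], bank)

    def test_quartile_contrast_flat_null_ramp_positive(self):
        # flat within-patch signal: last-minus-first quartile contrast is
        # exactly zero (the main event regressor spans it); a planted
        # within-patch ramp drives the contrast positive
        ph = sb.build_phantom((4, 4, 4), 3.0, {"R": ((0, 4), (0, 4), (0, 4))})
        sched = ts.generate_schedule(ts.experiment_task_config(3, seed=4))
        event = dm.build_target_event_design(sched, 2.46, 144)
        poly = dm.add_polynomial_time_modulators(event, sched, degree=1)
        quart = dm.add_quartile_model(event, sched)
        weights = dm.quartile_contrast("high")
        noise = sb.NoiseSpec(sd=0.0, ar1=0.0)

        flat = sb.simulate_subject(ph, poly, noise,
                                   {"R": {"target_high": 1.0}}, seed=0)
        con = glm.contrast_map(glm.fit_first_level(flat, quart, ar1="none"),
                               weights)
        assert abs(con.effect[0, 0, 0]) < 1e-8

        ramp = sb.simulate_subject(ph, poly, noise,
                                   {"R": {"target_high_t1": 1.0}}, seed=0)
        con = glm.contrast_map(glm.fit_first_level(ramp, quart, ar1="none"),
                               weights)
        assert con.effect[0, 0, 0] > 0.1


class TestRecoveryCalibration:
    def test_amplitude_recovery_bias_below_two_percent(self):
        # cohorts of 17 at default noise: the prewhitened estimator
        # recovers a planted 0.5% patch amplitude essentially unbiased
        ph = sb.build_phantom((6, 6, 6), 3.0,
                              {"R": ((1, 4), (1, 4), (1, 4))})
        sched = ts.generate_schedule(ts.TaskConfig(seed=12))
        design = dm.build_block_design(sched, 2.46, 144)
        est = []
        for c in range(25):
            cohort = sb.CohortSpec(n_subjects=17, between_sd=0.0, seed=c)
            series = sb.simulate_cohort(ph, design, sb.NoiseSpec(), cohort,
                                        {"R": {"patch_high": 0.5}})
            for s in series:
                f = glm.fit_first_level(s, design)
                est.append(f.beta_map("patch_high")[ph.regions["R"]].mean())
        bias = np.mean(est) - 0.5
        assert abs(bias) / 0.5 < 0.02
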