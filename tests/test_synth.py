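"""Calibrated synthetic sway generation, cohorts, and device emulation."""
from __future__ import annotations

import numpy as np
import pytest
from scipy import stats

import ictsib as ic
from ictsib.errors import CalibrationError, DomainError
from ictsib.cop import GridGeometry, cop_from_corners, cop_from_grid
from ictsib.features import compute_sway_features
from ictsib.model import BOConfig, fit_condition_model
from ictsib.synth import (
    ConditionCalibration,
    GeneratorConfig,
    SiLink,
    emulate_devices,
    expected_features,
    generate_cohort,
    generate_cop_trial,
)
from ictsib.types import ALL_CONDITIONS, FEATURE_NAMES, Condition


class TestGenerateTrial:
    def test_deterministic(self, generator_config):
        a = generate_cop_trial(generator_config, Condition.EC_FOAM1, seed=11)
        b = generate_cop_trial(generator_config, Condition.EC_FOAM1, seed=11)
        np.testing.assert_array_equal(a.x, b.x)
        np.testing.assert_array_equal(a.y, b.y)

    def test_sample_count(self, generator_config):
        tr = generate_cop_trial(generator_config, Condition.EO_FIRM, seed=0)
        assert tr.n_samples == 690  # 30 s at 23 Hz
        assert tr.fs == 23.0

    def test_trial_passes_invariants(self, generator_config):
        tr = generate_cop_trial(generator_config, Condition.EO_FOAM2, seed=3)
        assert np.all(np.isfinite(tr.x)) and np.all(np.isfinite(tr.y))
        assert tr.duration_s == pytest.approx(689 / 23)

    def test_monte_carlo_velocity_calibration(self, generator_config):
        # 200 trials: sample mean of mean_velocity within 3 SE of the target
        target = generator_config.conditions[Condition.EO_FIRM].target_mean_velocity_cm_s
        vals = [
            compute_sway_features(
                generate_cop_trial(generator_config, Condition.EO_FIRM, seed=10_000 + i)
            ).mean_velocity_cm_s
            for i in range(200)
        ]
        vals = np.asarray(vals)
        se = vals.std(ddof=1) / np.sqrt(len(vals))
        assert abs(vals.mean() - target) < 3 * se

    def test_infeasible_triple_target_raises(self):
        # velocity+area+median jointly overconstrain a stationary Gaussian
        # process; the error must name the conflicting targets
        cal = ConditionCalibration(
            target_mean_velocity_cm_s=1.20,
            target_ellipse_area_cm2=0.34,
            target_freq_median_hz=1.44,
        )
        cfg = GeneratorConfig(
            conditions={Condition.EO_FIRM: cal}, si_link=SiLink(weights={"mean_velocity_cm_s": 1.0})
        )
        with pytest.raises(CalibrationError) as exc:
            generate_cop_trial(cfg, Condition.EO_FIRM, seed=0)
        msg = str(exc.value)
        assert "velocity" in msg or "area" in msg or "median" in msg

    def test_expected_features_match_targets(self, generator_config):
        for cond in ALL_CONDITIONS:
            cal = generator_config.conditions[cond]
            exp = expected_features(generator_config, cond)
            assert exp["mean_velocity_cm_s"] == pytest.approx(
                cal.target_mean_velocity_cm_s, rel=1e-6
            )
            if cal.target_freq_median_hz is not None:
                assert exp["freq_median_hz"] == pytest.approx(
                    cal.target_freq_median_hz, rel=1e-6
                )
            if cal.target_ellipse_area_cm2 is not None:
                assert exp["ellipse_area_cm2"] == pytest.approx(
                    cal.target_ellipse_area_cm2, rel=1e-6
                )


class TestGenerateCohort:
    def test_cohort_shape(self, generator_config):
        cohort = generate_cohort(generator_config, 10, seed=2)
        assert len(cohort.rows) == 10 * 7
        assert len(cohort.trials) == 10 * 7
        assert len(cohort.training_table().subjects()) == 10

    def test_103_subjects_721_rows(self, generator_config):
        cohort = generate_cohort(generator_config, 103, seed=4)
        assert len(cohort.rows) == 721

    def test_too_few_subjects(self, generator_config):
        with pytest.raises(DomainError):
            generate_cohort(generator_config, 1, seed=0)

    def test_si_reference_reproducible_from_link(self, small_cohort):
        for row in small_cohort.rows[:20]:
            reconstructed = small_cohort.si_link.apply(row.features) + row.noise_draw
            assert row.si_reference == pytest.approx(max(reconstructed, 0.0), abs=1e-9)

    def test_zero_noise_link_identity(self, generator_config):
        from dataclasses import replace

        link = SiLink(
            weights=dict(generator_config.si_link.weights),
            intercept=generator_config.si_link.intercept,
            noise_sd=0.0,
        )
        cfg = replace(generator_config, si_link=link)
        cohort = generate_cohort(cfg, 5, seed=3)
        for row in cohort.rows:
            assert row.si_reference == pytest.approx(
                max(link.apply(row.features), 0.0), abs=1e-12
            )

    def test_severity_monotone_with_area(self, small_cohort):
        # within one condition, larger latent severity means larger sway area
        rows = [r for r in small_cohort.rows if r.condition == Condition.EC_FOAM2]
        sev = [r.severity for r in rows]
        area = [r.features.ellipse_area_cm2 for r in rows]
        rho, _ = stats.spearmanr(sev, area)
        assert rho > 0.5

    def test_features_computed_through_pipeline(self, small_cohort, generator_config):
        row = small_cohort.rows[0]
        trial = small_cohort.trials[(row.subject_id, row.condition)]
        recomputed = compute_sway_features(trial, generator_config.filter_spec)
        np.testing.assert_allclose(
            recomputed.to_array(), row.features.to_array(), rtol=1e-9
        )


class TestSiLinkRecovery:
    def test_zero_noise_cohort_recovers_link_weights(self, generator_config):
        from dataclasses import replace

        link = SiLink(
            weights=dict(generator_config.si_link.weights),
            intercept=generator_config.si_link.intercept,
            noise_sd=0.0,
        )
        cfg = replace(generator_config, si_link=link)
        cohort = generate_cohort(cfg, 40, seed=21)
        table = cohort.training_table().for_condition(Condition.EO_FIRM)
        model = fit_condition_model(table, "linear")
        beta = dict(zip(FEATURE_NAMES, model.beta))
        # mean_path == mean_velocity and mean_distance == mean_velocity / fs
        # are exactly collinear columns: substituting x_dist = x_vel / fs, only
        # the combined coefficient beta_path + beta_vel + beta_dist / fs is
        # identifiable; ridge splits the weight across the proportional columns
        fs = cfg.fs
        group = ("mean_path_cm_s", "mean_velocity_cm_s", "mean_distance_cm")
        combined = beta[group[0]] + beta[group[1]] + beta[group[2]] / fs
        true_combined = (
            link.weights.get("mean_path_cm_s", 0.0)
            + link.weights.get("mean_velocity_cm_s", 0.0)
            + link.weights.get("mean_distance_cm", 0.0) / fs
        )
        assert combined == pytest.approx(true_combined, abs=1e-2)
        for name in FEATURE_NAMES:
            if name in group:
                continue
            assert beta[name] == pytest.approx(
                link.weights.get(name, 0.0), abs=1e-2
            )


class TestEmulateDevices:
    def test_zero_noise_grid_inversion_within_half_pitch(self, eo_firm_trial):
        frames, _ = emulate_devices(
            eo_firm_trial, grid_noise_sd=0.0, corner_noise_sd=0.0, seed=0
        )
        tr = cop_from_grid(frames)
        geom = GridGeometry()
        assert np.max(np.abs(tr.x - eo_firm_trial.x)) < geom.pitch_x_mm / 20.0
        assert np.max(np.abs(tr.y - eo_firm_trial.y)) < geom.pitch_y_mm / 20.0

    def test_zero_noise_corner_inversion_exact(self, eo_firm_trial):
        _, corners = emulate_devices(
            eo_firm_trial, grid_noise_sd=0.0, corner_noise_sd=0.0, seed=0
        )
        tr = cop_from_corners(corners)
        assert np.max(np.abs(tr.x - eo_firm_trial.x)) < 1e-9
        assert np.max(np.abs(tr.y - eo_firm_trial.y)) < 1e-9

    def test_total_load_preserved(self, eo_firm_trial):
        frames, corners = emulate_devices(
            eo_firm_trial, grid_noise_sd=0.0, corner_noise_sd=0.0, seed=0
        )
        np.testing.assert_allclose(frames.frames.sum(axis=(1, 2)), 60.0, rtol=1e-9)
        total = corners.tl + corners.tr + corners.bl + corners.br
        np.testing.assert_allclose(total, 60.0, rtol=1e-12)

    def test_deterministic(self, eo_firm_trial):
        f1, c1 = emulate_devices(eo_firm_trial, seed=42)
        f2, c2 = emulate_devices(eo_firm_trial, seed=42)
        np.testing.assert_array_equal(f1.frames, f2.frames)
        np.testing.assert_array_equal(c1.tr, c2.tr)

    def test_out_of_range_trajectory_raises(self, generator_config):
        from conftest import make_trial

        x = np.linspace(0, 30.0, 100)  # walks off the board
        with pytest.raises(DomainError):
            emulate_devices(make_trial(x, np.zeros_like(x)))

    def test_noise_dead_band(self, eo_firm_trial):
        frames, _ = emulate_devices(eo_firm_trial, grid_noise_sd=0.02, seed=1)
        nz = frames.frames[frames.frames > 0]
        assert nz.min() >= 3 * 0.02 - 1e-12


def _session_si(trials, link):
    return float(np.mean([link.apply(compute_sway_features(t)) for t in trials]))


def agreement_run(cfg, n_subjects, seed, grid_noise, corner_noise):
    """Dual-device SI agreement over an emulated cohort (one r per call)."""
    rng = np.random.default_rng(seed)
    link = cfg.si_link
    sigma = cfg.severity_sigma
    si_a, si_b = [], []
    for _ in range(n_subjects):
        sev = float(np.exp(rng.normal(-0.5 * sigma**2, sigma)))
        trials_g, trials_c = [], []
        for cond in ALL_CONDITIONS:
            tr = generate_cop_trial(cfg, cond, rng, amplitude_multiplier=sev)
            frames, corners = emulate_devices(
                tr, grid_noise_sd=grid_noise, corner_noise_sd=corner_noise, seed=rng
            )
            trials_g.append(cop_from_grid(frames, condition=cond))
            trials_c.append(cop_from_corners(corners, condition=cond))
        si_a.append(_session_si(trials_g, link))
        si_b.append(_session_si(trials_c, link))
    r, _ = ic.device_agreement(si_a, si_b)
    return r
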