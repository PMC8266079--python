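"""Gain identification: OLS core, model fits, modulators, delay sweep."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from comfeedback.dataset import Dataset
from comfeedback.errors import (
    ConditioningError,
    DegenerateModulatorError,
    InsufficientDataError,
    UndefinedR2Error,
    ValidationError,
)
from comfeedback.identify import (
    contralateral_toeoff_phase,
    delay_sensitivity,
    fit_constant_gain,
    fit_discrete_onset,
    fit_gains,
    fit_modulated_gain,
    fit_phase_binned,
    fit_results_to_csv,
    onset_phase,
    select_by_onset_phase,
    uncentered_r2,
)
from comfeedback.preprocessing import DelayConfig, apply_delay


class TestUncenteredR2:
    def test_identity(self):
        y = [0.1, -0.2, 0.3]
        assert uncentered_r2(y, y) == 1.0

    def test_zero_model(self):
        y = np.array([0.5, -1.0, 2.0])
        assert uncentered_r2(y, np.zeros(3)) == pytest.approx(0.0)

    def test_direct_evaluation(self):
        # 1 - 1/5 = 0.8
        assert uncentered_r2([1.0, 2.0], [1.0, 1.0]) == pytest.approx(0.8)

    def test_all_zero_measured(self):
        with pytest.raises(UndefinedR2Error):
            uncentered_r2([0.0, 0.0], [1.0, 1.0])

    def test_can_be_negative(self):
        assert uncentered_r2([1.0, 1.0], [3.0, 3.0]) < 0

    def test_brute_force_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            y = rng.standard_normal(10)
            yhat = rng.standard_normal(10)
            expected = 1.0 - sum((a - b) ** 2 for a, b in zip(y, yhat)) / \
                sum(a ** 2 for a in y)
            assert uncentered_r2(y, yhat) == pytest.approx(expected, abs=1e-12)


class TestFitGains:
    def test_exact_linear_system(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((20, 2))
        y = 2.0 * X[:, 0] + 1.0 * X[:, 1]
        res = fit_gains(X, y)
        assert res.gains.kp == pytest.approx(2.0, abs=1e-12)
        assert res.gains.kv == pytest.approx(1.0, abs=1e-12)
        assert res.r2 == pytest.approx(1.0, abs=1e-12)
        assert res.rmse < 1e-12

    def test_collinear_raises_conditioning_error(self):
        x = np.random.default_rng(2).standard_normal(10)
        X = np.column_stack([x, 2.0 * x])
        with pytest.raises(ConditioningError) as exc:
            fit_gains(X, x)
        assert exc.value.condition_number > 1e8

    def test_too_few_rows(self):
        with pytest.raises(InsufficientDataError):
            fit_gains(np.ones((3, 2)), np.ones(3))

    def test_normal_equations_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(30):
            X = rng.standard_normal((8, 2))
            y = rng.standard_normal(8)
            res = fit_gains(X, y)
            beta = np.linalg.solve(X.T @ X, X.T @ y)
            assert res.gains.kp == pytest.approx(beta[0], abs=1e-10)
            assert res.gains.kv == pytest.approx(beta[1], abs=1e-10)

    def test_monte_carlo_matches_analytic_se(self):
        # y = 2 xp + 1 xv + noise; mean |K - K_true| < 3 x analytic OLS SE
        rng = np.random.default_rng(4)
        sigma, n, reps = 0.01, 500, 200
        X = rng.standard_normal((n, 2))
        cov = sigma ** 2 * np.linalg.inv(X.T @ X)
        se = np.sqrt(np.diag(cov))
        errs = np.empty((reps, 2))
        for r in range(reps):
            y = 2.0 * X[:, 0] + 1.0 * X[:, 1] + sigma * rng.standard_normal(n)
            res = fit_gains(X, y)
            errs[r] = [res.gains.kp - 2.0, res.gains.kv - 1.0]
        assert np.all(np.abs(errs.mean(axis=0)) < 3 * se)
        # spread also matches the analytic covariance within 20 %
        assert np.allclose(errs.std(axis=0), se, rtol=0.2)

    @given(c=st.floats(0.1, 10.0), seed=st.integers(0, 100))
    @settings(max_examples=25, deadline=None)
    def test_scale_equivariance(self, c, seed):
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((12, 2))
        y = rng.standard_normal(12)
        a = fit_gains(X, y)
        b = fit_gains(X, c * y)
        assert b.gains.kp == pytest.approx(c * a.gains.kp, rel=1e-9)
        assert b.gains.kv == pytest.approx(c * a.gains.kv, rel=1e-9)
        assert b.r2 == pytest.approx(a.r2, rel=1e-9)


class TestDiscreteOnset:
    def test_standing_noiseless_exact(self, standing_noiseless):
        dataset, truth = standing_noiseless
        res = fit_discrete_onset(dataset, model="com", output="moment")
        assert res.gains.kp == pytest.approx(truth.params.gains.kp, rel=1e-9)
        assert res.gains.kv == pytest.approx(truth.params.gains.kv, rel=1e-9)
        assert res.r2 == pytest.approx(1.0, abs=1e-12)
        assert res.rmse < 1e-12

    def test_standing_joint_model_markedly_worse(self, standing_noisy):
        dataset, _ = standing_noisy
        com = fit_discrete_onset(dataset, model="com")
        joint = fit_discrete_onset(dataset, model="joint")
        assert com.r2 > joint.r2 + 0.1

    def test_pelvis_noiseless_exact_at_response_phase(self, pelvis_noiseless):
        dataset, truth = pelvis_noiseless
        res = fit_discrete_onset(dataset, model="com", output="moment")
        spec = truth.params.schedule[0]
        s_out = spec.onset_phase + (0.150 + truth.params.tau_T) / truth.params.stride_time
        kp_true, kv_true = truth.gain_at_stance_phase(
            s_out / truth.params.stance_fraction)
        assert res.gains.kp == pytest.approx(kp_true, rel=1e-6)
        assert res.gains.kv == pytest.approx(kv_true, rel=1e-6)
        assert res.r2 == pytest.approx(1.0, abs=1e-9)

    def test_unperturbed_rows_included(self, standing_noiseless):
        dataset, _ = standing_noiseless
        with_rows = fit_discrete_onset(dataset)
        without = fit_discrete_onset(dataset, include_unperturbed=False)
        n_unpert = len(dataset.unperturbed())
        assert with_rows.n_rows == without.n_rows + n_unpert

    def test_emg_pooled_scope_rejected(self, standing_noiseless):
        dataset, _ = standing_noiseless
        with pytest.raises(ValidationError, match="per-subject"):
            fit_discrete_onset(dataset, output="emg:soleus", scope="pooled")

    def test_emg_direction_split_recovery(self, standing_noiseless):
        dataset, truth = standing_noiseless
        res = fit_discrete_onset(dataset, output="emg:gastrocnemius",
                                 scope="subject:S01")
        kp_e, kv_e = truth.params.emg_gains["gastrocnemius"]
        assert res.gains.direction_split
        assert res.gains.kp["forward"] == pytest.approx(kp_e, rel=1e-6)
        assert res.gains.kv["forward"] == pytest.approx(kv_e, rel=1e-6)

    def test_emg_tibialis_negative_gains_backward(self, standing_noiseless):
        dataset, truth = standing_noiseless
        res = fit_discrete_onset(dataset, output="emg:tibialis_anterior",
                                 scope="subject:S01")
        kp_e, kv_e = truth.params.emg_gains["tibialis_anterior"]
        assert res.gains.kp["backward"] == pytest.approx(-kp_e, rel=1e-6)
        assert res.gains.kv["backward"] == pytest.approx(-kv_e, rel=1e-6)

    def test_insufficient_trials(self, standing_noiseless):
        dataset, _ = standing_noiseless
        small = Dataset(dataset.trials[:2], dataset.provenance)
        with pytest.raises(InsufficientDataError):
            fit_discrete_onset(small, include_unperturbed=False)

    def test_belt_discrete_noiseless_exact(self, belt_discrete_noiseless):
        dataset, truth = belt_discrete_noiseless
        res = fit_discrete_onset(dataset, model="com", output="moment")
        assert res.r2 == pytest.approx(1.0, abs=1e-9)
        assert res.rmse < 1e-9


class TestOnsetPhaseSelection:
    def test_onset_phase(self, pelvis_noiseless):
        dataset, truth = pelvis_noiseless
        trial = dataset.perturbed().trials[0]
        spec = truth.params.schedule[0]
        assert onset_phase(trial) == pytest.approx(spec.onset_phase, abs=1e-9)

    def test_contralateral_toeoff_phase(self, pelvis_noiseless):
        dataset, truth = pelvis_noiseless
        trial = dataset.trials[0]
        # contralateral stance began half a stride before the analyzed heel
        # strike; its toe-off lands at stance_fraction - 0.5 of the stride
        expected = truth.params.stance_fraction - 0.5
        assert contralateral_toeoff_phase(trial) == pytest.approx(expected, abs=1e-9)

    def test_select_by_onset_phase(self, pelvis_noiseless):
        dataset, truth = pelvis_noiseless
        sel = select_by_onset_phase(dataset, target="contralateral_toe_off",
                                    tol=0.05)
        # default schedule onsets at phase 0.1, contralateral toe-off at 0.1
        assert len(sel.perturbed()) == len(dataset.perturbed())
        none = select_by_onset_phase(dataset, target=0.4, tol=0.05)
        assert len(none.perturbed()) == 0


class TestPhaseBinned:
    def test_noiseless_binned_profile_recovery(self, continuous_binned_noiseless):
        dataset, truth = continuous_binned_noiseless
        res = fit_phase_binned(dataset, n_bins=16)
        kp_true, kv_true = truth.gain_at_stance_bins(16)
        active = kp_true > 0.1 * kp_true.max()
        rel_kp = np.abs(res.gains.kp[active] - kp_true[active]) / kp_true[active]
        rel_kv = np.abs(res.gains.kv[active] - kv_true[active]) / kv_true[active]
        assert np.nanmax(rel_kp) < 1e-2
        assert np.nanmax(rel_kv) < 1e-2
        assert np.all(res.r2_by_bin[active] > 1 - 1e-9)

    def test_noisy_profile_correlation(self, continuous_smooth_noisy):
        dataset, truth = continuous_smooth_noisy
        res = fit_phase_binned(dataset, n_bins=16)
        kp_true, _ = truth.gain_at_stance_bins(16)
        ok = np.isfinite(res.gains.kp)
        corr = np.corrcoef(res.gains.kp[ok], kp_true[ok])[0, 1]
        assert corr > 0.95

    def test_empty_bins_flagged_absent(self, continuous_binned_noiseless):
        dataset, _ = continuous_binned_noiseless
        res = fit_phase_binned(dataset, n_bins=16)
        # zero-gain bins have (numerically) zero response: flagged, not 0
        assert res.n_by_bin.sum() == res.n_rows

    def test_requires_walking_rows(self, standing_noiseless):
        dataset, _ = standing_noiseless
        with pytest.raises(Exception):
            fit_phase_binned(dataset)


class TestConstantAndModulated:
    def test_constant_matches_binned_for_constant_truth(self):
        from comfeedback.simulate import GainSchedule, SimParams, simulate_walking

        params = SimParams(
            protocol="belt_continuous", seed=21,
            gains=GainSchedule(kp=1.8, kv=0.7, kind="constant"),
            noise={"ankle_moment": 0.05},
            n_strides=40, n_unperturbed=1,
        )
        dataset, _ = simulate_walking(params)
        binned = fit_phase_binned(dataset, n_bins=16)
        const = fit_constant_gain(dataset, n_bins=16)
        assert const.gains.kp == pytest.approx(1.8, abs=0.05)
        ok = np.isfinite(binned.gains.kp)
        np.testing.assert_allclose(binned.gains.kp[ok], const.gains.kp, atol=0.15)

    def test_phase_varying_truth_favors_binned(self, continuous_smooth_noisy):
        dataset, _ = continuous_smooth_noisy
        binned = fit_phase_binned(dataset, n_bins=16)
        const = fit_constant_gain(dataset, n_bins=16)
        assert binned.stance_average_r2 > const.stance_average_r2

    def test_nested_model_inequality_per_bin(self, continuous_smooth_noisy):
        dataset, _ = continuous_smooth_noisy
        binned = fit_phase_binned(dataset, n_bins=16)
        const = fit_constant_gain(dataset, n_bins=16)
        both = np.isfinite(binned.r2_by_bin) & np.isfinite(const.r2_by_bin)
        assert np.all(binned.r2_by_bin[both] >= const.r2_by_bin[both] - 1e-12)

    def test_m_equals_one_reduces_to_constant_bitwise(self, continuous_smooth_noisy):
        dataset, _ = continuous_smooth_noisy
        const = fit_constant_gain(dataset)
        none_mod = fit_modulated_gain(dataset, modulator="none")
        assert none_mod.gains.kp == const.gains.kp
        assert none_mod.gains.kv == const.gains.kv
        assert none_mod.r2 == const.r2
        assert none_mod.rmse == const.rmse

    def test_generative_modulated_recovery(self, continuous_smooth_noisy):
        # rebuild moments with the Fy-modulated law; fit must recover exactly
        dataset, truth = continuous_smooth_noisy
        params = truth.params
        sub = params.subject
        mgl = sub.mass * sub.gravity * sub.com_height
        kdel = round(params.tau_T * params.fs)
        kp, kv = 1.4, 0.5
        rebuilt = []
        for trial, gt in zip(dataset, truth.deviations):
            x, v = gt["d_com_pos"], gt["d_com_vel"]
            n = len(x)
            xd = np.zeros(n)
            vd = np.zeros(n)
            xd[kdel:] = x[:n - kdel] / sub.com_height
            vd[kdel:] = v[:n - kdel] / np.sqrt(sub.gravity * sub.com_height)
            m_raw = trial.grf_vertical / (sub.mass * sub.gravity)
            md = np.zeros(n)
            md[kdel:] = m_raw[:n - kdel]
            t_dev = md * mgl * (kp * xd + kv * vd)
            # keep nominal gait moment + measurement noise, replace the
            # reactive part with the modulated generative law
            base = trial.ankle_moment - gt["d_ankle_moment"]
            rebuilt.append(dataclasses.replace(trial, ankle_moment=base + t_dev))
        ds2 = Dataset(rebuilt, dataset.provenance)
        res = fit_modulated_gain(ds2, modulator="fy")
        assert res.gains.kp == pytest.approx(kp, abs=1e-3)
        assert res.gains.kv == pytest.approx(kv, abs=1e-3)
        assert res.r2 > 0.999

    def test_degenerate_modulator(self, continuous_smooth_noisy):
        dataset, _ = continuous_smooth_noisy
        zeroed = [dataclasses.replace(tr, grf_vertical=np.zeros(tr.n_samples))
                  for tr in dataset]
        # zero Fy removes gait events detectability but trials keep stored
        # events; the modulator is zero over every stance row
        with pytest.raises(DegenerateModulatorError):
            fit_modulated_gain(Dataset(zeroed), modulator="fy")

    def test_cop_modulator_requires_bounds(self, continuous_smooth_noisy):
        dataset, _ = continuous_smooth_noisy
        stripped = [dataclasses.replace(tr, foot_heel_ap=None, foot_toe_ap=None)
                    for tr in dataset]
        with pytest.raises(ValidationError, match="foot"):
            fit_modulated_gain(Dataset(stripped), modulator="cop_bound")


class TestDelaySensitivity:
    def test_single_value_grid(self, standing_noisy):
        dataset, _ = standing_noisy
        sweep = delay_sensitivity(dataset, [0.1])
        assert len(sweep.taus) == 1
        assert sweep.tau_best == 0.1

    def test_empty_grid(self, standing_noisy):
        dataset, _ = standing_noisy
        with pytest.raises(ValueError):
            delay_sensitivity(dataset, [])

    def test_argmax_near_true_delay(self, standing_noisy):
        dataset, truth = standing_noisy
        sweep = delay_sensitivity(dataset, np.arange(0.0, 0.201, 0.01))
        assert abs(sweep.tau_best - truth.tau_T) <= 0.0101

    def test_r2_decreases_away_from_true_delay(self, standing_noisy):
        dataset, _ = standing_noisy
        sweep = delay_sensitivity(dataset, [0.02, 0.10, 0.18])
        assert sweep.r2[1] > sweep.r2[0]
        assert sweep.r2[1] > sweep.r2[2]


class TestSerialization:
    def test_csv_round_trip_columns(self, tmp_path, standing_noiseless,
                                    continuous_binned_noiseless):
        import pandas as pd

        scalar = fit_discrete_onset(standing_noiseless[0])
        binned = fit_phase_binned(continuous_binned_noiseless[0])
        out = tmp_path / "fits.csv"
        fit_results_to_csv([scalar, binned], out)
        df = pd.read_csv(out)
        assert set(df.columns) == {"model", "output", "scope", "bin_lo",
                                   "bin_hi", "direction", "Kp", "Kv", "r2",
                                   "rmse", "n_rows"}
        assert len(df) == 1 + 16

    def test_delay_override_matches_default(self, standing_noiseless):
        dataset, _ = standing_noiseless
        a = fit_discrete_onset(dataset)
        b = fit_discrete_onset(dataset, tau_T_override=0.100)
        assert a.gains.kp == b.gains.kp

    def test_joint_delay_config(self):
        cfg = DelayConfig.for_model("joint")
        assert cfg.tau_m == 0.040 and cfg.tau_T == 0.080
        cfg = DelayConfig.for_model("com")
        assert cfg.tau_m == 0.060 and cfg.tau_T == 0.100
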