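import math

import numpy as np
import pytest
from scipy.optimize import minimize_scalar

from osteounit import phantoms, relaxation
from osteounit.relaxation import (
    LoadingProtocol,
    PiecewiseRelaxationModel,
    RelaxationCurve,
    compute_stress_strain,
    extract_moduli,
    fit_piecewise,
)

PARAM_NAMES = ("A1", "tau1", "B1", "A2", "tau2", "B2")
RESULT_KEYS = ("A1_kPa", "tau1_s", "B1_kPa", "A2_kPa", "tau2_s", "B2_kPa")


class TestStressStrain:
    def test_unit_force_maps_to_known_stress(self, protocol):
        # 1 N over a 6.4 mm circle is 1/(pi*3.2^2) N/mm^2 = 31.08 kPa
        t = np.arange(30.0)
        f = np.concatenate([np.linspace(0, 1, 5), np.full(25, 1.0)])
        d = np.concatenate([np.linspace(0, 255, 5), np.full(25, 255.0)])
        curve = compute_stress_strain(t, f, d, protocol)
        assert curve.stress_kPa[0] == pytest.approx(31.08, abs=0.01)

    def test_zero_force_zero_stress(self, protocol):
        t = np.arange(20.0)
        f = np.zeros(20)
        f[0] = 1e-9  # peak marker at ramp end
        curve = compute_stress_strain(t, f, np.full(20, 255.0), protocol)
        assert np.allclose(curve.stress_kPa[1:], 0.0)

    def test_strain_is_displacement_over_thickness(self, protocol):
        disp = 0.15 * protocol.sample_thickness_mm * 1000.0
        t = np.arange(15.0)
        curve = compute_stress_strain(t, np.ones(15), np.full(15, disp), protocol)
        assert curve.applied_strain == pytest.approx(0.150)

    def test_non_monotone_time_rejected(self, protocol):
        with pytest.raises(ValueError, match="increasing"):
            compute_stress_strain([0, 1, 1], [1, 1, 1], [9, 9, 9], protocol)


class TestModuli:
    def test_constant_curve_moduli(self, protocol):
        curve = RelaxationCurve(np.arange(0, 901.0), np.ones(901), 0.15, protocol)
        mod = extract_moduli(curve, eq_window_s=100.0)
        assert mod.E_peak_kPa == pytest.approx(1.0 / 0.15, rel=1e-9)
        assert mod.E_eq_kPa == pytest.approx(6.67, abs=0.01)

    def test_exact_recovery_on_noiseless_truth(self, noiseless_curve,
                                               terrestrial_truth):
        mod = extract_moduli(noiseless_curve)
        sigma_peak = terrestrial_truth.A1 + terrestrial_truth.B1
        assert mod.sigma_peak_kPa == pytest.approx(sigma_peak, rel=1e-12)
        assert mod.E_peak_kPa >= mod.E_eq_kPa

    def test_noisy_equilibrium_within_standard_error(self, terrestrial_truth):
        sd = 0.05
        devs = []
        for seed in range(20):
            curve, _ = phantoms.gen_relaxation_curve(
                truth=terrestrial_truth, noise_sd_kPa=sd, seed=seed)
            mod = extract_moduli(curve, eq_window_s=100.0)
            n = np.sum(curve.time_s >= curve.time_s[-1] - 100.0)
            truth_eq = float(np.mean(terrestrial_truth.evaluate(
                curve.time_s[curve.time_s >= curve.time_s[-1] - 100.0])))
            devs.append(abs(mod.sigma_eq_kPa - truth_eq) / (sd / math.sqrt(n)))
        # deviations are ~N(0,1) in SEM units; the median must sit well below 3
        assert np.median(devs) < 3.0

    def test_window_longer_than_hold_rejected(self, noiseless_curve):
        with pytest.raises(ValueError, match="exceeds"):
            extract_moduli(noiseless_curve, eq_window_s=1e5)


class TestPiecewiseFit:
    def test_constant_curve_degenerates(self, protocol):
        curve = RelaxationCurve(np.arange(0, 901.0), np.ones(901), 0.15, protocol)
        res = fit_piecewise(curve)
        assert abs(res.A1_kPa) < 1e-6
        assert abs(res.A2_kPa) < 1e-6
        assert res.B1_kPa == pytest.approx(1.0, abs=1e-6)
        assert res.B2_kPa == pytest.approx(1.0, abs=1e-6)
        assert res.rmse_kPa < 1e-8

    def test_noiseless_parameter_recovery(self, noiseless_curve,
                                          terrestrial_truth):
        res = fit_piecewise(noiseless_curve)
        for name, key in zip(PARAM_NAMES, RESULT_KEYS):
            truth_val = getattr(terrestrial_truth, name)
            assert res.params[key] == pytest.approx(truth_val, rel=1e-3), name

    def test_constraints_hold_on_noisy_fits(self, terrestrial_truth):
        for seed in range(5):
            curve, _ = phantoms.gen_relaxation_curve(
                truth=terrestrial_truth, noise_sd_kPa=0.07, seed=seed)
            res = fit_piecewise(curve)
            tol = 1e-6 * res.sigma_peak_kPa
            assert res.continuity_residual_kPa <= tol
            assert res.peak_residual_kPa <= tol

    def test_two_branch_rmse_never_worse_than_single_exponential(
            self, terrestrial_truth):
        # the two-branch model nests the constrained single exponential
        # (tau1 = tau2, shared amplitude), so its RMSE can only be lower
        curve, _ = phantoms.gen_relaxation_curve(
            truth=terrestrial_truth, noise_sd_kPa=0.07, seed=3)
        model = PiecewiseRelaxationModel(curve)

        def single_rmse(log_tau):
            tau = math.exp(log_tau)
            w = float(np.mean(np.exp(-model._t_win / tau)))
            if abs(1.0 - w) < 1e-12:
                return np.inf
            A = (model.sigma_peak - model.sigma_eq) / (1.0 - w)
            B = model.sigma_peak - A
            pred = A * np.exp(-curve.time_s / tau) + B
            return float(np.sqrt(np.mean((pred - curve.stress_kPa) ** 2)))

        opt = minimize_scalar(single_rmse, bounds=(0.0, 9.0), method="bounded")
        assert fit_piecewise(curve).rmse_kPa <= opt.fun + 1e-12

    def test_scale_equivariance(self, noiseless_curve):
        res = fit_piecewise(noiseless_curve)
        scaled = RelaxationCurve(
            noiseless_curve.time_s, 3.7 * noiseless_curve.stress_kPa,
            noiseless_curve.applied_strain, noiseless_curve.protocol)
        res2 = fit_piecewise(scaled)
        assert res2.tau1_s == pytest.approx(res.tau1_s, rel=1e-6)
        assert res2.tau2_s == pytest.approx(res.tau2_s, rel=1e-6)
        for key in ("A1_kPa", "B1_kPa", "A2_kPa", "B2_kPa"):
            assert res2.params[key] == pytest.approx(3.7 * res.params[key],
                                                     rel=1e-6)

    def test_short_curve_rejected(self, protocol):
        curve = RelaxationCurve(np.arange(0, 50.0), np.ones(50), 0.15, protocol)
        with pytest.raises(ValueError, match="t_split"):
            fit_piecewise(curve)


class TestGroupRates:
    def test_preset_tau1_ordering_and_equal_tau2(self):
        fits = {"terrestrial": [], "aquatic": []}
        for habitat in fits:
            truth = phantoms.relaxation_preset(habitat)
            for seed in range(9):
                curve, _ = phantoms.gen_relaxation_curve(
                    truth=truth, noise_sd_kPa=0.02, seed=seed)
                fits[habitat].append(fit_piecewise(curve))
        out = relaxation.compare_relaxation_rates(fits)
        g = out["groups"]
        assert g["aquatic"]["tau1_mean_s"] > g["terrestrial"]["tau1_mean_s"]
        # both presets share tau2 = 300 s: the slow phase must not differ
        assert out["comparisons"]["tau2"].pairwise.p_adj.iloc[0] > 0.05

    def test_identical_groups_not_significant(self, terrestrial_truth):
        fits = []
        for seed in range(4):
            curve, _ = phantoms.gen_relaxation_curve(
                truth=terrestrial_truth, noise_sd_kPa=0.05, seed=seed)
            fits.append(fit_piecewise(curve))
        out = relaxation.compare_relaxation_rates({"a": fits, "b": list(fits)})
        assert out["comparisons"]["tau1"].anova_p > 0.9

    def test_single_member_group_rejected(self, noiseless_curve):
        res = fit_piecewise(noiseless_curve)
        with pytest.raises(ValueError, match="at least 2"):
            relaxation.compare_relaxation_rates({"a": [res, res], "b": [res]})


class TestProtocolValidation:
    @pytest.mark.parametrize("kwargs", [
        dict(sample_diameter_mm=-1, sample_thickness_mm=1.7),
        dict(sample_diameter_mm=6.4, sample_thickness_mm=1.7, target_strain=1.5),
    ])
    def test_invalid_protocol(self, kwargs):
        with pytest.raises(ValueError):
            LoadingProtocol(**kwargs)
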