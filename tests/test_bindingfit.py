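"""Binding fitters: self-inversion, noise robustness, ITC mass balance, CSP."""

import numpy as np
import pytest
from scipy import optimize

from ccpquant import bindingfit, synthgen
from ccpquant.bindingfit import (ITCExperiment, fit_amplitude_isotherm,
                                 fit_anisotropy, fit_dissociation, fit_itc,
                                 itc_predicted_heats, shift_perturbation)


class TestAnisotropy:
    def test_noiseless_self_inversion(self):
        df = synthgen.generate_titration(
            "anisotropy", {"F_f": 0.08, "F_b": 0.25, "Kd_uM": 10.0},
            design={"ligand_uM": np.geomspace(0.2, 300, 14)})
        fit = fit_anisotropy(df["ligand_uM"], df["anisotropy"])
        assert fit.converged
        assert fit.params["Kd"] == pytest.approx(10.0, rel=1e-6)
        assert fit.params["F_f"] == pytest.approx(0.08, rel=1e-6)
        assert fit.params["F_b"] == pytest.approx(0.25, rel=1e-6)

    def test_midpoint_residual_zero(self):
        L = np.array([1.0, 3.0, 10.0, 30.0, 100.0])
        F = bindingfit.anisotropy_model(L, 0.1, 0.3, 10.0)
        fit = fit_anisotropy(L, F)
        pred = bindingfit.anisotropy_model(10.0, **{
            k: fit.params[k] for k in ("F_f", "F_b")}, Kd=fit.params["Kd"])
        assert pred == pytest.approx((0.1 + 0.3) / 2, rel=1e-6)

    def test_noisy_median_recovery_within_10pct(self):
        kds = []
        for rep in range(50):
            df = synthgen.generate_titration(
                "anisotropy", {"F_f": 0.1, "F_b": 0.3, "Kd_uM": 10.0},
                design={"ligand_uM": np.geomspace(0.2, 300, 14)},
                noise_sd=0.004, seed=rep)  # 2% of the anisotropy span
            kds.append(fit_anisotropy(df["ligand_uM"],
                                      df["anisotropy"]).params["Kd"])
        assert abs(np.median(kds) - 10.0) / 10.0 < 0.10

    def test_no_saturation_flagged(self):
        L = np.array([0.01, 0.02, 0.05, 0.1, 0.2])  # far below Kd
        F = bindingfit.anisotropy_model(L, 0.1, 0.3, 50.0)
        fit = fit_anisotropy(L, F)
        assert not fit.converged and "no_saturation" in fit.flags


class TestDissociation:
    def test_zero_slow_amplitude_collapses_single_exponential(self):
        t = np.arange(0, 511, 1.0)
        R = 50.0 * np.exp(-0.05 * t)
        fit = fit_dissociation(t, R)
        assert fit.params["A_fast"] == pytest.approx(50.0, rel=1e-3)
        assert fit.params["k_fast"] == pytest.approx(0.05, rel=1e-3)
        assert abs(fit.params["A_slow"]) < 0.5

    def test_noisy_biexponential_recovery_within_15pct(self):
        truth = {"A_fast": 50.0, "k_fast": 0.05, "A_slow": 30.0,
                 "k_slow": 0.005}
        df = synthgen.generate_titration("spr_dissociation", truth,
                                         noise_sd=0.8, seed=5)  # 1% of R0
        fit = fit_dissociation(df["time_s"], df["response_RU"])
        for k, v in truth.items():
            assert fit.params[k] == pytest.approx(v, rel=0.15)

    def test_rate_ordering_contract(self):
        for seed in range(5):
            df = synthgen.generate_titration(
                "spr_dissociation",
                {"A_fast": 40.0, "k_fast": 0.08, "A_slow": 25.0,
                 "k_slow": 0.004}, noise_sd=0.5, seed=seed)
            fit = fit_dissociation(df["time_s"], df["response_RU"])
            assert fit.params["k_fast"] > fit.params["k_slow"] >= 0


class TestAmplitudeIsotherm:
    def test_noiseless_self_inversion(self):
        C = np.geomspace(0.05, 50.0, 8)  # 50 nM .. 50 uM in uM
        A = bindingfit.amplitude_isotherm(C, 120.0, 2.0)
        fit = fit_amplitude_isotherm(C, A)
        assert fit.params["K_D"] == pytest.approx(2.0, rel=1e-6)
        assert fit.params["A_max"] == pytest.approx(120.0, rel=1e-6)

    def test_half_saturation_at_kd(self):
        assert bindingfit.amplitude_isotherm(2.0, 120.0, 2.0) == \
            pytest.approx(60.0)

    def test_noisy_recovery_within_20pct(self, rng):
        C = np.geomspace(0.05, 50.0, 8)
        kds = []
        for rep in range(50):
            A = bindingfit.amplitude_isotherm(C, 120.0, 2.0)
            A = A + rng.normal(0, 6.0, len(C))  # 5% of A_max
            kds.append(fit_amplitude_isotherm(C, A).params["K_D"])
        assert abs(np.median(kds) - 2.0) / 2.0 < 0.20


def itc_oracle_heats(exp: ITCExperiment, Kd, n, dH):
    """Independent mass-balance integration: per injection, explicit mole
    bookkeeping plus brentq root-finding on the mass-action equation (no
    closed-form quadratic)."""
    V0 = exp.cell_volume_L
    M, X, B_prev = exp.cell_conc_M, 0.0, 0.0
    out = []
    for v in np.asarray(exp.injection_volumes_L, float):
        d = 1.0 - v / V0
        M *= d
        X = X * d + exp.syringe_conc_M * v / V0

        def mass_action(B):
            return (n * M - B) * (X - B) / Kd - B

        B = optimize.brentq(mass_action, 0.0, min(n * M, X) * (1 - 1e-15))
        out.append(dH * V0 * (B - B_prev * d))
        B_prev = B
    return np.array(out)


class TestITC:
    DESIGN = dict(cell_conc_M=125e-6, syringe_conc_M=2.5e-3)

    def test_oracle_equivalence(self):
        """Closed-form heats match the independent brentq integration."""
        exp = ITCExperiment(**self.DESIGN)
        for kd in (55e-6, 8e-6, 1e-7):
            ours = itc_predicted_heats(exp, kd, 1.0, -40e3)
            oracle = itc_oracle_heats(exp, kd, 1.0, -40e3)
            assert np.max(np.abs(ours - oracle)) / np.max(np.abs(ours)) < 1e-6

    def test_noiseless_self_inversion_55uM(self):
        exp = ITCExperiment(**self.DESIGN)
        exp.heats_J = itc_predicted_heats(exp, 55e-6, 1.0, -40e3)
        fit = fit_itc(exp)
        assert fit.converged
        assert fit.params["K_D"] == pytest.approx(55e-6, rel=1e-3)
        assert fit.params["n"] == pytest.approx(1.0, rel=1e-3)
        assert fit.params["dH"] == pytest.approx(-40e3, rel=1e-3)

    def test_zero_enthalpy_zero_heats(self):
        exp = ITCExperiment(**self.DESIGN)
        assert np.allclose(itc_predicted_heats(exp, 55e-6, 1.0, 0.0), 0.0)

    def test_heat_conservation_bound(self):
        """Cumulative heat magnitude never exceeds |n dH| x initial cell
        moles and reaches it in the saturation limit."""
        exp = ITCExperiment(**self.DESIGN)
        cap = 40e3 * 1.0 * 125e-6 * exp.cell_volume_L
        total = abs(itc_predicted_heats(exp, 55e-6, 1.0, -40e3).sum())
        assert total <= cap * (1 + 1e-9)
        sat = ITCExperiment(cell_conc_M=125e-6, syringe_conc_M=50e-3,
                            injection_volumes_L=np.full(20, 0.5e-6))
        total_sat = abs(itc_predicted_heats(sat, 1e-12, 1.0, -40e3).sum())
        assert total_sat == pytest.approx(40e3 * 125e-6 * sat.cell_volume_L,
                                          rel=0.01)

    def test_c_value_flagged(self):
        exp = ITCExperiment(cell_conc_M=1e-6, syringe_conc_M=50e-6)
        exp.heats_J = itc_predicted_heats(exp, 1e-3, 1.0, -40e3)
        fit = fit_itc(exp)
        assert "low_information_c_value" in fit.flags


class TestShiftPerturbation:
    def test_identical_shifts_zero(self):
        shifts = {"R90": 8.2, "R113": 7.9}
        n15 = {"R90": 120.0, "R113": 118.5}
        out = shift_perturbation(shifts, n15, shifts, n15)
        assert np.allclose(out["delta_delta"], 0.0)

    def test_hand_computed_example(self):
        """ddH = 0.1, ddN = 0.5 -> sqrt(0.01 + 0.01) ~ 0.1414."""
        out = shift_perturbation({"A": 8.0}, {"A": 120.0},
                                 {"A": 8.1}, {"A": 120.5})
        assert out["delta_delta"].iloc[0] == pytest.approx(np.sqrt(0.02))

    def test_nitrogen_scaling_cancels(self):
        """ddH = 0, ddN = 5.0 -> dd = 1.0 exactly."""
        out = shift_perturbation({"A": 8.0}, {"A": 120.0},
                                 {"A": 8.0}, {"A": 125.0})
        assert out["delta_delta"].iloc[0] == pytest.approx(1.0)

    def test_missing_residues_absent_not_zero(self):
        out = shift_perturbation({"A": 8.0, "B": 7.5}, {"A": 120.0, "B": 118.0},
                                 {"A": 8.1}, {"A": 120.5})
        assert list(out.index) == ["A"]
        assert out.attrs["missing"] == ["B"]

    def test_mismatched_assignments_within_state_rejected(self):
        with pytest.raises(ValueError):
            shift_perturbation({"A": 8.0}, {"B": 120.0},
                               {"A": 8.1}, {"A": 120.5})


class TestUnitHonesty:
    def test_kd_in_input_units(self):
        """Fitting the same curve in uM and M gives K_D differing by 1e6."""
        L_uM = np.geomspace(0.2, 300, 14)
        F = bindingfit.anisotropy_model(L_uM, 0.1, 0.3, 10.0)
        kd_uM = fit_anisotropy(L_uM, F).params["Kd"]
        kd_M = fit_anisotropy(L_uM * 1e-6, F).params["Kd"]
        assert kd_uM == pytest.approx(10.0, rel=1e-6)
        assert kd_M * 1e6 == pytest.approx(kd_uM, rel=1e-4)
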