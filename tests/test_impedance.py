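"""Element models, circuit composition, Cole–Cole analysis and complex
nonlinear least-squares fitting."""

import numpy as np
import pytest

from aptascreen.impedance import (CircuitSpec, ColeColeCurve, FitResult,
                                  ImpedanceSpectrum, circuit_impedance,
                                  cole_cole_transform, effective_capacitance,
                                  eis_decision_rule, extract_eis_features,
                                  fit_circuit, select_circuit,
                                  topology_parameters, z_cpe, z_warburg)
from aptascreen.synthetic import (default_faradaic_circuit,
                                  default_frequencies,
                                  default_nonfaradaic_circuit, simulate_eis)


class TestElements:
    def test_cpe_alpha_one_is_ideal_capacitor(self):
        z = z_cpe(1e-6, 1.0, 1e3)
        assert z == pytest.approx(-1000j)

    def test_cpe_alpha_zero_limit_is_resistor(self):
        z = z_cpe(0.01, 1e-9, 50.0)
        assert z.real == pytest.approx(100.0, rel=1e-6)
        assert abs(z.imag) < 1e-4

    def test_cpe_modulus_and_phase_at_table_values(self):
        T, alpha = 4.2e-5, 0.72
        omega = 2 * np.pi * 100.0
        z = z_cpe(T, alpha, omega)
        assert abs(z) == pytest.approx(1.0 / (T * omega**alpha), rel=1e-12)
        assert np.degrees(np.angle(z)) == pytest.approx(-64.8, abs=0.05)

    def test_cpe_magnitude_at_reference_frequency(self):
        omega = 2 * np.pi * 159.15  # ~1e3 rad/s
        assert abs(z_cpe(1e-6, 1.0, omega)) == pytest.approx(1.0e3, rel=1e-3)

    def test_cpe_rejects_out_of_range_alpha(self):
        with pytest.raises(ValueError):
            z_cpe(1e-6, 1.2, 100.0)
        with pytest.raises(ValueError):
            z_cpe(1e-6, 0.0, 100.0)

    def test_semi_infinite_warburg_at_unit_omega(self):
        assert z_warburg(100.0, 0.5, "semi_infinite", 1.0) \
            == pytest.approx(100.0 - 100.0j)

    def test_semi_infinite_warburg_constant_phase(self):
        for omega in (0.1, 10.0, 1e4):
            z = z_warburg(50.0, 0.5, "semi_infinite", omega)
            assert np.degrees(np.angle(z)) == pytest.approx(-45.0)

    def test_generalized_short_approaches_semi_infinite_scaling(self):
        """At large omega*tau with P = 0.5, |Z| halves when omega
        quadruples, the semi-infinite diffusion signature."""
        R, tau = 100.0, 1.0
        z1 = z_warburg(R, 0.5, "generalized_short", 1e4, tau=tau)
        z2 = z_warburg(R, 0.5, "generalized_short", 4e4, tau=tau)
        assert abs(z1) / abs(z2) == pytest.approx(2.0, rel=1e-3)

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError, match="variant"):
            z_warburg(100.0, 0.5, "spiral", 1.0)


class TestCircuitImpedance:
    def test_randles_reduction_apex_and_diameter(self):
        """With an ideal capacitor and negligible Warburg, M0 reduces to the
        textbook Randles semicircle: -Im peak at omega = 1/(Rct*C) and
        real-axis diameter Rct."""
        Rs, Rct, C = 100.0, 2000.0, 1e-6
        circuit = CircuitSpec("M0_randles_w",
                              {"Rs": Rs, "CPE_T": C, "CPE_P": 1.0,
                               "Rct": Rct, "W_R": 1e-9},
                              warburg_variant="semi_infinite")
        freqs = np.logspace(-2, 6, 4000)
        spectrum = circuit_impedance(circuit, freqs)
        z = spectrum.impedance
        apex_omega = spectrum.omega[np.argmax(-z.imag)]
        assert apex_omega == pytest.approx(1.0 / (Rct * C), rel=5e-3)
        diameter = z.real.max() - Rs
        assert diameter == pytest.approx(Rct, rel=1e-3)

    def test_high_frequency_limit_is_series_resistance(self):
        circuit = default_faradaic_circuit()
        spectrum = circuit_impedance(circuit, [1e6, 5e5, 2e5, 1e5,
                                               5e4, 2e4, 1e4, 5e3])
        assert spectrum.impedance.real[0] == pytest.approx(
            circuit["Rs"], rel=0.01)

    def test_m2_is_series_sum_of_its_blocks(self):
        circuit = default_nonfaradaic_circuit()
        freqs = default_frequencies(16)
        omega = 2 * np.pi * freqs
        p = circuit.parameters
        block1 = 1.0 / (1.0 / z_cpe(p["CPE1_T"], p["CPE1_P"], omega)
                        + 1.0 / p["Rp1"])
        zw = z_warburg(p["W_R"], p["W_P"], "generalized_short", omega,
                       tau=p["W_tau"])
        block2 = 1.0 / (1.0 / z_cpe(p["CPE2_T"], p["CPE2_P"], omega)
                        + 1.0 / (p["Rp2"] + zw))
        expected = p["Rs"] + block1 + block2
        np.testing.assert_allclose(
            circuit_impedance(circuit, freqs).impedance, expected,
            rtol=1e-12)

    def test_missing_parameter_named_in_error(self):
        params = dict(default_faradaic_circuit().parameters)
        params.pop("Rct")
        with pytest.raises(ValueError, match="Rct"):
            CircuitSpec("M0_randles_w", params)

    def test_real_part_monotone_in_frequency_for_defaults(self):
        """Kramers–Kronig-consistent forward models: Re(Z) never increases
        with frequency for the implemented topologies at defaults."""
        freqs = default_frequencies(80)
        for circuit in (default_faradaic_circuit(),
                        default_nonfaradaic_circuit()):
            re = circuit_impedance(circuit, freqs).impedance.real
            assert np.all(np.diff(re) >= -1e-9)  # descending freq order


class TestColeCole:
    def test_pure_capacitor_identity(self):
        C = 1e-6
        freqs = default_frequencies(16)
        omega = 2 * np.pi * freqs
        spectrum = ImpedanceSpectrum(freqs, z_cpe(C, 1.0, omega))
        curve = cole_cole_transform(spectrum)
        np.testing.assert_allclose(curve.C_real, C, rtol=1e-12)
        np.testing.assert_allclose(curve.C_imag, 0.0, atol=1e-18)

    def test_pure_resistor(self):
        R = 250.0
        freqs = default_frequencies(16)
        spectrum = ImpedanceSpectrum(
            freqs, np.full(16, complex(R, 0.0)))
        curve = cole_cole_transform(spectrum)
        np.testing.assert_allclose(curve.C_real, 0.0, atol=1e-18)
        np.testing.assert_allclose(
            curve.C_imag, 1.0 / (curve.angular_frequencies * R), rtol=1e-12)

    def test_series_rc_at_characteristic_frequency(self):
        R, C = 100.0, 1e-6
        omega_c = 1.0 / (R * C)
        freqs = np.array([omega_c]) / (2 * np.pi)
        freqs = np.concatenate([default_frequencies(8) * 1e3, freqs])
        z = R + 1.0 / (1j * 2 * np.pi * freqs * C)
        curve = cole_cole_transform(ImpedanceSpectrum(freqs, z))
        idx = np.argmin(np.abs(curve.angular_frequencies - omega_c))
        assert curve.C_real[idx] == pytest.approx(C / 2, rel=1e-9)


class TestEISFeatures:
    def test_capacitor_plateau_and_missing_extrema(self):
        C = 1e-6
        freqs = default_frequencies(20)
        spectrum = ImpedanceSpectrum(freqs, z_cpe(C, 1.0, 2 * np.pi * freqs))
        feats = extract_eis_features(cole_cole_transform(spectrum))
        assert feats.C_dl == pytest.approx(C, rel=1e-9)
        assert np.isnan(feats.omega_min)
        assert np.isnan(feats.omega_max)

    def test_blocking_cell_minimum_lies_between_relaxations(self):
        """A blocking double-interface cell has two in-band loss
        relaxations; the C'' dip sits between them (brute-force dense-grid
        oracle)."""
        circuit = CircuitSpec("M2_nonfaradaic", {
            "Rs": 400.0, "CPE1_T": 4.0e-5, "CPE1_P": 0.90, "Rp1": 2e5,
            "CPE2_T": 5.0e-6, "CPE2_P": 0.85, "Rp2": 5e4,
            "W_R": 1500.0, "W_tau": 0.05, "W_P": 0.45})
        feats = extract_eis_features(
            cole_cole_transform(circuit_impedance(circuit,
                                                  default_frequencies(60))))
        assert np.isfinite(feats.omega_min) and np.isfinite(feats.omega_max)
        assert feats.omega_min != feats.omega_max
        # dense-grid oracle for the dip location
        dense = cole_cole_transform(
            circuit_impedance(circuit, default_frequencies(2000)))
        o = np.argsort(dense.angular_frequencies)
        w, ci = dense.angular_frequencies[o], dense.C_imag[o]
        interior = slice(1, -1)
        mins = [i for i in range(1, len(ci) - 1)
                if ci[i] < ci[i - 1] and ci[i] < ci[i + 1]]
        oracle_omega = w[min(mins, key=lambda i: ci[i])]
        assert feats.omega_min == pytest.approx(oracle_omega, rel=0.1)
        assert feats.omega_min < feats.omega_max

    def test_c_min_is_real_part_at_omega_min(self):
        circuit = CircuitSpec("M2_nonfaradaic", {
            "Rs": 400.0, "CPE1_T": 4.0e-5, "CPE1_P": 0.90, "Rp1": 2e5,
            "CPE2_T": 5.0e-6, "CPE2_P": 0.85, "Rp2": 5e4,
            "W_R": 1500.0, "W_tau": 0.05, "W_P": 0.45})
        curve = cole_cole_transform(
            circuit_impedance(circuit, default_frequencies(60)))
        feats = extract_eis_features(curve)
        idx = np.argmin(np.abs(curve.angular_frequencies - feats.omega_min))
        assert feats.C_min == pytest.approx(curve.C_real[idx])

    def test_invariant_to_frequency_sort_order(self):
        circuit = default_nonfaradaic_circuit()
        curve = cole_cole_transform(
            circuit_impedance(circuit, default_frequencies(40)))
        flipped = ColeColeCurve(curve.angular_frequencies[::-1].copy(),
                                curve.C_real[::-1].copy(),
                                curve.C_imag[::-1].copy())
        a = extract_eis_features(curve).as_dict()
        b = extract_eis_features(flipped).as_dict()
        for key in a:
            np.testing.assert_equal(a[key], b[key])

    def test_short_curve_rejected(self):
        curve = ColeColeCurve(np.arange(1.0, 6.0), np.ones(5), np.ones(5))
        with pytest.raises(ValueError, match="at least 8"):
            extract_eis_features(curve)


class TestFitCircuit:
    def test_noiseless_self_generated_recovery(self):
        circuit = default_faradaic_circuit()
        spectrum = circuit_impedance(circuit, default_frequencies(40))
        fit = fit_circuit(spectrum, "M0_randles_w")
        assert fit.converged
        for name, truth in circuit.parameters.items():
            assert fit.circuit[name] == pytest.approx(truth, rel=1e-3), name

    def test_cpe_recovery_at_reference_values(self):
        """Zero-noise spectrum generated with CPE-T = 4.2e-5 and
        CPE-P = 0.72: both recovered within 1% / 0.01."""
        circuit = default_faradaic_circuit(CPE_T=4.2e-5, CPE_P=0.72)
        spectrum = circuit_impedance(circuit, default_frequencies(40))
        fit = fit_circuit(spectrum, "M0_randles_w", weighting="modulus")
        assert fit.circuit["CPE_T"] == pytest.approx(4.2e-5, rel=0.01)
        assert fit.circuit["CPE_P"] == pytest.approx(0.72, abs=0.01)
        assert fit.chi_square < 1e-12

    def test_zero_noise_recovery_all_topologies(self):
        for circuit in (default_faradaic_circuit(),
                        default_nonfaradaic_circuit()):
            spectrum = circuit_impedance(circuit, default_frequencies(40))
            fit = fit_circuit(spectrum, circuit.topology_id)
            for name, truth in circuit.parameters.items():
                assert fit.circuit[name] == pytest.approx(truth, rel=1e-6), \
                    (circuit.topology_id, name)

    def test_monte_carlo_recovery_under_noise(self):
        """1% multiplicative noise: median relative error of every
        parameter stays below 10% over 50 replicates."""
        circuit = CircuitSpec(
            "M0_randles_w",
            {"Rs": 100.0, "CPE_T": 4.2e-5, "CPE_P": 0.72, "Rct": 5000.0,
             "W_R": 3000.0},
            warburg_variant="semi_infinite")
        freqs = default_frequencies(40)
        errors = {name: [] for name in circuit.parameters}
        for rep in range(50):
            spectrum = simulate_eis(circuit, freqs, noise_fraction=0.01,
                                    seed=rep)
            fit = fit_circuit(spectrum, "M0_randles_w", n_starts=2,
                              warburg_variant="semi_infinite")
            for name, truth in circuit.parameters.items():
                errors[name].append(abs(fit.circuit[name] - truth) / truth)
        for name, errs in errors.items():
            assert np.median(errs) < 0.10, name

    def test_refit_from_converged_solution_is_idempotent(self):
        circuit = default_faradaic_circuit()
        spectrum = simulate_eis(circuit, default_frequencies(40),
                                noise_fraction=0.01, seed=0)
        fit1 = fit_circuit(spectrum, "M0_randles_w", n_starts=2)
        fit2 = fit_circuit(spectrum, "M0_randles_w",
                           initial_guess=fit1.circuit, n_starts=0)
        assert fit2.chi_square <= fit1.chi_square * (1 + 1e-9)

    def test_uncertainties_are_finite_and_nonnegative(self):
        circuit = default_faradaic_circuit()
        spectrum = simulate_eis(circuit, default_frequencies(40),
                                noise_fraction=0.02, seed=3)
        fit = fit_circuit(spectrum, "M0_randles_w", n_starts=2)
        for name, sigma in fit.uncertainties.items():
            assert np.isfinite(sigma) and sigma >= 0, name

    def test_too_short_spectrum_rejected(self):
        circuit = default_faradaic_circuit()
        spectrum = circuit_impedance(circuit, default_frequencies(8))
        assert spectrum.impedance.size == 8
        with pytest.raises(ValueError, match="free parameters"):
            fit_circuit(spectrum, "M2_nonfaradaic")


class TestEffectiveCapacitance:
    def test_alpha_one_returns_T_for_both_methods(self):
        assert effective_capacitance(1e-5, 1.0, "hsu_mansfeld",
                                     omega_peak=123.0) \
            == pytest.approx(1e-5)
        assert effective_capacitance(1e-5, 1.0, "brug", Rs=100.0,
                                     Rct=1e4) == pytest.approx(1e-5)

    def test_brug_closed_form_value(self):
        # hand-evaluated: (1e-5)^(1/0.9) * (1/100 + 1/1e4)^(-0.1/0.9)
        value = effective_capacitance(1e-5, 0.9, "brug", Rs=100.0, Rct=1e4)
        assert value == pytest.approx(4.6365e-6, rel=1e-4)

    def test_methods_agree_within_factor_two_on_single_arc(self):
        Rs, Rct, T, alpha = 100.0, 2000.0, 1e-5, 0.9
        circuit = CircuitSpec("M0_randles_w",
                              {"Rs": Rs, "CPE_T": T, "CPE_P": alpha,
                               "Rct": Rct, "W_R": 1e-9},
                              warburg_variant="semi_infinite")
        spectrum = circuit_impedance(circuit, np.logspace(-1, 5, 500))
        omega_peak = spectrum.omega[np.argmax(-spectrum.impedance.imag)]
        c_hm = effective_capacitance(T, alpha, "hsu_mansfeld",
                                     omega_peak=omega_peak)
        c_brug = effective_capacitance(T, alpha, "brug", Rs=Rs, Rct=Rct)
        assert 0.5 < c_hm / c_brug < 2.0

    def test_missing_context_is_named(self):
        with pytest.raises(ValueError, match="omega_peak"):
            effective_capacitance(1e-5, 0.9, "hsu_mansfeld")
        with pytest.raises(ValueError, match="Rs"):
            effective_capacitance(1e-5, 0.9, "brug", Rct=1e4)


class TestSelectCircuit:
    FREQS = default_frequencies(40)
    M0 = default_faradaic_circuit()
    M1 = CircuitSpec("M1_randles_w_extra",
                     dict(M0.parameters, CPE2_T=1e-5, CPE2_P=0.9,
                          Rp2=1500.0))

    def test_extra_block_detected_when_present(self):
        spectrum = simulate_eis(self.M1, self.FREQS, noise_fraction=0.01,
                                seed=2)
        best, fits = select_circuit(
            spectrum, ["M0_randles_w", "M1_randles_w_extra"], n_starts=3)
        assert best == "M1_randles_w_extra"
        assert fits["M1_randles_w_extra"].aic < fits["M0_randles_w"].aic

    def test_parsimony_wins_when_extra_block_absent(self):
        spectrum = simulate_eis(self.M0, self.FREQS, noise_fraction=0.01,
                                seed=1)
        best, _ = select_circuit(
            spectrum, ["M0_randles_w", "M1_randles_w_extra"], n_starts=3)
        assert best == "M0_randles_w"

    def test_fewer_than_two_candidates_rejected(self):
        spectrum = circuit_impedance(self.M0, self.FREQS)
        with pytest.raises(ValueError, match="two candidate"):
            select_circuit(spectrum, ["M0_randles_w"])


def _m2_fit(cpe1_t, cpe2_t, converged=True):
    base = default_nonfaradaic_circuit()
    circuit = base.with_parameters(CPE1_T=cpe1_t, CPE2_T=cpe2_t)
    return FitResult(circuit=circuit, uncertainties={}, chi_square=0.0,
                     n_points=40, converged=converged, aic=0.0)


class TestDecisionRule:
    def test_order_of_magnitude_drop_with_rise_is_positive(self):
        decision = eis_decision_rule(_m2_fit(4e-5, 1e-6),
                                     _m2_fit(4e-7, 3e-6))
        assert decision.call == "LC_positive"
        assert decision.log10_cpe1_drop == pytest.approx(2.0)

    def test_identical_fits_are_negative(self):
        decision = eis_decision_rule(_m2_fit(4e-5, 1e-6),
                                     _m2_fit(4e-5, 1e-6))
        assert decision.call == "negative"

    def test_drop_without_rise_is_negative(self):
        decision = eis_decision_rule(_m2_fit(4e-5, 2e-6),
                                     _m2_fit(4e-7, 1e-6))
        assert decision.call == "negative"

    def test_non_converged_fit_is_indeterminate(self):
        with pytest.warns(UserWarning, match="non-converged"):
            decision = eis_decision_rule(
                _m2_fit(4e-5, 1e-6), _m2_fit(4e-7, 3e-6, converged=False))
        assert decision.call == "indeterminate"

    def test_wrong_topology_rejected(self):
        fit = FitResult(circuit=default_faradaic_circuit(),
                        uncertainties={}, chi_square=0.0, n_points=40,
                        converged=True, aic=0.0)
        with pytest.raises(ValueError, match="M2"):
            eis_decision_rule(fit, fit)


class TestSpectrumValidation:
    def test_zero_frequency_rejected(self):
        freqs = np.array([0.0, 1, 2, 3, 4, 5, 6, 7], dtype=float)
        with pytest.raises(ValueError, match="positive"):
            ImpedanceSpectrum(freqs, np.ones(8, dtype=complex))

    def test_short_spectrum_rejected(self):
        with pytest.raises(ValueError, match="at least 8"):
            ImpedanceSpectrum(np.arange(1.0, 6.0),
                              np.ones(5, dtype=complex))

    def test_sorted_descending_on_construction(self):
        freqs = np.arange(1.0, 9.0)
        spectrum = ImpedanceSpectrum(freqs, np.ones(8, dtype=complex)
                                     * (1 + 1j))
        assert np.all(np.diff(spectrum.frequencies) < 0)
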