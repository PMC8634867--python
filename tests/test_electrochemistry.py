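"""Surface-confined voltammetry: simulation, peaks, thermodynamics, kinetics."""

import numpy as np
import pytest

import ccbiophys as cc
from ccbiophys.electrochemistry import (
    FARADAY,
    GAS_CONSTANT,
    _model_peaks,
    laviron_irreversible_peak,
)


class TestSimulator:
    def test_reversible_limit_has_negligible_peak_separation(self):
        ks, T = 100.0, 298.15
        v = ks * GAS_CONSTANT * T / FARADAY * 1e-3  # deep reversible regime
        vg = cc.simulate_surface_voltammogram(0.0, ks, 0.5, v, T)
        epa, epc = cc.extract_peaks(vg)
        assert abs(epa - epc) < 2.0

    def test_full_conversion_over_each_half_sweep(self):
        vg = cc.simulate_surface_voltammogram(0.0, 100.0, 0.5, 1.0, 298.15,
                                              half_width_mV=400.0)
        vertex = int(np.argmax(vg.potential_mV))
        dt_up = np.abs(np.diff(vg.potential_mV[: vertex + 1])) * 1e-3 / vg.scan_rate
        # integral of |dtheta| = integral |i| dt over the anodic half sweep
        i_up = vg.current[: vertex + 1]
        conv = np.sum(np.abs(0.5 * (i_up[1:] + i_up[:-1])) * dt_up)
        assert conv == pytest.approx(1.0, abs=1e-3)

    def test_irreversible_cathodic_peak_matches_laviron_asymptote(self):
        # alpha*f*v/ks ~ 19 >> 10: closed-form asymptote applies
        e0, ks, alpha, v, T = 0.0, 10.0, 0.5, 10.0, 298.15
        _, epc = _model_peaks(e0, ks, alpha, v, T)
        expected = laviron_irreversible_peak(e0, ks, alpha, v, T, anodic=False)
        assert abs(epc - expected) < 3.0

    def test_peak_separation_monotone_in_scan_rate(self):
        seps = []
        for v in [0.5, 2.0, 10.0, 50.0, 200.0]:
            epa, epc = _model_peaks(0.0, 100.0, 0.5, v, 298.15)
            seps.append(epa - epc)
        assert np.all(np.array(seps) >= -1e-9)
        assert np.all(np.diff(seps) > -0.05)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            cc.simulate_surface_voltammogram(0.0, 100.0, 1.5, 1.0, 298.15)
        with pytest.raises(ValueError):
            cc.simulate_surface_voltammogram(0.0, 100.0, 0.5, 1.0, 298.15,
                                             half_width_mV=100.0)


class TestPeakExtraction:
    def test_reversible_wave_peaks_at_formal_potential(self):
        vg = cc.simulate_surface_voltammogram(184.0, 1300.0, 0.5, 0.1, 298.15)
        epa, epc = cc.extract_peaks(vg)
        assert epa == pytest.approx(184.0, abs=1.0)
        assert epc == pytest.approx(184.0, abs=1.0)

    def test_linear_baseline_does_not_shift_peaks(self):
        vg = cc.simulate_surface_voltammogram(0.0, 1300.0, 0.5, 1.0, 298.15)
        epa0, epc0 = cc.extract_peaks(vg)
        tilted = cc.Voltammogram(vg.potential_mV,
                                 vg.current + 2e-4 * vg.potential_mV + 0.05,
                                 vg.scan_rate, vg.temperature, vg.reference)
        epa1, epc1 = cc.extract_peaks(tilted)
        assert abs(epa1 - epa0) < 1.0 and abs(epc1 - epc0) < 1.0

    def test_quasireversible_separation_matches_simulator_positions(self):
        vg = cc.simulate_surface_voltammogram(0.0, 1300.0, 0.5, 100.0, 298.15)
        epa, epc = cc.extract_peaks(vg)
        pa, pc = _model_peaks(0.0, 1300.0, 0.5, 100.0, 298.15)
        assert epa - epc > 0
        assert epa == pytest.approx(pa, abs=1.0)
        assert epc == pytest.approx(pc, abs=1.0)

    def test_pure_noise_raises(self):
        rng = np.random.default_rng(0)
        e = np.concatenate([np.linspace(-300, 300, 500),
                            np.linspace(300, -300, 500)[1:]])
        vg = cc.Voltammogram(e, rng.normal(0, 1e-3, e.size), 1.0, 298.15)
        with pytest.raises(ValueError, match="no peak"):
            cc.extract_peaks(vg)


class TestMidpointPotential:
    def test_agcl_offset_applied(self):
        assert cc.midpoint_potential(-4.0, -12.0, "Ag/AgCl") == pytest.approx(184.0)

    def test_nhe_identity(self):
        assert cc.midpoint_potential(170.0, 170.0, "NHE") == 170.0

    def test_offset_applied_exactly_once(self):
        e = cc.midpoint_potential(-4.0, -12.0, "Ag/AgCl")
        assert cc.midpoint_potential(e, e, "NHE") == e


class TestRedoxThermodynamics:
    def test_slope_maps_to_wt_reduction_entropy(self):
        T = np.array([278.15, 288.15, 298.15, 308.15, 318.15])
        slope = -142.0 / FARADAY * 1000.0  # mV/K equivalent of -142 J/K/mol
        assert slope == pytest.approx(-1.4717, abs=1e-3)
        e = 184.0 + slope * (T - 298.15)
        thermo = cc.reduction_thermodynamics(T, e)
        assert thermo.dS_rc == pytest.approx(-142.0, abs=0.01)

    def test_zero_slope_gives_zero_entropy_and_enthalpy_from_potential(self):
        T = np.array([278.15, 298.15, 318.15])
        e = np.full(3, 184.0)
        thermo = cc.reduction_thermodynamics(T, e)
        assert thermo.dS_rc == pytest.approx(0.0, abs=1e-9)
        assert thermo.dH_rc == pytest.approx(-FARADAY * 0.184 / 1000.0, rel=1e-9)

    @pytest.mark.parametrize("dS,dH", [(-142.0, -60.0), (-130.0, -56.0),
                                       (-108.0, -49.0)])
    def test_round_trip_with_gibbs_helmholtz(self, dS, dH):
        T = np.linspace(278.15, 318.15, 5)
        e = [cc.gibbs_helmholtz_potential(dS, dH, t) for t in T]
        thermo = cc.reduction_thermodynamics(T, e)
        assert thermo.dS_rc == pytest.approx(dS, rel=1e-3)
        assert thermo.dH_rc == pytest.approx(dH, rel=1e-3)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            cc.reduction_thermodynamics([298.0, 308.0], [184.0, 170.0])

    def test_constructed_identity_point(self):
        # (dS=0, dH=-9.6485 kJ/mol) at 100 K -> exactly 100 mV
        assert cc.gibbs_helmholtz_potential(0.0, -9.6485, 100.0) == pytest.approx(100.0)


class TestTrumpet:
    def test_wt_rate_constant_recovered_within_five_percent(self):
        rates = np.array([1, 2, 5, 10, 20, 50, 100, 200, 500.0])
        rng = np.random.default_rng(10)
        epa, epc = [], []
        for v in rates:
            a, c = _model_peaks(184.0, 1300.0, 0.5, v, 298.15)
            epa.append(a + rng.normal(0, 2.0))
            epc.append(c + rng.normal(0, 2.0))
        kin = cc.fit_trumpet(rates, epa, epc, T=298.15)
        assert kin.ks == pytest.approx(1300.0, rel=0.05)

    def test_symmetric_branches_recover_half_alpha(self):
        rates = np.array([1, 5, 20, 100, 300, 500.0])
        peaks = [_model_peaks(0.0, 200.0, 0.5, v, 298.15) for v in rates]
        kin = cc.fit_trumpet(rates, [p[0] for p in peaks],
                             [p[1] for p in peaks], T=298.15)
        assert kin.alpha == pytest.approx(0.5, abs=0.02)

    def test_grid_oracle_brackets_optimum(self):
        rates = np.array([1, 5, 20, 100, 300, 500.0])
        peaks = [_model_peaks(0.0, 200.0, 0.5, v, 298.15) for v in rates]
        epa = np.array([p[0] for p in peaks])
        epc = np.array([p[1] for p in peaks])
        kin = cc.fit_trumpet(rates, epa, epc, T=298.15)

        def cost(ks, alpha):
            r = []
            for v, a, c in zip(rates, epa, epc):
                pa, pc = _model_peaks(kin.e0_mV, ks, alpha, v, 298.15)
                r += [pa - a, pc - c]
            return float(np.sum(np.square(r)))

        grid = min(cost(ks, al) for ks in np.geomspace(50, 1000, 7)
                   for al in [0.35, 0.5, 0.65])
        assert cost(kin.ks, kin.alpha) <= grid + 1e-9

    def test_all_reversible_flags_lower_bound(self):
        rates = np.array([0.01, 0.02, 0.05, 0.1, 0.2, 0.5])
        peaks = [_model_peaks(0.0, 5000.0, 0.5, v, 298.15) for v in rates]
        kin = cc.fit_trumpet(rates, [p[0] for p in peaks],
                             [p[1] for p in peaks], T=298.15)
        assert "ks_lower_bound_only" in kin.flags


class TestArrhenius:
    def test_two_exact_points_recovered_exactly(self):
        T = np.array([288.15, 308.15])
        ks = [cc.predict_arrhenius(3.1e5, 13.6, t) for t in T]
        with pytest.warns(UserWarning, match="2 points"):
            kin = cc.fit_arrhenius(T, ks)
        assert kin.A == pytest.approx(3.1e5, rel=1e-9)
        assert kin.dH_act == pytest.approx(13.6, rel=1e-9)

    def test_wt_parameters_recovered_from_five_temperatures(self):
        T = np.linspace(278.15, 318.15, 5)
        ks = [cc.predict_arrhenius(3.1e5, 13.6, t) for t in T]
        kin = cc.fit_arrhenius(T, ks)
        assert kin.A == pytest.approx(3.1e5, rel=0.01)
        assert kin.dH_act == pytest.approx(13.6, rel=0.01)

    def test_round_trip_identity(self):
        T = np.linspace(280.0, 320.0, 4)
        ks = [cc.predict_arrhenius(1e6, 20.0, t) for t in T]
        kin = cc.fit_arrhenius(T, ks)
        back = [cc.predict_arrhenius(kin.A, kin.dH_act, t) for t in T]
        np.testing.assert_allclose(back, ks, rtol=1e-9)

    def test_nonpositive_ks_rejected(self):
        with pytest.raises(ValueError):
            cc.fit_arrhenius([280.0, 300.0, 320.0], [1.0, -2.0, 3.0])

    @pytest.mark.parametrize("A,dH,computed,printed", [
        (3.1e5, 13.6, 1.28e3, 1300.0), (9.7e5, 15.8, 1.65e3, 1600.0),
    ])
    def test_predicted_ks_consistent_with_printed_values(self, A, dH,
                                                         computed, printed):
        ks = cc.predict_arrhenius(A, dH)
        assert ks == pytest.approx(computed, rel=0.01)
        assert ks == pytest.approx(printed, rel=0.04)


class TestFullPipelineRoundTrip:
    def test_generated_wt_set_recovers_all_five_quantities(self):
        """End-to-end: synthetic variable-temperature CV set with the WT
        ground-truth parameters -> E1/2, reduction entropy/enthalpy, ks and
        activation enthalpy all recovered within realistic uncertainty."""
        rates = [1, 2, 5, 10, 20, 50, 100, 200, 500.0]
        temps = [278.15, 288.15, 298.15, 308.15, 318.15]
        cvset = cc.gen_voltammogram_set(184.0, -142.0, 3.1e5, 13.6, 0.5,
                                        rates, temps,
                                        noise=cc.NoiseSpec(0.005, 7),
                                        step_mV=0.2)
        e_half, ks_T = [], []
        for T in temps:
            peaks = {v: cc.extract_peaks(cvset.at(T, v)) for v in rates}
            e_half.append(cc.midpoint_potential(*peaks[rates[0]],
                                                reference="NHE"))
            kin = cc.fit_trumpet(rates, [peaks[v][0] for v in rates],
                                 [peaks[v][1] for v in rates], T=T)
            ks_T.append(kin.ks)
        thermo = cc.reduction_thermodynamics(temps, e_half)
        arr = cc.fit_arrhenius(temps, ks_T)
        assert e_half[2] == pytest.approx(184.0, abs=5.0)
        assert thermo.dS_rc == pytest.approx(-142.0, abs=8.0)
        assert thermo.dH_rc == pytest.approx(-60.0, abs=6.0)
        assert ks_T[2] == pytest.approx(1300.0, abs=50.0)
        assert arr.dH_act == pytest.approx(13.6, abs=0.5)
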