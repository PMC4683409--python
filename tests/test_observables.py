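"""Observable mappings: currents, streaming potentials, conductance fits."""

import numpy as np
import pytest

from kirflux import (Condition, ConductanceCurve, PhysicalConstants,
                     chord_conductance, conductance_curve,
                     cycle_contribution_surface, fit_michaelis_menten,
                     iv_curve, predict_current, predict_vstream, slope_to_cr)

CONSTS = PhysicalConstants()

# printed slope (mV per Osm/kg) -> reported coupling ratio
SLOPE_CR_PAIRS = [(-0.63, 1.39), (-0.83, 1.84), (-0.82, 1.80),
                  (-1.08, 2.37), (-0.98, 2.15), (-1.35, 2.98)]


class TestPredictCurrent:
    def test_zero_at_equilibrium(self, diagram, wt_params):
        i = predict_current(diagram, wt_params, Condition.symmetric(0.0, 150.0))
        i_ref = predict_current(diagram, wt_params,
                                Condition.symmetric(-100.0, 150.0))
        assert abs(i) < 1e-9 * abs(i_ref)

    def test_inward_current_negative(self, diagram, wt_params):
        i = predict_current(diagram, wt_params,
                            Condition.symmetric(-100.0, 150.0))
        assert i < 0

    def test_chord_conductance_positive_symmetric(self, diagram, wt_params):
        for v in (-100.0, -40.0, 40.0, 100.0):
            assert chord_conductance(diagram, wt_params, 150.0, v) > 0

    def test_chord_conductance_undefined_at_reversal(self, diagram, wt_params):
        with pytest.raises(ValueError):
            chord_conductance(diagram, wt_params, 150.0, 0.0)


class TestStreamingPotential:
    def test_zero_gradient_gives_zero(self):
        assert predict_vstream(1.39, 0.0) == 0.0

    def test_unit_coupling_magnitude(self):
        # CR = 1, 1 Osm/kg at 295 K: v_w R T / F = 0.4593 mV, negative sign
        assert predict_vstream(1.0, 1.0) == pytest.approx(-0.4593, abs=5e-4)

    def test_low_k_example_magnitude(self):
        # CR 2.15 at a 1.5 Osm/kg pulse, comparable to the measured
        # -1.57 +/- 0.26 mV shift at 15 mM
        v = predict_vstream(2.15, 1.5)
        assert v == pytest.approx(-1.48, abs=0.01)
        assert abs(v - (-1.57)) < 0.26

    @pytest.mark.parametrize("slope, cr", SLOPE_CR_PAIRS)
    def test_slope_conversions_match_reported_ratios(self, slope, cr):
        assert slope_to_cr(slope) == pytest.approx(cr, rel=0.03)

    def test_zero_slope_gives_zero_cr(self):
        assert slope_to_cr(0.0) == 0.0

    def test_vstream_and_slope_are_exact_inverses(self):
        for cr in (0.5, 1.0, 1.39, 2.98):
            slope = predict_vstream(cr, 1.0)
            assert slope_to_cr(slope) == pytest.approx(cr, rel=1e-12)


class TestCycleContributions:
    def test_contributions_sum_to_one(self, diagram, wt_params):
        df = cycle_contribution_surface(diagram, wt_params,
                                        voltages_mV=[-100.0, 50.0],
                                        K_mM_list=[15.0, 150.0])
        sums = df.groupby(["V_mV", "K_mM"])["contribution"].sum()
        assert np.allclose(sums, 1.0, atol=1e-9)

    def test_cycle_conductances_sum_to_total(self, diagram, wt_params):
        df = cycle_contribution_surface(diagram, wt_params,
                                        voltages_mV=[-100.0],
                                        K_mM_list=[150.0])
        total = chord_conductance(diagram, wt_params, 150.0, -100.0)
        assert df["conductance_pS"].sum() == pytest.approx(total, rel=1e-8)

    def test_wild_type_mode_switch_with_depolarisation(self, diagram,
                                                       wt_params):
        """With depolarisation the two-ion cycle a loses weight and the
        one-ion cycle c gains weight at 150 mM."""
        df = cycle_contribution_surface(diagram, wt_params,
                                        voltages_mV=[-100.0, 100.0],
                                        K_mM_list=[150.0])
        piv = df.pivot_table(index="cycle_id", columns="V_mV",
                             values="contribution")
        assert piv.loc["a", 100.0] < piv.loc["a", -100.0]
        assert piv.loc["c", 100.0] > piv.loc["c", -100.0]

    def test_low_k_dominated_by_high_ccr_cycles(self, diagram, wt_params):
        """At low [K+] the cycles with ccr 2 and 3 carry most of the flux."""
        df = cycle_contribution_surface(diagram, wt_params,
                                        voltages_mV=[-1.0],
                                        K_mM_list=[15.0, 300.0])
        high = df[df.ccr >= 2].groupby("K_mM")["contribution"].sum()
        assert high[15.0] > high[300.0]
        assert high[15.0] > 0.5


class TestMichaelisMenten:
    def test_recovers_exact_parameters_from_noiseless_data(self):
        k = np.array([2.0, 5.0, 10.0, 25.0, 50.0, 150.0, 300.0])
        g = 30.0 * k / (k + 12.0)
        curve = ConductanceCurve(points=list(zip(k, g)), V_mV=-100.0)
        gmax, km = fit_michaelis_menten(curve)
        assert gmax == pytest.approx(30.0, rel=1e-6)
        assert km == pytest.approx(12.0, rel=1e-6)

    def test_half_maximum_at_km(self):
        gmax, km = 30.0, 12.0
        g_at_km = gmax * km / (km + km)
        assert g_at_km == pytest.approx(gmax / 2)

    def test_requires_three_points(self):
        curve = ConductanceCurve(points=[(10.0, 5.0), (100.0, 20.0)], V_mV=-100)
        with pytest.raises(ValueError):
            fit_michaelis_menten(curve)

    def test_anchored_fit_passes_through_top_point(self):
        k = np.array([5.0, 15.0, 50.0, 150.0, 300.0])
        g = 28.0 * k / (k + 9.0)
        curve = ConductanceCurve(points=list(zip(k, g)), V_mV=-100.0)
        gmax, km = fit_michaelis_menten(curve, anchor_gmax=True)
        assert gmax * 300.0 / (300.0 + km) == pytest.approx(g[-1], rel=1e-9)

    def test_model_conductance_curve_deviates_from_mm(self, diagram,
                                                      wt_params):
        """The model's conductance-[K+] relation has two phases that a
        single Michaelis-Menten component cannot capture."""
        k_list = [2.0, 5.0, 10.0, 15.0, 25.0, 50.0, 100.0, 150.0, 300.0]
        curve = conductance_curve(diagram, wt_params, k_list, V_mV=-100.0)
        gmax, km = fit_michaelis_menten(curve)
        g = np.array([p[1] for p in curve.points])
        pred = gmax * np.array(k_list) / (np.array(k_list) + km)
        rel_resid = np.abs(pred - g) / g.max()
        assert rel_resid.max() > 0.02  # systematic misfit, not noise


class TestIVCurveShapes:
    def test_wild_type_near_linear_at_high_k(self, diagram, wt_params):
        curve = iv_curve(diagram, wt_params, 300.0, range(-100, 101, 20))
        v, i = curve.as_arrays()
        rect = i[-1] / abs(i[0])  # i(+100)/|i(-100)|
        assert 0.8 < rect < 1.2

    def test_mutant_inwardly_rectifying_at_all_k(self, diagram, mut_params):
        for k in (15.0, 50.0, 150.0, 300.0):
            curve = iv_curve(diagram, mut_params, k, [-100, 100])
            v, i = curve.as_arrays()
            assert i[1] / abs(i[0]) < 0.65

    def test_mutant_current_smaller_than_wild_type(self, diagram, wt_params,
                                                   mut_params):
        for v in (-100.0, -60.0, 60.0, 100.0):
            cond = Condition.symmetric(v, 150.0)
            i_wt = predict_current(diagram, wt_params, cond)
            i_mut = predict_current(diagram, mut_params, cond)
            assert abs(i_mut) < abs(i_wt)
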