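"""Unit and property tests of the intracellular signalling model."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from quorumfate.signaling import (CellInputs, CellState, RegulatoryCurve,
                                  SignalingParams, derivatives, integrate_step,
                                  regulatory, wnt_signal, STATE_NAMES,
                                  load_params, save_params, PACKED_SIZE)

from conftest import up_curve, down_curve


class TestRegulatoryCurve:
    @pytest.mark.parametrize("hill", [1.0, 2.0, 4.0, 6.0, 3.5])
    def test_anchor_points(self, hill):
        """Up curves vanish at zero and halve at half_sat; down curves mirror."""
        up = up_curve(vmax=3.0, half_sat=2.0, hill=hill)
        down = down_curve(vmax=3.0, half_sat=2.0, hill=hill)
        assert up(0.0) == 0.0
        assert down(0.0) == 3.0
        assert up(2.0) == pytest.approx(1.5)
        assert down(2.0) == pytest.approx(1.5)

    def test_monotonicity_by_finite_differences(self):
        """Sign of successive differences matches the curve kind on a dense grid."""
        x = np.linspace(0.0, 20.0, 100)
        for curve, sign in [(up_curve(2.0, 3.0), 1), (down_curve(2.0, 3.0), -1)]:
            diffs = np.diff(curve(x))
            assert np.all(sign * diffs > 0)

    def test_asymptotes(self):
        assert up_curve(vmax=5.0)(1e9) == pytest.approx(5.0)
        assert down_curve(vmax=5.0)(1e9) == pytest.approx(0.0, abs=1e-8)

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            regulatory(-0.1, up_curve())

    @pytest.mark.parametrize("kwargs", [
        {"kind": "sideways"}, {"vmax": 0.0}, {"half_sat": -1.0}, {"hill": 0.5},
    ])
    def test_invalid_construction(self, kwargs):
        base = {"kind": "up", "vmax": 1.0, "half_sat": 1.0, "hill": 2.0}
        with pytest.raises(ValueError):
            RegulatoryCurve(**{**base, **kwargs})


class TestWntSignal:
    def test_no_ligand_no_signal(self, params):
        assert wnt_signal(0.0, 0.0, params) == 0.0

    def test_no_inhibitor_gives_bare_signal(self, params):
        assert wnt_signal(1.5, 0.0, params) == pytest.approx(
            params.wnt_signal_curve(1.5))

    def test_saturating_inhibition(self, params):
        assert wnt_signal(1.5, 1e9, params) == pytest.approx(0.0, abs=1e-9)

    def test_monotone_in_both_arguments(self, params):
        dkk = np.linspace(0, 50, 25)
        w = np.array([wnt_signal(1.0, d, params) for d in dkk])
        assert np.all(np.diff(w) <= 0)
        wnt = np.linspace(0, 10, 25)
        w2 = np.array([wnt_signal(x, 5.0, params) for x in wnt])
        assert np.all(np.diff(w2) >= 0)


class TestDerivatives:
    def test_zero_state_structure(self, params, quiet_inputs):
        """With everything at zero only constitutive Notch synthesis acts."""
        d = derivatives(CellState(), quiet_inputs, params)
        named = dict(zip(STATE_NAMES, d))
        assert named["dkk_produced"] == 0.0
        assert named["pf"] == 0.0
        assert named["hes"] == 0.0
        assert named["notch"] == params.notch_synth > 0

    def test_linear_species_steady_states_are_roots(self, params, active_inputs):
        """dX/dt vanishes exactly at the closed-form synthesis/degradation ratio."""
        lef = 1.3
        state = CellState(
            dkk_produced=params.dkk_synth_curve(lef) / params.dkk_deg,
            lef_tcf=lef,
            ecad_total=params.ecad_synth_curve(lef) / params.ecad_deg,
            pf=params.pf_synth_curve(lef) / params.pf_deg,
            notch=params.notch_synth / params.notch_deg_curve(lef),
        )
        d = dict(zip(STATE_NAMES, derivatives(state, active_inputs, params)))
        for name in ("dkk_produced", "ecad_total", "pf", "notch"):
            assert d[name] == pytest.approx(0.0, abs=1e-12)

    def test_activated_notch_is_dsl_limited(self, params):
        """HES synthesis saturates in Notch once DSL becomes limiting."""
        lo = CellInputs(wnt_ext=1.0, dkk_ext=0.0, bound_ecad=0.0, dsl_sum=1.0)
        d1 = derivatives(CellState(notch=5.0), lo, params)
        d2 = derivatives(CellState(notch=50.0), lo, params)
        assert d1[5] == d2[5]  # dH/dt identical: activation capped by dsl_sum


class TestIntegrateStep:
    def test_invalid_dt(self, params, quiet_inputs):
        with pytest.raises(ValueError):
            integrate_step(CellState(), quiet_inputs, params, 0.0)

    def test_steady_state_is_fixed_point(self, params, active_inputs):
        """A cell relaxed to steady state does not move."""
        cell = CellState(lef_tcf=1.0)
        for _ in range(8000):
            cell = integrate_step(cell, active_inputs, params, 0.1)
        before = cell.as_array()
        after = integrate_step(cell, active_inputs, params, 0.1).as_array()
        # slowest mode (Notch at low degradation) is still relaxing at the
        # ppm level after 800 h; everything else is parked
        np.testing.assert_allclose(after, before, rtol=1e-5)

    def test_pure_decay_matches_exponential(self, params, quiet_inputs):
        """With zero LEF/TCF the proliferation factor decays as P0*exp(-dP*t)."""
        cell = CellState(pf=4.0)
        t, dt = 0.0, 0.01
        while t < 10.0 - 1e-12:
            cell = integrate_step(cell, quiet_inputs, params, dt)
            t += dt
        expected = 4.0 * np.exp(-params.pf_deg * 10.0)
        assert cell.pf == pytest.approx(expected, rel=1e-6)

    def test_step_halving_convergence(self, params, active_inputs):
        """Richardson-style check: halving dt barely moves the 24 h endpoint."""
        def endpoint(dt):
            cell = CellState(lef_tcf=2.0, notch=5.0, hes=3.0)
            for _ in range(int(round(24.0 / dt))):
                cell = integrate_step(cell, active_inputs, params, dt)
            return cell.as_array()
        coarse, fine = endpoint(0.2), endpoint(0.1)
        scale = np.maximum(np.abs(fine), 1e-3)
        assert np.max(np.abs(coarse - fine) / scale) < 1e-4

    def test_steady_state_oracle_all_species(self, params):
        """Frozen inputs: every linear species lands within 1% of its
        synthesis/degradation ratio after 20 relaxation half-lives."""
        inputs = CellInputs(wnt_ext=1.0, dkk_ext=2.0, bound_ecad=3.0, dsl_sum=2.4)
        cell = CellState()
        horizon = 20 * np.log(2) / min(params.dkk_deg, params.ecad_deg,
                                       params.pf_deg, params.hes_deg,
                                       params.df_deg)
        for _ in range(int(round(horizon / 0.1))):
            cell = integrate_step(cell, inputs, params, 0.1)
        lef = cell.lef_tcf
        w = wnt_signal(inputs.wnt_ext, inputs.dkk_ext, params)
        assert lef == pytest.approx(
            w * params.lef_ecad_curve(inputs.bound_ecad) / params.lef_deg, rel=0.01)
        assert cell.pf == pytest.approx(
            params.pf_synth_curve(lef) / params.pf_deg, rel=0.01)
        assert cell.notch == pytest.approx(
            params.notch_synth / params.notch_deg_curve(lef), rel=0.01)
        n_act = min(cell.notch, inputs.dsl_sum)
        hes = params.hes_synth_curve(n_act) / params.hes_deg
        assert cell.hes == pytest.approx(hes, rel=0.01)
        assert cell.df == pytest.approx(
            params.df_synth_curve(hes) / params.df_deg, rel=0.01)

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(
        levels=st.lists(st.floats(0, 50), min_size=7, max_size=7),
        wnt=st.floats(0, 10), dkk=st.floats(0, 50),
        bound=st.floats(0, 30), dsl=st.floats(0, 10),
    )
    def test_positivity_preserved(self, params, levels, wnt, dkk, bound, dsl):
        """All levels stay non-negative from any non-negative start."""
        cell = CellState(*levels)
        inputs = CellInputs(wnt_ext=wnt, dkk_ext=dkk, bound_ecad=bound, dsl_sum=dsl)
        for _ in range(50):
            cell = integrate_step(cell, inputs, params, 0.1)
            assert np.all(cell.as_array() >= 0.0)

    def test_quasi_steady_monotone_in_dkk(self, params):
        """More extracellular Dkk1 never raises steady LEF/TCF or PF."""
        def quasi_steady(dkk):
            inputs = CellInputs(wnt_ext=1.0, dkk_ext=dkk, bound_ecad=2.0, dsl_sum=2.4)
            cell = CellState()
            for _ in range(2000):
                cell = integrate_step(cell, inputs, params, 0.1)
            return cell
        cells = [quasi_steady(d) for d in (0.0, 5.0, 10.0, 20.0, 40.0)]
        lef = [c.lef_tcf for c in cells]
        pf = [c.pf for c in cells]
        assert np.all(np.diff(lef) <= 1e-12)
        assert np.all(np.diff(pf) <= 1e-12)


class TestParamsIO:
    def test_roundtrip(self, params, tmp_path):
        path = tmp_path / "p.yaml"
        save_params(params, path)
        again = load_params(path)
        np.testing.assert_array_equal(again.pack(), params.pack())

    def test_pack_layout(self, params):
        pk = params.pack()
        assert pk.shape == (PACKED_SIZE,)
        assert pk[-7:] == pytest.approx(params.initial_state.as_array())

    def test_validation(self, params):
        with pytest.raises(ValueError):
            dataclasses.replace(params, lef_deg=-1.0)
        with pytest.raises(ValueError):
            dataclasses.replace(params, ecad_binding_coeff=1.5)
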