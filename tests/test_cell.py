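"""Myocyte model: parameter construction, integration sanity, APD logic."""

import numpy as np
import pytest
from dataclasses import replace

from ventric import cell
from ventric.cell import (CellParameterSet, GATE_INDICES, NS, apd,
                          ionic_rhs, initial_state, make_cell_parameters,
                          pace, pace_to_limit_cycle)
from ventric.errors import AnalysisError, ConfigurationError, ConvergenceError


class TestParameters:
    def test_male_is_identity_scaling(self):
        p = make_cell_parameters("endo", "male", 0.0)
        no_sex = make_cell_parameters("endo", "male", 0.0,
                                      sex_factors={"male": {}, "female": {}})
        assert p == no_sex
        baseline = make_cell_parameters("endo", "male", 0.0, preset="baseline")
        assert np.allclose(baseline.multipliers()[:13], 1.0)

    def test_female_downregulates_repolarizing_currents(self):
        m = make_cell_parameters("epi", "male", 0.0)
        f = make_cell_parameters("epi", "female", 0.0)
        assert f.g_Kr < m.g_Kr
        assert f.g_Ks < m.g_Ks
        assert f.g_K1 < m.g_K1
        assert f.g_to < m.g_to
        assert f.g_NaCa > m.g_NaCa

    def test_apicobasal_gradient_only_scales_iks(self):
        apex = make_cell_parameters("mid", "male", 0.0)
        base = make_cell_parameters("mid", "male", 1.0)
        assert apex.multipliers()[5] > base.multipliers()[5]  # gKs row
        for name in ("g_Na", "g_to", "P_Ca", "g_Kr", "g_K1"):
            assert getattr(apex, name) == getattr(base, name)

    @pytest.mark.parametrize("kwargs", [
        {"cell_type": "purkinje"}, {"sex": "unknown"},
        {"apicobasal_position": 1.5}, {"preset": "nope"},
    ])
    def test_invalid_configuration_rejected(self, kwargs):
        args = {"cell_type": "endo", "sex": "male", "apicobasal_position": 0.0}
        args.update(kwargs)
        with pytest.raises(ConfigurationError):
            make_cell_parameters(args["cell_type"], args["sex"],
                                 args["apicobasal_position"],
                                 preset=args.get("preset", "dutta"))

    def test_negative_conductance_rejected(self):
        with pytest.raises(ConfigurationError):
            CellParameterSet(g_Kr=-0.1)


class TestDynamics:
    def test_rhs_finite_and_flags_bad_state(self):
        p = make_cell_parameters("endo", "male", 0.0)
        y = initial_state(1)[:, 0]
        dy = ionic_rhs(y, p)
        assert dy.shape == (NS,)
        assert np.all(np.isfinite(dy))
        y_bad = y.copy()
        y_bad[3] = np.nan
        with pytest.raises(Exception) as exc:
            ionic_rhs(y_bad, p)
        assert "ki" in str(exc.value)

    def test_resting_state_is_stable(self):
        p = replace(make_cell_parameters("endo", "male", 0.0),
                    stim_amplitude=0.0)
        t, v, _, _ = pace(p, 1, 1000.0)
        assert abs(v[-1] - v[0]) < 1.0

    def test_action_potential_morphology_and_state_bounds(self):
        p = make_cell_parameters("endo", "male", 0.0)
        t, v, cai, state = pace(p, 1, 1000.0)
        assert v.max() > 20.0
        assert abs(v[-1] + 88.0) < 3.0  # end-diastolic (resting) potential
        assert np.all(cai > 0)
        gates = state[GATE_INDICES]
        assert np.all(gates >= 0.0) and np.all(gates <= 1.0)
        assert np.all(state[1:9] > 0)  # concentrations


class TestApd:
    def test_square_pulse(self):
        t = np.arange(0.0, 400.0, 1.0)
        v = np.full(t.size, -85.0)
        v[1:200] = 15.0
        v[200] = -75.0  # exactly the 90% recovery level
        assert apd(t, v, 0.9) == pytest.approx(200.0)

    def test_fraction_zero_is_definition_limit(self):
        t = np.arange(0.0, 300.0, 1.0)
        v = np.full(t.size, -85.0)
        v[1:100] = 20.0
        assert apd(t, v, 0.0) == 0.0

    def test_no_upstroke_raises(self):
        t = np.arange(0.0, 100.0, 1.0)
        with pytest.raises(AnalysisError):
            apd(t, np.full(t.size, -85.0))


class TestLimitCycle:
    def test_infinite_tolerance_returns_after_one_beat(self):
        p = make_cell_parameters("endo", "male", 0.0)
        _, n_beats, _ = pace_to_limit_cycle(p, 600.0, tol_mmol=np.inf,
                                            max_beats=3)
        assert n_beats == 1

    def test_nonconvergence_carries_history(self):
        p = make_cell_parameters("endo", "male", 0.0)
        with pytest.raises(ConvergenceError) as exc:
            pace_to_limit_cycle(p, 600.0, tol_mmol=1e-12, max_beats=3)
        assert len(exc.value.history) == 2

    def test_limit_cycle_is_a_fixed_point(self, limit_cycle_endo):
        params, state, n_beats, history = limit_cycle_endo
        assert history[-1] < 1e-7
        # one more paced beat stays within tolerance of the previous cycle
        t, v, cai1, s1 = pace(params, 1, 600.0, sample_ms=1.0, state=state)
        t, v, cai2, s2 = pace(params, 1, 600.0, sample_ms=1.0, state=s1)
        rmse = float(np.sqrt(np.mean((cai2 - cai1) ** 2)))
        assert rmse < 1e-7

    def test_rmse_history_decreases(self, limit_cycle_endo):
        *_, history = limit_cycle_endo
        h = np.asarray(history)
        # eventually monotone: the last stretch decreases beat over beat
        tail = h[-10:]
        assert np.all(np.diff(tail) < 0) or tail[-1] < 2e-7
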