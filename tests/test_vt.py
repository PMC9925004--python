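"""Programmed stimulation: event detection, classification, tallies."""

import numpy as np
import pytest

from ventric import monodomain as md, vt
from ventric.anatomy import StimulusSite, make_cable, make_slab
from ventric.errors import ConfigurationError
from ventric.fibers import uniform_fibers


def _result(mesh, crossing_times, crossing_nodes, stim_end=400.0):
    n = mesh.n_nodes
    return md.SimulationResult(
        t_snap=np.arange(2.0), v_snap=np.zeros((2, n), dtype=np.float32),
        lat=np.full(n, np.nan), rt90=np.full(n, np.nan),
        crossing_times=np.asarray(crossing_times, dtype=float),
        crossing_nodes=np.asarray(crossing_nodes, dtype=int),
        stimulus_log=[{"label": "S2", "onset_ms": stim_end - 3.0,
                       "duration_ms": 3.0, "amplitude": -80.0, "n_nodes": 4}],
        config={}, excitable_mask=np.ones(n, dtype=bool))


def _full_reactivations(mesh, beat_times):
    """Crossing log in which every node re-activates at each beat."""
    n = mesh.n_nodes
    ct, cn = [], []
    for b in beat_times:
        ct.append(np.full(n, b) + 0.01 * np.arange(n))
        cn.append(np.arange(n))
    return np.concatenate(ct), np.concatenate(cn)


class TestDetection:
    def setup_method(self):
        self.mesh = make_slab(0.4, 0.4, 0.1, 0.1)

    def test_extinguished_activity_gives_no_events(self):
        res = _result(self.mesh, [390.0, 395.0], [0, 1])
        assert vt.detect_reentry(res) == []

    @pytest.mark.parametrize("n_beats,kind", [
        (2, "nonsustained_reentry"), (3, "sustained_VT"), (5, "sustained_VT"),
    ])
    def test_sustained_classification_rule(self, n_beats, kind):
        beats = [600.0 + 210.0 * k for k in range(n_beats)]
        ct, cn = _full_reactivations(self.mesh, beats)
        res = _result(self.mesh, ct, cn)
        events = vt.detect_reentry(res, (250.0,), "site")
        assert len(events) == 1
        ev = events[0]
        assert ev.kind == kind
        assert ev.n_reactivations == n_beats
        assert np.allclose(ev.cycle_lengths_ms, 210.0, atol=5.0)

    def test_partial_reactivations_are_wavelets_not_events(self):
        n = self.mesh.n_nodes
        few = np.arange(max(2, int(0.1 * n)))
        ct = np.concatenate([np.full(few.size, 600.0 + 200.0 * k)
                             for k in range(4)])
        cn = np.concatenate([few] * 4)
        res = _result(self.mesh, ct, cn)
        assert vt.detect_reentry(res) == []

    def test_sustained_event_requires_three(self):
        with pytest.raises(ConfigurationError):
            vt.ArrhythmiaEvent("sustained_VT", 2, [], [], (), "x")


class TestTally:
    @pytest.mark.parametrize("e,s,pct", [(4, 29, 14), (2, 33, 6), (0, 10, 0)])
    def test_event_percentage(self, e, s, pct):
        assert vt.event_percentage(e, s) == pct

    def test_tally_table(self):
        t_ev = vt.Trial((300.0,), (True,), ["ev"], "RV_apex")
        t_no = vt.Trial((280.0,), (True,), [], "RV_apex")
        table = vt.tally_events({("detailed", "male", "RV_apex"): [t_ev, t_no, t_no]})
        row = table.iloc[0]
        assert row.events == 1 and row.simulations == 3 and row.pct == 33

    def test_reference_event_percentages(self):
        from ventric.workbench import reference_aggregates
        agg = reference_aggregates()
        assert agg["event_pct"]["smoothed_male"] == 14
        assert agg["event_pct"]["detailed_female"] == 6


class TestRefractoriness:
    def test_sub_erp_extrastimulus_fails_to_capture(self):
        mesh = make_cable(2.0, 0.05)
        fib = uniform_fibers(mesh)
        prob = md.MonodomainProblem(mesh, fib, md.DiffusionSpec(),
                                    init_beats=3, dt_ms=0.02)
        end = np.flatnonzero(mesh.nodes[:, 0] <= 0.08)
        stims = [StimulusSite("S1", end, 0.0, -80.0, 2.0),
                 StimulusSite("S2", end, 120.0, -80.0, 2.0)]
        res = prob.run(stims, 190.0, analysis_start_ms=0.0)
        captured = res.activated_fraction((120.0, 190.0))
        assert captured < 0.3


class TestRingSubstrate:
    def test_induced_sustained_vt(self, ring_runs):
        events = ring_runs["induced"]["events"]
        assert len(events) == 1
        ev = events[0]
        assert ev.kind == "sustained_VT"
        assert ev.n_reactivations >= 3
        assert all(100.0 < c < 300.0 for c in ev.cycle_lengths_ms)

    def test_no_reentry_without_closed_circuit(self, ring_runs):
        assert ring_runs["control"]["events"] == []

    def test_reentry_sites_on_the_loop(self, ring_runs):
        run = ring_runs["induced"]
        sites = vt.locate_reentry_sites(run["result"], run["mesh"],
                                        run["events"])
        assert len(sites) >= 3
        r_mid = run["mesh"].metadata["r_mid"]
        L = run["mesh"].metadata["L"]
        for s in sites:
            r = np.hypot(s["centroid"][0] - L / 2, s["centroid"][1] - L / 2)
            assert abs(r - r_mid) < 0.5
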