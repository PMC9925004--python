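"""Pseudo-ECG: electrode placement, forward integral, lead algebra."""

import numpy as np
import pytest

from ventric import fibers as fb, monodomain as md, pseudo_ecg as pe
from ventric.anatomy import make_slab
from ventric.errors import AnalysisError, ConfigurationError


def _synthetic_result(mesh, v_snap, t=None):
    """Wrap hand-made potential snapshots in a SimulationResult."""
    nt = v_snap.shape[0]
    t = np.arange(nt, dtype=float) if t is None else t
    n = mesh.n_nodes
    return md.SimulationResult(
        t_snap=t, v_snap=v_snap.astype(np.float32),
        lat=np.full(n, np.nan), rt90=np.full(n, np.nan),
        crossing_times=np.empty(0), crossing_nodes=np.empty(0, dtype=int),
        stimulus_log=[], config={}, excitable_mask=np.ones(n, dtype=bool))


@pytest.fixture(scope="module")
def slab_setup():
    mesh = make_slab(1.0, 0.6, 0.3, 0.1)
    fib = fb.uniform_fibers(mesh)
    return mesh, fib, md.DiffusionSpec()


class TestElectrodes:
    def test_defaults_outside_hull_and_pair_identical(self, biv_pair):
        _, det, smo = biv_pair
        ed = pe.electrode_positions(det)
        es = pe.electrode_positions(smo)
        lo, hi = det.nodes.min(axis=0), det.nodes.max(axis=0)
        for name, p in ed.items():
            assert np.any((p < lo) | (p > hi))
            assert np.allclose(p, es[name], atol=0.15)

    def test_absolute_override_echoed(self, slab_setup):
        mesh, *_ = slab_setup
        pos = pe.electrode_positions(mesh, {"RA": (9, 9, 9), "LA": (-9, 0, 0),
                                            "LL": (0, -9, 0), "absolute": True})
        assert np.allclose(pos["RA"], (9, 9, 9))

    def test_inside_myocardium_rejected(self, slab_setup):
        mesh, *_ = slab_setup
        with pytest.raises(ConfigurationError):
            pe.electrode_positions(mesh, {"RA": (0.5, 0.3, 0.15),
                                          "LA": (-9, 0, 0), "LL": (0, -9, 0),
                                          "absolute": True})


class TestForwardModel:
    def test_uniform_potential_gives_zero_signal(self, slab_setup):
        mesh, fib, spec = slab_setup
        v = np.full((5, mesh.n_nodes), -20.0)
        res = _synthetic_result(mesh, v)
        ecg = pe.compute_pseudo_ecg(res, mesh, fib, spec)
        for lead in ("RA", "LA", "LL"):
            assert np.abs(ecg.lead(lead)).max() < 1e-10

    def test_einthoven_closure_exact(self, slab_setup):
        mesh, fib, spec = slab_setup
        rng = np.random.default_rng(7)
        v = rng.normal(-40, 30, size=(8, mesh.n_nodes))
        ecg = pe.compute_pseudo_ecg(_synthetic_result(mesh, v), mesh, fib, spec)
        closure = np.abs(ecg.lii - ecg.li - ecg.liii).max()
        assert closure <= 1e-9 * np.abs(ecg.lii).max()

    def test_linearity_in_potential_deviations(self, slab_setup):
        mesh, fib, spec = slab_setup
        rng = np.random.default_rng(3)
        rest = -85.0
        dv = rng.normal(0, 25, size=(6, mesh.n_nodes))
        e1 = pe.compute_pseudo_ecg(_synthetic_result(mesh, rest + dv),
                                   mesh, fib, spec)
        e3 = pe.compute_pseudo_ecg(_synthetic_result(mesh, rest + 3.0 * dv),
                                   mesh, fib, spec)
        # exact linearity of the forward operator, verified to the
        # float32 precision of the stored snapshots
        assert np.allclose(e3.lii, 3.0 * e1.lii, rtol=1e-4,
                           atol=1e-6 * np.abs(e1.lii).max())

    def test_far_field_falls_as_inverse_square(self):
        # compact dipolar source: a potential step across a small slab
        mesh = make_slab(0.2, 0.1, 0.1, 0.05)
        fib = fb.uniform_fibers(mesh)
        spec = md.DiffusionSpec()
        v = np.where(mesh.nodes[:, 0] < 0.1, -85.0, 15.0)[None, :]
        res = _synthetic_result(mesh, np.repeat(v, 2, axis=0))
        amps = []
        for d in (6.0, 12.0):
            pos = {"RA": (d, 0.05, 0.05), "LA": (0.05, d, 0.05),
                   "LL": (0.05, 0.05, d), "absolute": True}
            ecg = pe.compute_pseudo_ecg(res, mesh, fib, spec,
                                        pe.electrode_positions(mesh, pos))
            amps.append(abs(ecg.ra[0]))
        assert amps[0] / amps[1] == pytest.approx(4.0, rel=0.1)


class TestRmsd:
    def _trace(self, y):
        t = np.arange(y.size, dtype=float)
        z = np.zeros_like(y)
        return pe.EcgTrace(t, z, y, 2 * y, {})

    def test_identical_traces(self):
        a = self._trace(np.sin(np.linspace(0, 6, 50)))
        out = pe.ecg_rmsd(a, a)
        assert all(v == 0.0 for v in out.values())

    def test_constant_offset_closed_form(self):
        y = np.sin(np.linspace(0, 6, 50))
        a = self._trace(y)
        b = pe.EcgTrace(a.t, a.ra + 1.5, a.la + 1.5, a.ll + 1.5, {})
        out = pe.ecg_rmsd(a, b)
        # uniform electrode offsets cancel in every lead
        assert all(v == pytest.approx(0.0, abs=1e-12) for v in out.values())
        c = pe.EcgTrace(a.t, a.ra, a.la + 2.0, a.ll + 2.0, {})
        out = pe.ecg_rmsd(a, c, leads=("LI", "LII"))
        assert out["LI"] == pytest.approx(2.0)
        assert out["LII"] == pytest.approx(2.0)

    def test_disjoint_windows_rejected(self):
        y = np.zeros(10)
        a = self._trace(y)
        b = pe.EcgTrace(a.t + 100.0, y, y, y, {})
        with pytest.raises(AnalysisError):
            pe.ecg_rmsd(a, b)

    def test_reference_lead_means(self):
        from ventric.workbench import reference_aggregates
        agg = reference_aggregates()
        assert agg["ecg_rmsd_mean_mv"]["i"] == pytest.approx(2.0, abs=0.05)
        assert agg["ecg_rmsd_mean_mv"]["ii"] == pytest.approx(4.9, abs=0.05)
        assert agg["ecg_rmsd_mean_mv"]["iii"] == pytest.approx(4.3, abs=0.05)
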