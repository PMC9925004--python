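"""Monodomain solver: operator structure, stability, causality, regions."""

import numpy as np
import pytest

from ventric import fem, fibers as fb, monodomain as md
from ventric.anatomy import (DENSE_SCAR, FAST_ENDO, FALSE_TENDON, TRABECULA,
                             StimulusSite, insert_scar, make_slab)
from ventric.errors import ConfigurationError


class TestOperators:
    def _slab(self):
        m = make_slab(0.4, 0.3, 0.2, 0.05)
        return m, fb.uniform_fibers(m, (1, 0, 0), (0, 1, 0))

    def test_symmetric_zero_row_sums(self):
        m, f = self._slab()
        K, M = md.assemble_operators(m, f, md.DiffusionSpec())
        assert abs(K - K.T).max() < 1e-12
        assert np.abs(np.asarray(K.sum(axis=1))).max() < 1e-10
        assert np.all(M > 0)
        assert M.sum() == pytest.approx(0.4 * 0.3 * 0.2)

    def test_constant_field_in_null_space(self):
        m, f = self._slab()
        K, _ = md.assemble_operators(m, f, md.DiffusionSpec())
        v = np.full(m.n_nodes, -84.0)
        assert np.abs(K @ v).max() < 1e-9

    def test_isotropic_tensor_equals_scalar_laplacian(self):
        m, f = self._slab()
        d = 2.3e-3
        spec = md.DiffusionSpec({r: (d, d, d) for r in range(6)},
                                md.DiffusionSpec().excitable)
        K, _ = md.assemble_operators(m, f, spec)
        K_ref = fem.assemble_stiffness(m.nodes, m.tets) * d
        assert abs(K - K_ref).max() < 1e-12

    def test_non_orthonormal_triads_rejected(self):
        m, f = self._slab()
        f.s[:] = f.f  # degenerate sheet axis
        with pytest.raises(ConfigurationError):
            md.assemble_operators(m, f, md.DiffusionSpec())

    def test_scar_must_be_non_excitable(self):
        with pytest.raises(ConfigurationError):
            md.DiffusionSpec(excitable={**md.DiffusionSpec().excitable,
                                        DENSE_SCAR: True})


class TestDynamics:
    def test_resting_tissue_is_quiescent(self):
        m = make_slab(0.4, 0.2, 0.1, 0.05)
        f = fb.uniform_fibers(m)
        prob = md.MonodomainProblem(m, f, md.DiffusionSpec(), init_beats=3)
        v0 = prob.v.copy()
        res = prob.run([], 100.0, analysis_start_ms=0.0)
        assert np.abs(prob.v - v0).max() < 0.5
        assert res.crossing_times.size == 0

    def test_cable_activation_is_causal(self, cable_runs):
        mesh = cable_runs["L04"]["mesh"]
        res = cable_runs["L04"]["result"]
        x = mesh.nodes[:, 0]
        # LAT averaged per cross-section strictly increases with distance
        xs = np.unique(np.round(x, 6))
        lat_profile = [res.lat[np.isclose(x, xv)].mean() for xv in xs]
        d = np.diff(lat_profile)
        assert np.all(d[2:-2] > 0)

    def test_full_capture_on_biventricular(self, biv_sinus):
        for name in ("detailed", "smoothed"):
            assert biv_sinus[name]["result"].activated_fraction() > 0.999

    def test_fast_endocardial_layer_accelerates_activation(self):
        # slab with a one-element fast layer on its endocardial face,
        # paced from one corner: the layer carries activation along the
        # surface and shortens the total activation time
        m = make_slab(1.2, 0.6, 0.2, 0.05)
        region = m.region.copy()
        bottom = m.centroids()[:, 2] < 0.05
        region[bottom] = FAST_ENDO
        from dataclasses import replace
        m = replace(m, region=region)
        f = fb.uniform_fibers(m)
        spec = md.DiffusionSpec().with_scaled(3.0)
        site = StimulusSite("edge", np.flatnonzero(
            (m.nodes[:, 0] <= 0.16) & (m.nodes[:, 2] <= 0.051)),
            0.0, -200.0, 3.0)
        tats = {}
        for label, sp in (("fast", spec),
                          ("slow", spec.with_region(FAST_ENDO,
                                                    spec.diffusivities[0]))):
            prob = md.MonodomainProblem(m, f, sp, init_beats=5, dt_ms=0.02)
            res = prob.run([site], 60.0, analysis_start_ms=0.0)
            assert res.activated_fraction() > 0.99
            tats[label] = np.nanmax(res.lat)
        assert tats["slow"] > tats["fast"]

    def test_dense_scar_never_activates(self):
        m = make_slab(1.0, 0.5, 0.05, 0.05)
        m = insert_scar(m, (0.5, 0.25, 0.025), 0.15, 0.0)
        f = fb.uniform_fibers(m)
        spec = md.DiffusionSpec().with_scaled(3.0)
        prob = md.MonodomainProblem(m, f, spec, init_beats=3, dt_ms=0.02)
        site = StimulusSite("edge", np.flatnonzero(m.nodes[:, 0] <= 0.06),
                            0.0, -150.0, 3.0)
        res = prob.run([site], 60.0, analysis_start_ms=0.0)
        scar_only = np.ones(m.n_nodes, dtype=bool)
        exc = np.isin(m.region, list(r for r in range(6)
                                     if spec.excitable.get(r, True)))
        for a in range(4):
            scar_only[m.tets[exc, a]] = False
        assert not np.isin(res.crossing_nodes, np.flatnonzero(scar_only)).any()
        assert res.activated_fraction() > 0.95  # wave went around the core


class TestConductionVelocity:
    def test_cv_refinement_increases_monotonically(self, cable_runs):
        assert cable_runs["L02"]["cv"] > cable_runs["L04"]["cv"]

    def test_transverse_slower_than_longitudinal(self, cable_runs):
        assert cable_runs["T02"]["cv"] < cable_runs["L02"]["cv"]
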