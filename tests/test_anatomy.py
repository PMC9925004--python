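"""Synthetic anatomies: construction contracts, coordinates, labels, sites."""

import numpy as np
import pytest

from ventric import anatomy
from ventric.anatomy import (BORDER_ZONE, DENSE_SCAR, FALSE_TENDON, FAST_ENDO,
                             MYOCARDIUM, TRABECULA, BiventricularConfig,
                             StimulusSite, insert_scar, make_biventricular_pair,
                             make_cable, make_ridge_slab, make_slab, place_iars,
                             place_pacing_site, trabecular_volume_pct)
from ventric.errors import ConfigurationError, GenerationError


class TestBasicMeshes:
    def test_cable_construction(self):
        m = make_cable(2.0, 0.04)
        assert m.n_elements == 50 * 6
        assert m.volumes().min() > 0
        assert np.array_equal(make_cable(2.0, 0.04).nodes, m.nodes)

    def test_cable_preconditions(self):
        with pytest.raises(ConfigurationError):
            make_cable(2.0, -0.1)
        with pytest.raises(ConfigurationError):
            make_cable(0.2, 0.04)

    def test_slab_construction(self):
        m = make_slab(1.0, 0.5, 0.3, 0.05)
        assert m.volumes().min() > 0
        assert m.phi.min() == 0.0 and m.phi.max() == 1.0
        with pytest.raises(ConfigurationError):
            make_slab(1.0, 0.0, 0.3, 0.05)

    def test_boundary_faces_closed_box(self):
        m = make_slab(0.4, 0.2, 0.1, 0.05)
        faces = m.boundary_faces()
        # surface area of the box, each square face split into 2 triangles
        area = 2 * (0.4 * 0.2 + 0.4 * 0.1 + 0.2 * 0.1)
        assert faces.shape[0] == int(round(area / (0.5 * 0.05 ** 2)))


class TestTrabecularVolume:
    @pytest.mark.parametrize("vd,vs,expected", [
        (394.2, 329.8, 16.3), (199.6, 180.5, 9.6),
        (170.6, 155.8, 8.7), (299.2, 268.0, 10.4),
    ])
    def test_reference_pairs(self, vd, vs, expected):
        assert round(trabecular_volume_pct(vd, vs), 1) == expected

    def test_degenerate_and_invalid(self):
        assert trabecular_volume_pct(5.0, 5.0) == 0.0
        with pytest.raises(ConfigurationError):
            trabecular_volume_pct(1.0, 2.0)


class TestBiventricularPair:
    def test_target_fraction_met(self, biv_pair):
        cfg, det, smo = biv_pair
        frac = trabecular_volume_pct(det.total_volume(), smo.total_volume())
        assert abs(frac - 100.0 * cfg.trabecular_fraction_target) <= 2.0

    def test_cohort_fraction_range_achievable(self):
        for target, seed in ((0.087, 3), (0.163, 2)):
            cfg = BiventricularConfig(resolution=0.14,
                                      trabecular_fraction_target=target,
                                      seed=seed)
            det, smo = make_biventricular_pair(cfg)
            frac = trabecular_volume_pct(det.total_volume(), smo.total_volume())
            assert abs(frac - 100.0 * target) <= 2.0

    def test_pair_shares_epicardial_outline(self, biv_pair):
        _, det, smo = biv_pair
        # smoothed nodes are a subset of the shared grid positions
        key = {tuple(np.round(p, 6)) for p in det.nodes}
        shared = sum(tuple(np.round(p, 6)) in key for p in smo.nodes)
        assert shared / smo.n_nodes > 0.95

    def test_regions_and_coordinates(self, biv_pair):
        _, det, smo = biv_pair
        assert (det.region == TRABECULA).sum() > 0
        assert (det.region == FALSE_TENDON).sum() > 0
        assert (smo.region == TRABECULA).sum() == 0
        for m in (det, smo):
            assert m.volumes().min() > 0
            assert 0.0 <= m.phi.min() and m.phi.max() <= 1.0
            assert set(np.unique(m.layer)) <= {0, 1, 2}

    def test_fast_endo_layer_absent_from_base(self, biv_pair):
        _, det, smo = biv_pair
        for m in (det, smo):
            fast = m.region == FAST_ENDO
            assert fast.sum() > 0
            z_el = m.z[m.tets[fast]].mean(axis=1)
            assert z_el.max() < 2.0 / 3.0 + 0.05

    def test_no_false_tendons_on_request(self):
        cfg = BiventricularConfig(resolution=0.15, n_false_tendons=0,
                                  trabecular_fraction_target=0.05, seed=4)
        det, _ = make_biventricular_pair(cfg)
        assert (det.region == FALSE_TENDON).sum() == 0

    def test_unreachable_fraction_raises(self):
        cfg = BiventricularConfig(resolution=0.15, n_trabeculae=1,
                                  n_false_tendons=0,
                                  trabecular_fraction_target=0.25, seed=5)
        with pytest.raises(GenerationError):
            make_biventricular_pair(cfg)


class TestScar:
    def _slab(self):
        return make_slab(1.2, 1.2, 0.1, 0.1)

    def test_zero_radius_is_identity(self):
        m = self._slab()
        assert insert_scar(m, (0.6, 0.6, 0.05), 0.0, 0.1) is m

    def test_labels_disjoint_and_nonempty(self):
        m = insert_scar(self._slab(), (0.6, 0.6, 0.05), 0.3, 0.2, 0.15)
        assert (m.region == DENSE_SCAR).sum() > 0
        assert (m.region == BORDER_ZONE).sum() > 0

    def test_channel_connects_across_the_core(self):
        m = insert_scar(self._slab(), (0.6, 0.6, 0.05), 0.3, 0.2, 0.15,
                        channel_axis=(1, 0, 0))
        import scipy.sparse as sp
        ok = m.region != DENSE_SCAR
        idx = np.flatnonzero(ok)
        adj = m.element_adjacency()[idx][:, idx]
        n, comp = sp.csgraph.connected_components(adj, directed=False)
        assert n == 1  # the corridor keeps the excitable tissue connected

    def test_channel_wider_than_scar_rejected(self):
        with pytest.raises(ConfigurationError):
            insert_scar(self._slab(), (0.6, 0.6, 0.05), 0.2, 0.1, 0.5)


class TestActivationSites:
    def test_five_disjoint_sites(self, biv_pair):
        _, det, _ = biv_pair
        sites = place_iars(det)
        assert [s.label for s in sites] == list(anatomy.IAR_LABELS)
        all_nodes = np.concatenate([s.nodes for s in sites])
        assert all_nodes.size == np.unique(all_nodes).size

    def test_posterior_paraseptal_site_at_one_third(self, biv_pair):
        cfg, det, _ = biv_pair
        sites = place_iars(det)
        height = det.nodes[sites[4].nodes, 2].mean() / cfg.lv_height
        assert abs(height - 1.0 / 3.0) < 0.12

    def test_pair_sites_coincide(self):
        # lightly structured pair: the patch centroids are set by the
        # shared target coordinates, not by structural asymmetry
        cfg = BiventricularConfig(resolution=0.15,
                                  trabecular_fraction_target=0.09, seed=7)
        det, smo = make_biventricular_pair(cfg)
        diameter = np.sqrt(3.0) * cfg.resolution
        for sd, ss in zip(place_iars(det), place_iars(smo)):
            cd = det.nodes[sd.nodes].mean(axis=0)
            cs = smo.nodes[ss.nodes].mean(axis=0)
            assert np.linalg.norm(cd - cs) < diameter

    def test_pacing_sites(self, biv_pair):
        _, det, _ = biv_pair
        for label in anatomy.PACING_LABELS:
            s = place_pacing_site(det, label)
            assert s.nodes.size >= 4
        with pytest.raises(ConfigurationError):
            place_pacing_site(det, "outflow")

    def test_non_biventricular_mesh_rejected(self):
        with pytest.raises(ConfigurationError):
            place_iars(make_slab(1.0, 1.0, 0.2, 0.1))

    def test_empty_site_rejected(self):
        with pytest.raises(ConfigurationError):
            StimulusSite("x", np.array([], dtype=int))


def test_ridge_slab_detectable_trabecula():
    m = make_ridge_slab()
    ridge_nodes = np.unique(m.tets[m.region == TRABECULA])
    assert ridge_nodes.size > 0
    assert m.phi[ridge_nodes].mean() < 0.1
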