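"""Markers: activation statistics, intervals, differences, Welch test."""

import numpy as np
import pandas as pd
import pytest

from ventric import biomarkers as bm, monodomain as md, pseudo_ecg as pe
from ventric.anatomy import make_cable, make_slab
from ventric.errors import AnalysisError
from ventric.workbench import ingest_reference_tables


def _result_with_lat(mesh, lat, t0=0.0):
    n = mesh.n_nodes
    return md.SimulationResult(
        t_snap=np.arange(2.0), v_snap=np.zeros((2, n), dtype=np.float32),
        lat=lat, rt90=np.full(n, np.nan),
        crossing_times=np.empty(0), crossing_nodes=np.empty(0, dtype=int),
        stimulus_log=[], config={"analysis_start_ms": t0},
        excitable_mask=np.ones(n, dtype=bool))


class TestActivationMarkers:
    def test_simultaneous_activation(self):
        mesh = make_slab(0.4, 0.2, 0.1, 0.05)
        res = _result_with_lat(mesh, np.full(mesh.n_nodes, 17.0))
        tat, t10, t90, edi = bm.activation_markers(res, mesh)
        assert (tat, t10, t90, edi) == (17.0, 17.0, 17.0, 0.0)

    def test_uniform_ramp_closed_form(self):
        mesh = make_cable(2.0, 0.05)
        lat = 100.0 * mesh.nodes[:, 0] / 2.0
        res = _result_with_lat(mesh, lat)
        tat, t10, t90, edi = bm.activation_markers(res, mesh)
        assert tat == pytest.approx(100.0)
        assert t10 == pytest.approx(10.0, abs=2.0)
        assert t90 == pytest.approx(90.0, abs=2.0)
        assert edi == pytest.approx(100.0 / np.sqrt(12.0), abs=1.0)

    def test_time_shift_invariance(self):
        mesh = make_cable(2.0, 0.05)
        lat = 100.0 * mesh.nodes[:, 0] / 2.0
        a = bm.activation_markers(_result_with_lat(mesh, lat), mesh)
        b = bm.activation_markers(_result_with_lat(mesh, lat + 55.0, t0=55.0), mesh)
        assert np.allclose(a, b)

    def test_incomplete_activation_flagged(self):
        mesh = make_cable(2.0, 0.05)
        lat = np.full(mesh.n_nodes, 5.0)
        lat[0] = np.nan
        with pytest.raises(AnalysisError):
            bm.activation_markers(_result_with_lat(mesh, lat), mesh)

    def test_cable_transit_time(self, cable_runs):
        mesh = cable_runs["L04"]["mesh"]
        res = cable_runs["L04"]["result"]
        tat, *_ = bm.activation_markers(res, mesh)
        cv_cm_ms = cable_runs["L04"]["cv"] / 1000.0
        assert tat == pytest.approx(2.0 / cv_cm_ms, rel=0.2)


class TestApparentCV:
    def _planar(self, cv_cm_s):
        mesh = make_slab(1.0, 1.0, 0.1, 0.05)
        lat = mesh.nodes[:, 0] / (cv_cm_s / 1000.0)
        return mesh, _result_with_lat(mesh, lat)

    def test_planar_wave_mode(self):
        mesh, res = self._planar(60.0)
        cv = bm.apparent_cv(res, mesh)
        assert abs(cv - 60.0) <= 2.0

    def test_doubling_lat_halves_cv(self):
        mesh, res = self._planar(60.0)
        res2 = _result_with_lat(mesh, 2.0 * res.lat)
        assert bm.apparent_cv(res2, mesh) == pytest.approx(
            bm.apparent_cv(res, mesh) / 2.0, abs=2.0)

    def test_flat_lat_rejected(self):
        mesh = make_slab(1.0, 1.0, 0.1, 0.05)
        res = _result_with_lat(mesh, np.zeros(mesh.n_nodes))
        with pytest.raises(AnalysisError):
            bm.apparent_cv(res, mesh)


def _triphasic_ecg(qrs_end=95.0, t_end=None, dt=1.0, total=450.0):
    """Synthetic beat: triphasic QRS returning to baseline at ``qrs_end``,
    optional T wave returning at ``t_end``."""
    t = np.arange(0.0, total, dt)
    y = np.zeros(t.size)
    up = (t >= 5) & (t < 40)
    y[up] = np.sin((t[up] - 5) / 35 * 2 * np.pi) * 40
    tail = (t >= 40) & (t < qrs_end)
    y[tail] = -5.0
    if t_end is not None:
        tw = (t >= 200) & (t < t_end)
        y[tw] = 12.0  # T wave held clear of the baseline band until t_end
    return pe.EcgTrace(t, np.zeros(t.size), y, 0.5 * y, {})


class TestIntervals:
    def test_qrs_end_on_synthetic_complex(self):
        ecg = _triphasic_ecg(qrs_end=95.0)
        assert bm.qrs_duration(ecg, 0.0) == pytest.approx(95.0, abs=3.0)

    def test_flat_leads_rejected(self):
        t = np.arange(0.0, 300.0)
        z = np.zeros(t.size)
        with pytest.raises(AnalysisError):
            bm.qrs_duration(pe.EcgTrace(t, z, z, z, {}), 0.0)

    def test_qt_end_on_synthetic_beat(self):
        ecg = _triphasic_ecg(qrs_end=95.0, t_end=350.0)
        qt = bm.qt_interval(ecg, 0.0)
        assert qt == pytest.approx(350.0, abs=5.0)
        assert qt >= bm.qrs_duration(ecg, 0.0)

    def test_fractionation_counter(self):
        smooth = _triphasic_ecg()
        notched = _triphasic_ecg()
        y = notched.la.copy()
        y[20:30] *= -1.0  # extra excursion through baseline
        notched = pe.EcgTrace(notched.t, notched.ra, y, notched.ll, {})
        assert (bm.lead_zero_crossings(notched, "LI", 0.0, 100.0)
                > bm.lead_zero_crossings(smooth, "LI", 0.0, 100.0))


class TestDifferences:
    def test_reference_sex_differences_recomputed(self):
        mk = ingest_reference_tables()["markers"].rename(columns={
            "cv_cm_s": "cv_cm_s"})
        diffs = bm.difference_markers(mk)
        sex = diffs["sex_diff"].set_index(["heart", "geometry"])
        printed = mk.groupby(["heart", "geometry"]).qt_diff_printed_ms.first()
        mismatches = []
        for key, row in sex.iterrows():
            if row.qt_diff_ms != printed[key]:
                mismatches.append(key)
        # a single known-inconsistent printed cell (heart B, smoothed)
        assert mismatches == [("B", "smoothed")]

    def test_reference_geometry_differences_match(self):
        tables = ingest_reference_tables()
        diffs = bm.difference_markers(tables["markers"])
        geo = diffs["geometry_diff"].set_index(["heart", "sex"])
        ref = tables["geometry_diffs"].set_index(["heart", "sex"])
        for key in geo.index:
            assert geo.loc[key, "tat_gdiff"] == pytest.approx(
                ref.loc[key, "tat_gdiff_ms"], abs=0.11)
        assert geo["tat_gdiff"].mean() == pytest.approx(3.35, abs=0.02)

    def test_unmatched_rows_dropped(self):
        df = pd.DataFrame([
            dict(heart="X", geometry="detailed", sex="male", qrs_ms=90,
                 qt_ms=340, tat_ms=100, tat10_ms=10, tat90_ms=70, edi_ms=20,
                 cv_cm_s=80)])
        diffs = bm.difference_markers(df)
        assert diffs["sex_diff"].empty and diffs["geometry_diff"].empty


class TestWelch:
    def test_identical_groups(self):
        t, df, p = bm.welch_ttest([1.0, 1.0, 1.0], [1.0, 1.0])
        assert (t, p) == (0.0, 1.0)

    def test_reference_qt_comparison(self):
        male = [349.0, 339.0, 337.0, 357.0]
        female = [391.0, 376.0, 364.0, 391.0]
        t, df, p = bm.welch_ttest(female, male)
        # frozen from the closed-form Welch formulas on these samples
        assert t == pytest.approx(4.36, abs=0.05)
        assert df == pytest.approx(5.4, abs=0.2)
        from scipy import stats
        t_ref, p_ref = stats.ttest_ind(female, male, equal_var=False)
        assert t == pytest.approx(float(t_ref), abs=1e-12)
        assert p == pytest.approx(float(p_ref), abs=1e-12)

    def test_swapping_groups_flips_sign(self):
        a, b = [1.0, 2.0, 3.0], [4.0, 5.0, 7.0]
        t1, _, p1 = bm.welch_ttest(a, b)
        t2, _, p2 = bm.welch_ttest(b, a)
        assert t1 == -t2 and p1 == p2

    def test_small_groups_rejected(self):
        with pytest.raises(AnalysisError):
            bm.welch_ttest([1.0], [2.0, 3.0])
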