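"""Shared fixtures: desk-scale meshes and the simulations several test
modules analyse.  The expensive tissue runs are session-scoped so each is
integrated exactly once."""

import numpy as np
import pytest

from ventric import anatomy, biomarkers as bm, fibers as fb, monodomain as md
from ventric import pseudo_ecg as pe, vt, workbench as wb
from ventric.anatomy import StimulusSite


@pytest.fixture(scope="session")
def cable_runs():
    """Planar-wave cable runs under the physiological myocardial diffusion.

    ``L04``/``L02``: fiber-direction propagation at 0.04 / 0.02 cm;
    ``T02``: cross-fiber propagation at 0.02 cm.
    """
    out = {}
    spec = md.DiffusionSpec()
    cases = {"L04": (0.04, (1, 0, 0), 40.0),
             "L02": (0.02, (1, 0, 0), 40.0),
             "T02": (0.02, (0, 1, 0), 70.0)}
    for key, (dx, direction, dur) in cases.items():
        mesh = anatomy.make_cable(2.0, dx)
        fib = fb.uniform_fibers(mesh, direction=direction, sheet=(0, 0, 1))
        prob = md.MonodomainProblem(mesh, fib, spec, init_beats=3, dt_ms=0.01)
        site = StimulusSite("end", np.flatnonzero(mesh.nodes[:, 0] <= 0.08),
                            0.0, -80.0, 2.0)
        res = prob.run([site], dur, analysis_start_ms=0.0)
        out[key] = {"mesh": mesh, "result": res, "cv": md.cable_cv(mesh, res)}
    return out


@pytest.fixture(scope="session")
def biv_pair():
    """Heart-A-like twin pair: 16.3% trabecular volume, three long false
    tendons — the cohort's most heavily structured anatomy."""
    cfg = anatomy.BiventricularConfig(trabecular_fraction_target=0.163,
                                      n_false_tendons=3, seed=1)
    detailed, smoothed = anatomy.make_biventricular_pair(cfg)
    return cfg, detailed, smoothed


@pytest.fixture(scope="session")
def biv_sinus(biv_pair):
    """Male sinus-rhythm beats on the detailed/smoothed pair.

    The pair runs with all diffusivities scaled 3.5x, the desk-scale
    calibration that keeps discrete propagation robust at the fixture's
    0.075-cm elements.
    """
    _, detailed, smoothed = biv_pair
    spec = md.DiffusionSpec().with_scaled(3.5)
    out = {}
    for name, mesh in (("detailed", detailed), ("smoothed", smoothed)):
        fib = fb.assign_fibers(mesh)
        sites = anatomy.place_iars(mesh)
        res = md.run_simulation(mesh, fib, spec, sites, 80.0, sex="male",
                                dt_ms=0.02, init_beats=8, snapshot_ms=0.5)
        ecg = pe.compute_pseudo_ecg(res, mesh, fib, spec)
        out[name] = {"mesh": mesh, "fibers": fib, "spec": spec,
                     "sites": sites, "result": res, "ecg": ecg}
    return out


@pytest.fixture(scope="session")
def slab_matrix():
    """Male/female full beats on a transmural wedge, driven through the
    experiment-matrix pipeline.

    The wedge is a thin strand whose endo/mid/epi layers lie along the
    propagation axis — the classic preparation in which the transmural
    APD gradient generates a measurable T wave, so QRS and QT are both
    defined on the pseudo-ECG.
    """
    from dataclasses import replace
    m0 = anatomy.make_slab(1.2, 0.25, 0.1, 0.05)
    phi = m0.nodes[:, 0] / 1.2
    mesh = replace(m0, phi=phi, layer=np.digitize(phi, (0.3, 0.7)),
                   z=np.zeros(m0.n_nodes))
    fib = fb.uniform_fibers(mesh)
    spec = md.DiffusionSpec()
    site = StimulusSite("endo_end", np.flatnonzero(mesh.nodes[:, 0] <= 0.051),
                        0.0, -80.0, 2.0)
    cases = [wb.MatrixCase("W1", "detailed", sex, mesh, fib, spec, [site],
                           duration_ms=450.0 if sex == "male" else 490.0,
                           dt_ms=0.02, init_beats=25)
             for sex in ("male", "female")]
    return wb.run_matrix(cases, seed=1)


@pytest.fixture(scope="session")
def ridge_field():
    mesh = anatomy.make_ridge_slab(wall=0.45, h=0.03)
    return mesh, fb.assign_fibers(mesh)


@pytest.fixture(scope="session")
def limit_cycle_endo():
    from ventric import cell
    params = cell.make_cell_parameters("endo", "male", 0.0)
    state, n_beats, history = cell.pace_to_limit_cycle(params, 600.0)
    return params, state, n_beats, history


@pytest.fixture(scope="session")
def ring_runs():
    """Programmed-stimulation trials on the annular reentry substrate:
    the inducing S1-S2 plan with the circuit closed, and the open-loop
    (no-core) specificity control."""
    out = {}
    for key, with_core, observe in (("induced", True, 700.0),
                                    ("control", False, 450.0)):
        mesh, fib, spec, site = vt.make_ring_fixture(with_core=with_core)
        P = vt.ring_node_params(mesh)
        S = vt.ring_initial_state(mesh)
        prob = md.MonodomainProblem(mesh, fib, spec, dt_ms=0.02,
                                    node_params=P, initial_state=S)
        s2 = 140.0
        stims = [StimulusSite("S1", site.nodes, 0.0, -60.0, 2.0),
                 StimulusSite("S2", site.nodes, s2, -60.0, 2.0)]
        res = prob.run(stims, s2 + observe, snapshot_ms=5.0,
                       analysis_start_ms=0.0)
        events = vt.detect_reentry(res, (s2,), site.label, mesh=mesh,
                                   site_nodes=site.nodes)
        out[key] = {"mesh": mesh, "result": res, "events": events,
                    "site": site}
    return out
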