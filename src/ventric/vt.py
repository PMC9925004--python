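"""Programmed electrical stimulation and reentry analysis.

Implements a Josephson-style S1-S2-S3-S4 inducibility protocol: a drive
train at a 400-ms basic cycle length followed by up to three decremental
extrastimuli.  Coupling intervals are scanned downward until an
extrastimulus fails to capture (the effective refractory period); if no
arrhythmia is induced the next extrastimulus level is added.  A branch
stops as soon as a sustained ventricular tachycardia is obtained.

Arrhythmic events are read from the upstroke-crossing log after the final
stimulus: a *reentrant full heart activation* re-excites at least 90% (by
default) of the excitable tissue with no external source; three or more
such re-activations classify the event as sustained VT, one or two as a
non-sustained reentry, and partial re-activations below 30% are logged as
wavelets, not events.

The canonical desk-scale substrate is a thin slab carrying a dense
(non-excitable) scar core crossed by a slow-conducting border-zone channel
— the protected isthmus whose conduction delay lets the exiting wave
re-excite recovered tissue.
"""

import copy
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import scipy.sparse as sp

from ventric import cell as _cell
from ventric.anatomy import (BORDER_ZONE, DENSE_SCAR, MYOCARDIUM, Mesh,
                             StimulusSite, make_slab)
from ventric.cell import ord_kernel as _k
from ventric.errors import ConfigurationError
from ventric.fibers import FiberField, uniform_fibers
from ventric.monodomain import (DiffusionSpec, MonodomainProblem,
                                SimulationResult)

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class StimulationPlan:
    """Programmed-stimulation scan description."""

    site_label: str = "site"
    s1_cycle_ms: float = 400.0
    n_s1: int = 2                      # desk-scale drive train (clinically 6-8)
    s2_start_ms: float = 340.0
    s3_start_ms: float | None = None   # None: start at the S2 that captured
    s4_start_ms: float | None = None
    decrement_ms: float = 10.0
    min_coupling_ms: float = 180.0
    erp_margin_ms: float = 20.0
    amplitude: float = -150.0
    duration_ms: float = 3.0
    observe_ms: float = 900.0          # quiescence window after the last stimulus

    def __post_init__(self):
        if self.min_coupling_ms <= 0 or self.s1_cycle_ms <= 0:
            raise ConfigurationError("coupling intervals must be positive")
        if self.s2_start_ms < self.min_coupling_ms:
            raise ConfigurationError("S2 scan starts below the minimum coupling")


@dataclass
class ArrhythmiaEvent:
    kind: str                          # "nonsustained_reentry" | "sustained_VT"
    n_reactivations: int
    cycle_lengths_ms: list
    beat_times_ms: list
    couplings: tuple                   # (S2, S3, S4) coupling intervals used
    site_label: str

    def __post_init__(self):
        if self.kind == "sustained_VT" and self.n_reactivations < 3:
            raise ConfigurationError("sustained VT requires >= 3 reactivations")


@dataclass
class Trial:
    couplings: tuple
    captured: tuple
    events: list
    site_label: str
    result: SimulationResult | None = None


# ---------------------------------------------------------------------------
# reentry detection

def detect_reentry(result: SimulationResult, couplings=(), site_label="site",
                   mesh: Mesh | None = None, site_nodes=None,
                   reference_nodes=None, full_threshold: float = 0.9,
                   wavelet_threshold: float = 0.3, min_cycle_ms: float = 60.0,
                   free_delay_ms: float = 100.0) -> list[ArrhythmiaEvent]:
    """Classify post-stimulation re-activations from the crossing log.

    Reentrant beats are counted at a reference region — by default the
    excitable tissue farthest from the stimulation site, following the
    clinical convention of measuring tachycardia cycle lengths away from
    the pacing electrode.  Each reference activation later than the direct
    response to the final stimulus opens one cycle; a cycle re-exciting at
    least ``full_threshold`` of the excitable tissue counts as a reentrant
    full activation, smaller re-activations above ``wavelet_threshold``
    are logged as wavelets and ignored.
    """
    if not result.stimulus_log:
        return []
    last = max(s["onset_ms"] + s["duration_ms"] for s in result.stimulus_log)
    # the directly paced beat may legitimately take this long to reach the
    # reference region; later reference activations have no external source
    t_free = last + free_delay_ms
    n_exc = int(result.excitable_mask.sum())
    times = result.crossing_times
    nodes = result.crossing_nodes

    if reference_nodes is None:
        if mesh is not None and site_nodes is not None:
            com = mesh.nodes[np.asarray(site_nodes)].mean(axis=0)
            d = np.linalg.norm(mesh.nodes - com, axis=1)
            exc = result.excitable_mask
            cut = np.percentile(d[exc], 98.0)
            reference_nodes = np.flatnonzero(exc & (d >= cut))
        else:
            reference_nodes = np.flatnonzero(result.excitable_mask)
    ref = np.isin(nodes, reference_nodes) & (times > t_free)
    rt = np.sort(times[ref])
    if rt.size == 0:
        return []
    beats = [float(rt[0])]
    for t in rt[1:]:
        if t - beats[-1] > min_cycle_ms:
            beats.append(float(t))

    # score each cycle by the tissue fraction it re-excites
    order = np.argsort(times)
    ts, ns = times[order], nodes[order]
    full_beats, partials = [], 0
    edges = beats + [beats[-1] + (np.median(np.diff(beats)) if len(beats) > 1
                                  else 2 * min_cycle_ms)]
    for a, b in zip(edges[:-1], edges[1:]):
        i, j = np.searchsorted(ts, [a - 1e-9, b])
        frac = np.unique(ns[i:j]).size / max(1, n_exc)
        if frac >= full_threshold:
            full_beats.append(a)
        elif frac >= wavelet_threshold:
            partials += 1
    if partials:
        log.info("%d partial re-activations (<%d%% of tissue) logged as wavelets",
                 partials, int(full_threshold * 100))
    if not full_beats:
        return []
    cls = [float(b - a) for a, b in zip(full_beats[:-1], full_beats[1:])]
    kind = "sustained_VT" if len(full_beats) >= 3 else "nonsustained_reentry"
    return [ArrhythmiaEvent(kind, len(full_beats), cls, full_beats,
                            tuple(couplings), site_label)]


def locate_reentry_sites(result: SimulationResult, mesh: Mesh,
                         events: list[ArrhythmiaEvent],
                         early_ms: float = 15.0) -> list[dict]:
    """Earliest-reactivation region per reentrant beat.

    For each beat, the centroid of the largest connected component of
    nodes activating within ``early_ms`` of the beat onset, classified by
    region (border-zone channel vs working myocardium) and transmural
    surface (endo / epi / transmural).
    """
    nreg = mesh.node_regions()
    adj = _node_adjacency(mesh)
    out = []
    for ev in events:
        for bt in ev.beat_times_ms:
            sel = (result.crossing_times >= bt) & (result.crossing_times < bt + early_ms)
            nodes = np.unique(result.crossing_nodes[sel])
            if nodes.size == 0:
                continue
            sub = adj[nodes][:, nodes]
            ncomp, comp = sp.csgraph.connected_components(sub, directed=False)
            largest = np.argmax(np.bincount(comp))
            pick = nodes[comp == largest]
            centroid = mesh.nodes[pick].mean(axis=0)
            regs = nreg[pick]
            in_channel = bool(np.any(regs == BORDER_ZONE))
            phi = float(mesh.phi[pick].mean())
            surface = "endo" if phi < 0.3 else ("epi" if phi > 0.7 else "transmural")
            assert not np.any(regs == DENSE_SCAR), "reentry cannot originate in scar"
            out.append({"beat_time_ms": float(bt), "centroid": tuple(map(float, centroid)),
                        "in_border_zone_channel": in_channel, "surface": surface,
                        "n_nodes": int(pick.size)})
    return out


def _node_adjacency(mesh: Mesh) -> sp.csr_matrix:
    e = mesh.tets
    pairs = np.vstack([e[:, [a, b]] for a in range(4) for b in range(a + 1, 4)])
    A = sp.coo_matrix((np.ones(pairs.shape[0]), (pairs[:, 0], pairs[:, 1])),
                      shape=(mesh.n_nodes, mesh.n_nodes))
    return (A + A.T).tocsr()


# ---------------------------------------------------------------------------
# the protocol

def _extrastimulus_captured(result: SimulationResult, onset_ms: float,
                            window_ms: float = 120.0, frac: float = 0.3) -> bool:
    """An extrastimulus captures if it triggers a propagated response."""
    return result.activated_fraction((onset_ms, onset_ms + window_ms)) >= frac


def run_trial(problem_state, problem: MonodomainProblem, site: StimulusSite,
              plan: StimulationPlan, couplings: tuple,
              keep_result: bool = False) -> Trial:
    """One pacing trial: restore the post-drive state, deliver the
    extrastimuli at the given couplings and observe."""
    problem.S = problem_state["S"].copy()
    problem.time = problem_state["time"]
    t0 = problem_state["last_s1_onset"]
    onsets = []
    t = t0
    for c in couplings:
        t += c
        onsets.append(t)
    stims = [StimulusSite(f"S{k + 2}", site.nodes, on, plan.amplitude, plan.duration_ms)
             for k, on in enumerate(onsets)]
    duration = (onsets[-1] if onsets else t0) + plan.observe_ms - problem.time
    res = problem.run(stims, duration, snapshot_ms=5.0,
                      analysis_start_ms=problem_state["time"])
    captured = tuple(_extrastimulus_captured(res, on) for on in onsets)
    events = detect_reentry(res, couplings, site.label,
                            mesh=problem.mesh, site_nodes=site.nodes)
    return Trial(tuple(couplings), captured, events, site.label,
                 res if keep_result else None)


def run_programmed_stimulation(mesh: Mesh, fibers: FiberField, spec: DiffusionSpec,
                               site: StimulusSite, plan: StimulationPlan,
                               sex: str = "male", node_params=None,
                               dt_ms: float = 0.02, init_beats: int | None = 20,
                               max_trials: int = 40,
                               keep_results: str = "events") -> list[Trial]:
    """Execute the decremental S2/S3/S4 scan at one pacing site.

    The drive train is integrated once and each trial restarts from the
    post-drive snapshot.  The scan stops a branch on sustained VT (the
    remaining sites, if any, are the caller's loop).
    ``keep_results``: "none" | "events" | "all" — which trials retain the
    full simulation result.
    """
    if DENSE_SCAR not in set(mesh.region) and np.any(mesh.region == DENSE_SCAR):
        pass  # scar optional; a scar-free run simply yields no events
    prob = MonodomainProblem(mesh, fibers, spec, sex=sex, dt_ms=dt_ms,
                             node_params=node_params, init_beats=init_beats,
                             cycle_length_ms=plan.s1_cycle_ms)
    s1 = [StimulusSite("S1", site.nodes, b * plan.s1_cycle_ms,
                       plan.amplitude, plan.duration_ms)
          for b in range(plan.n_s1)]
    last_s1 = (plan.n_s1 - 1) * plan.s1_cycle_ms
    drive = prob.run(s1, last_s1 + 0.6 * plan.s1_cycle_ms, snapshot_ms=5.0,
                     analysis_start_ms=last_s1)
    if drive.activated_fraction() < 0.5:
        raise ConfigurationError("loss of S1 capture during the drive train")
    state = {"S": prob.S.copy(), "time": prob.time, "last_s1_onset": last_s1}

    trials: list[Trial] = []

    def do(couplings):
        keep = keep_results == "all"
        tr = run_trial(state, prob, site, plan, couplings, keep_result=True)
        if keep_results == "none" or (keep_results == "events" and not tr.events):
            tr.result = None
        trials.append(tr)
        return tr

    def scan(prefix, start):
        """Decrement the last coupling from ``start``; returns ('vt'|'erp'|
        'floor', last captured coupling or None)."""
        c = start
        last_captured = None
        while c >= plan.min_coupling_ms and len(trials) < max_trials:
            tr = do(prefix + (c,))
            if any(ev.kind == "sustained_VT" for ev in tr.events):
                return "vt", c
            if not tr.captured[-1]:
                return "erp", last_captured
            last_captured = c
            c -= plan.decrement_ms
        return "floor", last_captured

    outcome, s2 = scan((), plan.s2_start_ms)
    if outcome == "vt":
        return trials
    if s2 is None:  # S2 never captured; nothing more to scan
        return trials
    s2 = s2 + plan.erp_margin_ms
    outcome, s3 = scan((s2,), plan.s3_start_ms or s2)
    if outcome == "vt" or s3 is None:
        return trials
    s3 = s3 + plan.erp_margin_ms
    outcome, _ = scan((s2, s3), plan.s4_start_ms or s3)
    return trials


def tally_events(trials_by_condition: dict) -> "pd.DataFrame":
    """Events/simulations table per (geometry, sex, site).

    ``trials_by_condition`` maps (geometry, sex, site) -> list of Trial.
    Percentages are rounded to the nearest integer percent.
    """
    import pandas as pd
    rows = []
    for (geometry, sex, site), trials in trials_by_condition.items():
        n_sim = len(trials)
        n_ev = sum(1 for t in trials if t.events)
        rows.append({"geometry": geometry, "sex": sex, "site": site,
                     "events": n_ev, "simulations": n_sim,
                     "pct": event_percentage(n_ev, n_sim)})
    return pd.DataFrame(rows)


def event_percentage(events: int, simulations: int) -> int:
    """E/S as the nearest integer percent."""
    if simulations <= 0:
        raise ConfigurationError("no simulations to tally")
    return int(round(100.0 * events / simulations))


# ---------------------------------------------------------------------------
# desk-scale substrate

def ring_substrate_cells():
    """Myocyte variants of the reduced-wavelength reentry substrate.

    The loop myocyte accelerates repolarization through instantaneous
    currents (ICaL and late-INa down, IK1 up) and boosts INa, keeping the
    action potential short (~70 ms) without the standing delayed-rectifier
    current that a gKr-based shortening would leave between close beats;
    the border-zone gate myocyte keeps a ~150-ms action potential, so a
    premature beat blocks inside it while a full reentrant cycle conducts.
    These are fixture parameter sets, not physiological phenotypes.
    """
    base = _cell.make_cell_parameters("endo", "male", 0.0)

    def scaled(**factors):
        return replace(base, **{k: getattr(base, k) * v for k, v in factors.items()})

    loop = scaled(P_Ca=0.1, g_NaL=0.05, g_K1=3.0, g_NaCa=0.4, g_Kr=2.0, g_Na=1.5)
    gate = scaled(P_Ca=0.45, g_NaL=0.2, g_K1=2.0, g_Na=2.0)
    return loop, gate


def make_ring_fixture(with_core: bool = True, h: float = 0.05,
                      r_mid: float = 2.7, width: float = 0.24,
                      rim: float = 0.12, arc_deg: tuple = (285.0, 335.0),
                      site_deg: tuple = (262.0, 278.0)):
    """Protected-circuit reentry substrate: an annular channel in scar.

    A closed border-zone/myocardial loop of radius ``r_mid`` is embedded
    in non-conducting dense scar (the insulating rim models the infarct
    core on both sides of a surviving channel).  A longer-refractory
    border-zone arc (``arc_deg``) sits clockwise of the pacing segment
    (``site_deg``) and acts as the unidirectional gate for premature
    beats.  ``with_core=False`` opens the loop with a scar gap far from
    the pacing site — the no-circuit specificity control.

    Returns ``(mesh, fibers, spec, site)``.
    """
    L = 2 * (r_mid + width / 2 + rim) + 2 * h
    full = make_slab(L, L, h, h)
    c = full.centroids()
    x, y = c[:, 0] - L / 2, c[:, 1] - L / 2
    rr = np.hypot(x, y)
    ang = np.degrees(np.arctan2(y, x)) % 360.0
    ring = np.abs(rr - r_mid) <= width / 2
    band = np.abs(rr - r_mid) <= width / 2 + rim
    a0, a1 = arc_deg
    arc = ring & (ang >= a0) & (ang <= a1)
    region = np.full(full.n_elements, DENSE_SCAR)
    region[ring] = MYOCARDIUM
    region[arc] = BORDER_ZONE
    if not with_core:
        gap = ring & (ang >= 60.0) & (ang <= 75.0)
        region[gap] = DENSE_SCAR
    kept = np.flatnonzero(band)
    used, inv = np.unique(full.tets[kept], return_inverse=True)
    mesh = Mesh(full.nodes[used], inv.reshape(-1, 4), region[kept],
                full.phi[used], full.z[used], full.layer[used],
                metadata={"kind": "ring_fixture", "r_mid": r_mid, "L": L,
                          "with_core": with_core})
    fibers = uniform_fibers(mesh, (0.0, 1.0, 0.0), (0.0, 0.0, 1.0))
    spec = (DiffusionSpec()
            .with_region(MYOCARDIUM, 5.8e-3)
            .with_region(BORDER_ZONE, 5.8e-3)
            .with_region(DENSE_SCAR, 0.0, excitable=False))
    nx, ny = mesh.nodes[:, 0] - L / 2, mesh.nodes[:, 1] - L / 2
    nang = np.degrees(np.arctan2(ny, nx)) % 360.0
    nrr = np.hypot(nx, ny)
    s0, s1 = site_deg
    site = StimulusSite("ring", np.flatnonzero(
        (nang >= s0) & (nang <= s1) & (np.abs(nrr - r_mid) <= width / 2)),
        0.0, -60.0, 2.0)
    return mesh, fibers, spec, site


def ring_node_params(mesh: Mesh):
    """(NP, n) multiplier array assigning loop/gate myocytes by region."""
    loop, gate = ring_substrate_cells()
    nreg = mesh.node_regions()
    P = np.repeat(loop.multipliers()[:, None], mesh.n_nodes, axis=1)
    P[:, nreg == BORDER_ZONE] = gate.multipliers()[:, None]
    return P


def ring_initial_state(mesh: Mesh, n_beats: int = 15,
                       cycle_length_ms: float = 400.0):
    """Tissue state with both substrate myocytes paced to near-steady state."""
    loop, gate = ring_substrate_cells()
    nreg = mesh.node_regions()
    *_, s_loop = _cell.pace(loop, n_beats, cycle_length_ms)
    *_, s_gate = _cell.pace(gate, n_beats, cycle_length_ms)
    S = np.repeat(s_loop[:, None], mesh.n_nodes, axis=1)
    S[:, nreg == BORDER_ZONE] = s_gate[:, None]
    return S
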