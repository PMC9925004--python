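"""Anisotropic monodomain reaction-diffusion solver on tetrahedral meshes.

The transmembrane potential obeys

    dV/dt = div(D grad V) - (I_ion - I_stim) / C_m

with a region-wise orthotropic diffusion tensor D = D_f f.f + D_t s.s +
D_n n.n built from the local fiber triad.  Space is discretized with
linear tetrahedral finite elements (lumped mass, zero-flux boundaries) and
time with operator splitting: an explicit Rush-Larsen/Euler reaction update
per node followed by an implicit (backward Euler) diffusion solve, at a
default step of 0.01 ms.

Default diffusivities (cm^2/ms) reproduce the physiological calibration of
the parent study: 5.8e-3 along the fiber and 1.9e-3 across it in the bulk
myocardium, and a fast-conducting endocardial layer at 1.7e-2 / 5.8e-3
standing in for the Purkinje network.  The fast layer extends over the
trabecular and false-tendon network.  The border zone conducts
isotropically at the normal transverse diffusion; the dense scar is a
non-excitable passive load with 10% of the transverse diffusion.
"""

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from ventric import cell as _cell
from ventric import fem
from ventric.anatomy import (BORDER_ZONE, DENSE_SCAR, FALSE_TENDON, FAST_ENDO,
                             MYOCARDIUM, TRABECULA, LAYER_NAMES, Mesh, StimulusSite)
from ventric.cell import ord_kernel as _k
from ventric.errors import ConfigurationError, NumericalError
from ventric.fibers import FiberField

log = logging.getLogger(__name__)

#: physiological myocardial diffusion, cm^2/ms
D_FIBER = 5.8e-3
D_TRANSVERSE = 1.9e-3
#: fast-conducting endocardial layer, cm^2/ms
D_FAST_FIBER = 1.7e-2
D_FAST_TRANSVERSE = 5.8e-3


@dataclass(frozen=True)
class DiffusionSpec:
    """Per-region diffusivities (cm^2/ms) and excitability flags."""

    diffusivities: dict = field(default_factory=lambda: {
        MYOCARDIUM: (D_FIBER, D_TRANSVERSE, D_TRANSVERSE),
        FAST_ENDO: (D_FAST_FIBER, D_FAST_TRANSVERSE, D_FAST_TRANSVERSE),
        TRABECULA: (D_FAST_FIBER, D_FAST_TRANSVERSE, D_FAST_TRANSVERSE),
        FALSE_TENDON: (D_FAST_FIBER, D_FAST_TRANSVERSE, D_FAST_TRANSVERSE),
        BORDER_ZONE: (D_TRANSVERSE, D_TRANSVERSE, D_TRANSVERSE),
        DENSE_SCAR: (0.1 * D_TRANSVERSE, 0.1 * D_TRANSVERSE, 0.1 * D_TRANSVERSE),
    })
    excitable: dict = field(default_factory=lambda: {
        MYOCARDIUM: True, FAST_ENDO: True, TRABECULA: True,
        FALSE_TENDON: True, BORDER_ZONE: True, DENSE_SCAR: False,
    })

    def __post_init__(self):
        for r, d in self.diffusivities.items():
            if min(d) < 0:
                raise ConfigurationError(f"negative diffusivity for region {r}")
        if self.excitable.get(DENSE_SCAR, False):
            raise ConfigurationError("dense scar must be non-excitable")

    def with_scaled(self, factor: float) -> "DiffusionSpec":
        """All diffusivities multiplied by ``factor`` (fixture design knob)."""
        return DiffusionSpec(
            {r: tuple(x * factor for x in d) for r, d in self.diffusivities.items()},
            dict(self.excitable))

    def with_region(self, region: int, d, excitable: bool | None = None) -> "DiffusionSpec":
        dd = dict(self.diffusivities)
        dd[region] = tuple(d) if np.iterable(d) else (d, d, d)
        ex = dict(self.excitable)
        if excitable is not None:
            ex[region] = excitable
        return DiffusionSpec(dd, ex)


@dataclass
class SimulationResult:
    """Output of one tissue simulation.

    ``lat``/``rt90`` are computed over the analysis window (by default the
    final stimulated beat): local activation time is the first upstroke
    crossing of 0 mV, repolarization time the first return below 90% of
    the local AP amplitude.  ``crossing_times``/``crossing_nodes`` hold
    every upstroke crossing of the whole run, for reentry analysis.
    """

    t_snap: np.ndarray            # (nt,) ms
    v_snap: np.ndarray            # (nt, n) mV, float32
    lat: np.ndarray               # (n,) ms, NaN where never activated in window
    rt90: np.ndarray              # (n,) ms, NaN where undefined
    crossing_times: np.ndarray    # (k,) ms, all upstroke crossings
    crossing_nodes: np.ndarray    # (k,) int
    stimulus_log: list
    config: dict
    excitable_mask: np.ndarray    # (n,) bool

    def activated_fraction(self, window=None) -> float:
        if window is None:
            ok = np.isfinite(self.lat[self.excitable_mask])
            return float(ok.mean())
        t0, t1 = window
        sel = (self.crossing_times >= t0) & (self.crossing_times < t1)
        nodes = np.unique(self.crossing_nodes[sel])
        return float(nodes.size / max(1, int(self.excitable_mask.sum())))


def _element_tensors(mesh: Mesh, fibers: FiberField, spec: DiffusionSpec) -> np.ndarray:
    for v in (fibers.f, fibers.s, fibers.n):
        if not np.allclose(np.linalg.norm(v, axis=1), 1.0, atol=1e-6):
            raise ConfigurationError("non-unit fiber triad vectors in assembly")
    if np.abs(np.einsum("ij,ij->i", fibers.f, fibers.s)).max() > 1e-6:
        raise ConfigurationError("non-orthonormal fiber triads in assembly")
    f, s, n = fibers.element_triads(mesh)
    d = np.array([spec.diffusivities[r] for r in mesh.region])
    D = (d[:, 0, None, None] * np.einsum("ij,ik->ijk", f, f)
         + d[:, 1, None, None] * np.einsum("ij,ik->ijk", s, s)
         + d[:, 2, None, None] * np.einsum("ij,ik->ijk", n, n))
    return D


def assemble_operators(mesh: Mesh, fibers: FiberField, spec: DiffusionSpec):
    """Discrete diffusion operator K and lumped mass vector M.

    K is symmetric positive-semidefinite with zero row sums (zero-flux
    exterior boundary); the dense scar contributes diffusion but carries no
    reaction term.
    """
    D = _element_tensors(mesh, fibers, spec)
    d = np.array([spec.diffusivities[r] for r in mesh.region])
    active = d.max(axis=1) > 0.0
    if active.all():
        K = fem.assemble_stiffness(mesh.nodes, mesh.tets, D)
        M = fem.lumped_mass(mesh.nodes, mesh.tets)
    else:
        # a zero-diffusivity region is an electrical insulator: it carries
        # neither flux nor capacitive load (no-flux interface)
        K = fem.assemble_stiffness(mesh.nodes, mesh.tets[active], D[active])
        M = fem.lumped_mass(mesh.nodes, mesh.tets[active])
        M[M == 0.0] = 1.0  # isolated nodes: hold their value
    return K, M


# ---------------------------------------------------------------------------
# per-node membrane parameters and initial states

def build_node_parameters(mesh: Mesh, sex: str, preset: str = "dutta",
                          iks_base_scale: float = 0.8,
                          sex_factors: dict | None = None) -> np.ndarray:
    """(NP, n) kernel multipliers: transmural type from the layer label,
    sex phenotype, and the linear apex-to-base IKs gradient from ``z``."""
    if sex_factors is None:
        sex_factors = _cell.load_sex_factors()
    P = np.empty((_k.NP, mesh.n_nodes))
    for layer, name in enumerate(LAYER_NAMES):
        params = _cell.make_cell_parameters(name, sex, 0.0, preset=preset,
                                            sex_factors=sex_factors)
        col = params.multipliers()
        P[:, mesh.layer == layer] = col[:, None]
    P[_k.PGKS] *= 1.0 - (1.0 - iks_base_scale) * mesh.z
    return P


_LIMIT_CYCLE_CACHE: dict = {}


def limit_cycle_state(cell_type: str, sex: str, cycle_length_ms: float = 600.0,
                      preset: str = "dutta", n_beats: int | None = None,
                      tol_mmol: float = 1e-7, max_beats: int = 1000) -> np.ndarray:
    """Cached end-diastolic state for one cell phenotype.

    With ``n_beats`` set, paces a fixed number of beats instead of
    iterating to the calcium-RMSE tolerance (the cheap option for tissue
    initialization in fixtures).
    """
    key = (cell_type, sex, cycle_length_ms, preset, n_beats, tol_mmol)
    if key not in _LIMIT_CYCLE_CACHE:
        params = _cell.make_cell_parameters(cell_type, sex, 0.0, preset=preset)
        if n_beats is not None:
            *_, state = _cell.pace(params, n_beats, cycle_length_ms)
        else:
            state, _, _ = _cell.pace_to_limit_cycle(params, cycle_length_ms,
                                                    tol_mmol=tol_mmol,
                                                    max_beats=max_beats)
        _LIMIT_CYCLE_CACHE[key] = state
    return _LIMIT_CYCLE_CACHE[key]


def tissue_initial_state(mesh: Mesh, sex: str, cycle_length_ms: float = 600.0,
                         preset: str = "dutta", n_beats: int | None = 25) -> np.ndarray:
    """(NS, n) state array with each layer at its paced end-diastolic state."""
    S = np.empty((_k.NS, mesh.n_nodes))
    for layer, name in enumerate(LAYER_NAMES):
        st = limit_cycle_state(name, sex, cycle_length_ms, preset, n_beats)
        S[:, mesh.layer == layer] = st[:, None]
    return S


# ---------------------------------------------------------------------------
# the solver

class MonodomainProblem:
    """Assembled operators plus membrane state for one mesh.

    ``step`` performs one operator-splitting step; ``run`` integrates a
    stimulus schedule and records snapshots, activation and repolarization.
    """

    def __init__(self, mesh: Mesh, fibers: FiberField, spec: DiffusionSpec,
                 sex: str = "male", dt_ms: float = 0.01,
                 node_params: np.ndarray | None = None,
                 initial_state: np.ndarray | None = None,
                 init_beats: int | None = 25, cycle_length_ms: float = 600.0,
                 preset: str = "dutta"):
        self.mesh = mesh
        self.spec = spec
        self.dt = float(dt_ms)
        self.sex = sex
        K, M = assemble_operators(mesh, fibers, spec)
        self.K, self.M = K, M
        A = sp.diags(M) + self.dt * K
        self._solve = spla.factorized(A.tocsc())
        self.P = (build_node_parameters(mesh, sex, preset=preset)
                  if node_params is None else node_params)
        self.excitable = mesh.excitable_nodes()
        self._exc8 = self.excitable.astype(np.uint8)
        if initial_state is None:
            initial_state = tissue_initial_state(mesh, sex, cycle_length_ms,
                                                 preset, init_beats)
        self.S = initial_state.copy()
        self.S[_k.IV, ~self.excitable] = -88.0
        self.time = 0.0

    @property
    def v(self) -> np.ndarray:
        return self.S[_k.IV]

    def step(self, istim: np.ndarray | None = None):
        """One reaction + diffusion step of ``self.dt`` ms."""
        n = self.mesh.n_nodes
        if istim is None:
            istim = np.zeros(n)
        _k.step(self.S, self.P, istim, self._exc8, self.dt)
        v = self.S[_k.IV]
        self.S[_k.IV] = self._solve(self.M * v)
        self.time += self.dt

    def run(self, stimuli: list[StimulusSite], duration_ms: float,
            snapshot_ms: float = 1.0, analysis_start_ms: float | None = None,
            check_every: int = 200) -> SimulationResult:
        """Integrate ``duration_ms`` under a stimulus schedule.

        The activation/repolarization maps cover the analysis window
        ``[analysis_start_ms, duration_ms]``; by default the window opens
        at the latest stimulus onset (the final beat).
        """
        dt = self.dt
        n = self.mesh.n_nodes
        n_steps = int(round(duration_ms / dt))
        snap_every = max(1, int(round(snapshot_ms / dt)))
        n_snaps = n_steps // snap_every + 1
        v_snap = np.empty((n_snaps, n), dtype=np.float32)
        t_snap = np.empty(n_snaps)
        v_snap[0] = self.S[_k.IV]
        t_snap[0] = self.time
        isn = 1

        if analysis_start_ms is None:
            analysis_start_ms = max((s.onset_ms for s in stimuli), default=0.0)

        # stimulus schedule in steps
        sched = []
        for s in stimuli:
            i0 = int(round(s.onset_ms / dt))
            i1 = i0 + max(1, int(round(s.duration_ms / dt)))
            sched.append((i0, i1, s.amplitude, np.asarray(s.nodes)))
        stim_log = [{"label": s.label, "onset_ms": s.onset_ms,
                     "duration_ms": s.duration_ms, "amplitude": s.amplitude,
                     "n_nodes": int(np.asarray(s.nodes).size)} for s in stimuli]

        istim = np.zeros(n)
        above = self.S[_k.IV] >= 0.0
        lat = np.full(n, np.nan)
        ct_list, cn_list = [], []
        t0 = self.time

        for i in range(n_steps):
            istim[:] = 0.0
            for (i0, i1, amp, nodes) in sched:
                if i0 <= i < i1:
                    istim[nodes] += amp
            self.step(istim)
            v = self.S[_k.IV]
            now = v >= 0.0
            new = now & ~above & self.excitable
            if new.any():
                idx = np.flatnonzero(new)
                ct_list.append(np.full(idx.size, self.time))
                cn_list.append(idx)
                in_win = self.time >= analysis_start_ms
                if in_win:
                    fresh = idx[np.isnan(lat[idx])]
                    lat[fresh] = self.time
            above = now
            if (i + 1) % snap_every == 0:
                v_snap[isn] = v
                t_snap[isn] = self.time
                isn += 1
            if (i + 1) % check_every == 0 and np.abs(v).max() > 300.0:
                bad = int(np.argmax(np.abs(v)))
                raise NumericalError(
                    f"membrane potential diverged (|V|>300 mV) at node {bad}, "
                    f"t={self.time:.2f} ms")

        v_snap = v_snap[:isn]
        t_snap = t_snap[:isn]
        ct = np.concatenate(ct_list) if ct_list else np.empty(0)
        cn = np.concatenate(cn_list).astype(int) if cn_list else np.empty(0, dtype=int)
        # clear activations from before the analysis window (lat only holds
        # in-window times by construction)
        rt90 = _repolarization_map(t_snap, v_snap, lat)
        n_unact = int(np.sum(np.isnan(lat[self.excitable])))
        if n_unact:
            log.info("%d of %d excitable nodes not activated in the analysis window",
                     n_unact, int(self.excitable.sum()))
        return SimulationResult(
            t_snap=t_snap, v_snap=v_snap, lat=lat, rt90=rt90,
            crossing_times=ct, crossing_nodes=cn, stimulus_log=stim_log,
            config={"dt_ms": dt, "duration_ms": duration_ms,
                    "snapshot_ms": snapshot_ms, "sex": self.sex,
                    "analysis_start_ms": analysis_start_ms,
                    "t_start_ms": t0},
            excitable_mask=self.excitable)


def _repolarization_map(t_snap, v_snap, lat):
    """RT90 per node: first time after activation below V90 of the local AP."""
    n = v_snap.shape[1]
    rt90 = np.full(n, np.nan)
    act = np.isfinite(lat)
    if not act.any() or t_snap.size < 3:
        return rt90
    idx = np.flatnonzero(act)
    v = v_snap[:, idx].astype(float)
    i_act = np.searchsorted(t_snap, lat[idx])
    baseline = v[np.maximum(i_act - 2, 0), np.arange(idx.size)]
    peak = v.max(axis=0)
    v90 = baseline + 0.1 * (peak - baseline)
    for j in range(idx.size):
        seg = v[i_act[j]:, j]
        below = np.flatnonzero(seg <= v90[j])
        # skip the upstroke sample itself
        below = below[below > 0]
        if below.size:
            rt90[idx[j]] = t_snap[i_act[j] + below[0]]
    return rt90


def sinus_stimuli(sites: list[StimulusSite], n_beats: int = 1,
                  cycle_length_ms: float = 600.0) -> list[StimulusSite]:
    """Repeat the initial-activation sites over a sinus beat train."""
    out = []
    for b in range(n_beats):
        for s in sites:
            out.append(StimulusSite(s.label, s.nodes, s.onset_ms + b * cycle_length_ms,
                                    s.amplitude, s.duration_ms))
    return out


def run_simulation(mesh: Mesh, fibers: FiberField, spec: DiffusionSpec,
                   stimuli: list[StimulusSite], duration_ms: float,
                   sex: str = "male", n_beats: int = 1,
                   cycle_length_ms: float = 600.0, dt_ms: float = 0.01,
                   snapshot_ms: float = 1.0, init_beats: int | None = 25,
                   node_params: np.ndarray | None = None,
                   initial_state: np.ndarray | None = None) -> SimulationResult:
    """Convenience driver: assemble, initialize, pace ``n_beats`` and analyse
    the final beat."""
    prob = MonodomainProblem(mesh, fibers, spec, sex=sex, dt_ms=dt_ms,
                             node_params=node_params, initial_state=initial_state,
                             init_beats=init_beats, cycle_length_ms=cycle_length_ms)
    sched = sinus_stimuli(stimuli, n_beats, cycle_length_ms)
    return prob.run(sched, duration_ms, snapshot_ms=snapshot_ms)


def cable_cv(mesh: Mesh, result: SimulationResult, lo: float = 0.25,
             hi: float = 0.75) -> float:
    """Planar conduction velocity (cm/s) from the LAT profile of a cable.

    Fits LAT against the axial coordinate between the ``lo`` and ``hi``
    fractions of the length, away from stimulus and boundary effects.
    """
    x = mesh.nodes[:, 0]
    L = x.max() - x.min()
    sel = (x >= x.min() + lo * L) & (x <= x.min() + hi * L) & np.isfinite(result.lat)
    if sel.sum() < 4:
        raise NumericalError("not enough activated nodes for a CV fit")
    slope = np.polyfit(x[sel], result.lat[sel], 1)[0]  # ms/cm
    if slope <= 0:
        raise NumericalError("non-positive activation slope on the cable")
    return 1000.0 / slope
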