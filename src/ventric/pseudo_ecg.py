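"""Pseudo-ECG forward computation.

The extracellular potential at a distant field point x' is approximated by
the infinite-homogeneous-medium integral of the diffusion-weighted
transmembrane-voltage gradient over the cardiac tissue,

    phi_e(x') = - sum_elements  [D grad V_m] . grad(1/|x - x'|) vol_e ,

evaluated at element centroids, without any torso volume conductor.  Three
field points stand in for the right-arm (RA), left-arm (LA) and left-leg
(LL) electrodes; the limb leads follow Einthoven's convention
LI = LA - RA, LII = LL - RA, LIII = LL - LA, so the closure
LII = LI + LIII holds bit-exactly by construction.  Because no torso
conductivity enters, the global amplitude scale is arbitrary
("model mV"); all comparative markers are scale-consistent within a run.
"""

import logging
from dataclasses import dataclass

import numpy as np

from ventric import fem
from ventric.anatomy import Mesh
from ventric.errors import AnalysisError, ConfigurationError
from ventric.fibers import FiberField
from ventric.monodomain import DiffusionSpec, SimulationResult, _element_tensors

log = logging.getLogger(__name__)

ELECTRODE_NAMES = ("RA", "LA", "LL")

#: default electrode offsets in units of the mesh bounding-box diagonal,
#: relative to the bounding-box center; a torso-like arrangement with the
#: left leg beyond the apex and the arms above the base
DEFAULT_OFFSETS = {
    "RA": (-1.2, 0.8, 1.1),
    "LA": (1.2, 0.8, 1.1),
    "LL": (0.3, -0.4, -1.6),
}


@dataclass
class EcgTrace:
    """Three-electrode pseudo-ECG with Einthoven limb leads."""

    t: np.ndarray
    ra: np.ndarray
    la: np.ndarray
    ll: np.ndarray
    metadata: dict

    @property
    def li(self) -> np.ndarray:
        return self.la - self.ra

    @property
    def lii(self) -> np.ndarray:
        return self.ll - self.ra

    @property
    def liii(self) -> np.ndarray:
        return self.ll - self.la

    def lead(self, name: str) -> np.ndarray:
        return {"LI": self.li, "LII": self.lii, "LIII": self.liii,
                "RA": self.ra, "LA": self.la, "LL": self.ll}[name]

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame({"t_ms": self.t, "RA": self.ra, "LA": self.la,
                             "LL": self.ll, "LI": self.li, "LII": self.lii,
                             "LIII": self.liii})


def electrode_positions(mesh: Mesh, offsets: dict | None = None) -> dict:
    """Field-point coordinates for RA, LA and LL.

    Offsets are expressed in units of the mesh bounding-box diagonal from
    the bounding-box center, so the same configuration yields identical
    physical electrode coordinates for both members of a detailed/smoothed
    pair (which share their outline).  Explicit coordinates can be passed
    as ``offsets={"RA": (x, y, z), ...}`` with ``"absolute": True``.
    """
    offsets = dict(DEFAULT_OFFSETS) if offsets is None else dict(offsets)
    absolute = bool(offsets.pop("absolute", False))
    lo = mesh.nodes.min(axis=0)
    hi = mesh.nodes.max(axis=0)
    center = 0.5 * (lo + hi)
    diag = float(np.linalg.norm(hi - lo))
    out = {}
    for name in ELECTRODE_NAMES:
        if name not in offsets:
            raise ConfigurationError(f"missing electrode {name!r}")
        v = np.asarray(offsets[name], dtype=float)
        p = v if absolute else center + diag * v
        if np.all(p >= lo) and np.all(p <= hi):
            d = np.linalg.norm(mesh.nodes - p, axis=1).min()
            if d < 0.5 * diag / 10:
                raise ConfigurationError(
                    f"electrode {name} lies inside/too close to the myocardium")
        out[name] = p
    return out


def compute_pseudo_ecg(result: SimulationResult, mesh: Mesh, fibers: FiberField,
                       spec: DiffusionSpec, electrodes: dict | None = None,
                       min_distance: float | None = None) -> EcgTrace:
    """Pseudo-ECG from the recorded V_m snapshots.

    ``min_distance`` clamps the source-to-electrode distance to guard an
    electrode coincident with an element centroid (logged if triggered).
    """
    if electrodes is None:
        electrodes = electrode_positions(mesh)
    grads, vols = fem.shape_gradients(mesh.nodes, mesh.tets)
    D = _element_tensors(mesh, fibers, spec)
    cents = mesh.centroids()
    if min_distance is None:
        min_distance = 1e-3
    weights = {}
    for name in ELECTRODE_NAMES:
        x = np.asarray(electrodes[name], dtype=float)
        r = cents - x  # points from electrode to source
        dist = np.linalg.norm(r, axis=1)
        clamped = dist < min_distance
        if clamped.any():
            log.warning("%d element centroids within %.2g cm of electrode %s; "
                        "distance clamped", int(clamped.sum()), min_distance, name)
            dist = np.maximum(dist, min_distance)
        # grad_x (1/|x - x'|) = -(x - x') / |x - x'|^3
        g = -r / dist[:, None] ** 3
        weights[name] = np.einsum("mij,mj->mi", D, g) * vols[:, None]

    v = result.v_snap.astype(float)
    nt = v.shape[0]
    gv = np.einsum("maj,tma->tmj", grads, v[:, mesh.tets])
    traces = {name: -np.einsum("tmj,mj->t", gv, w) for name, w in weights.items()}
    meta = {"electrodes": {k: tuple(map(float, p)) for k, p in electrodes.items()},
            "scale": "model mV (homogeneous infinite medium)"}
    return EcgTrace(result.t_snap.copy(), traces["RA"], traces["LA"],
                    traces["LL"], meta)


def ecg_rmsd(a: EcgTrace, b: EcgTrace, leads=("LI", "LII", "LIII")) -> dict:
    """Per-lead root-mean-square difference on a common time grid."""
    t0 = max(a.t.min(), b.t.min())
    t1 = min(a.t.max(), b.t.max())
    if t1 <= t0:
        raise AnalysisError("traces share no common time window")
    dt = min(np.diff(a.t).min(), np.diff(b.t).min())
    grid = np.arange(t0, t1 + 0.5 * dt, dt)
    out = {}
    for lead in leads:
        ya = np.interp(grid, a.t, a.lead(lead))
        yb = np.interp(grid, b.t, b.lead(lead))
        out[lead] = float(np.sqrt(np.mean((ya - yb) ** 2)))
    return out
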