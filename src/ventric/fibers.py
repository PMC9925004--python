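"""Rule-based myofiber orientation with trabecula detection.

The compact wall follows the classical transmural helix rule: the helix
angle interpolates linearly in the transmural coordinate from ``alpha_endo``
(+60 deg default) on the endocardium to ``alpha_epi`` (-60 deg) on the
epicardium, with zero transverse angle.  Endocardial sub-structures
(trabeculae, false tendons) are detected from the magnitude of the
transmural-coordinate gradient: inside thin cavity-spanning structures the
Laplace field is nearly constant, so ``|grad phi|`` collapses.  The
detection parameter is

    t = |grad phi| / T   where |grad phi| < T,   else   t = 1,

with the threshold T = 0.1 expressed per millimetre of the normalized
coordinate.  Fibers blend from the transmural helix rule (t = 1) to a pure
longitudinal orientation along the structure's long axis (t = 0):

    alpha = 90 * (1 - t) + alpha_wall * t,     beta = 0,

which guarantees a smooth transition across the trabecula-endocardium
junction.
"""

import logging
from dataclasses import dataclass

import numpy as np

from ventric import fem
from ventric.anatomy import Mesh
from ventric.errors import ConfigurationError

log = logging.getLogger(__name__)

#: detection threshold on |grad phi|, per mm (the mesh works in cm)
DEFAULT_THRESHOLD = 0.1
_CM_PER_MM = 0.1


@dataclass
class FiberField:
    """Per-node orthonormal fiber/sheet/normal triads.

    ``f`` points along the myofiber, ``s`` along the sheet (transmural)
    direction and ``n`` completes the right-handed triad.  ``t`` is the
    trabecula-detection parameter and ``alpha``/``beta`` the helix and
    transverse angles in degrees.
    """

    f: np.ndarray
    s: np.ndarray
    n: np.ndarray
    t: np.ndarray
    alpha: np.ndarray
    beta: np.ndarray

    def __post_init__(self):
        for v in (self.f, self.s, self.n):
            if not np.allclose(np.linalg.norm(v, axis=1), 1.0, atol=1e-6):
                raise ConfigurationError("fiber triad vectors must be unit length")
        if (np.abs(np.einsum("ij,ij->i", self.f, self.s)).max() > 1e-6
                or np.abs(np.einsum("ij,ij->i", self.f, self.n)).max() > 1e-6):
            raise ConfigurationError("fiber triad must be orthogonal")

    def element_triads(self, mesh: Mesh):
        """Orthonormalized per-element triads by nodal averaging."""
        f = self.f[mesh.tets].mean(axis=1)
        s = self.s[mesh.tets].mean(axis=1)
        f /= np.linalg.norm(f, axis=1, keepdims=True)
        s -= np.einsum("ij,ij->i", s, f)[:, None] * f
        nrm = np.linalg.norm(s, axis=1, keepdims=True)
        bad = (nrm[:, 0] < 1e-8)
        if bad.any():  # fiber and sheet collapsed; rebuild any perpendicular
            alt = np.zeros_like(s[bad])
            alt[:, 0] = -f[bad][:, 1]
            alt[:, 1] = f[bad][:, 0]
            alt[np.linalg.norm(alt, axis=1) < 1e-8, 2] = 1.0
            s[bad] = alt
            nrm = np.linalg.norm(s, axis=1, keepdims=True)
        s /= nrm
        n = np.cross(f, s)
        return f, s, n


def transmural_gradient(mesh: Mesh) -> np.ndarray:
    """Nodal gradient of the transmural Laplace coordinate (1/cm)."""
    if mesh.phi is None or not np.all(np.isfinite(mesh.phi)):
        raise ConfigurationError("mesh carries no valid transmural coordinate")
    grads, vols = fem.shape_gradients(mesh.nodes, mesh.tets)
    ge = fem.element_gradient(grads, mesh.tets, mesh.phi)
    return fem.node_average(mesh.n_nodes, mesh.tets, vols, ge)


def apicobasal_gradient(mesh: Mesh) -> np.ndarray:
    grads, vols = fem.shape_gradients(mesh.nodes, mesh.tets)
    ge = fem.element_gradient(grads, mesh.tets, mesh.z)
    return fem.node_average(mesh.n_nodes, mesh.tets, vols, ge)


def detect_trabeculae(grad_norm: np.ndarray, threshold: float = DEFAULT_THRESHOLD) -> np.ndarray:
    """Trabecula parameter t in [0, 1] from the gradient magnitude.

    ``grad_norm`` and ``threshold`` must share units; t ramps linearly from
    0 (vanishing gradient, deep inside a sub-structure) to 1 at the
    threshold and saturates beyond it.
    """
    grad_norm = np.asarray(grad_norm, dtype=float)
    if np.any(grad_norm < 0):
        raise ConfigurationError("gradient magnitudes must be non-negative")
    if threshold <= 0:
        raise ConfigurationError("threshold must be positive")
    return np.minimum(grad_norm / threshold, 1.0)


def _smooth_nodal(mesh: Mesh, values: np.ndarray, passes: int) -> np.ndarray:
    """Neighbor-averaging passes of a nodal scalar (mesh-graph Jacobi)."""
    import scipy.sparse as sp
    e = mesh.tets
    pairs = np.vstack([e[:, [a, b]] for a in range(4) for b in range(4) if a != b])
    A = sp.coo_matrix((np.ones(pairs.shape[0]), (pairs[:, 0], pairs[:, 1])),
                      shape=(mesh.n_nodes, mesh.n_nodes)).tocsr()
    A = A + sp.eye(mesh.n_nodes)
    deg = np.asarray(A.sum(axis=1)).ravel()
    out = values.copy()
    for _ in range(passes):
        out = (A @ out) / deg
    return out


def assign_fibers(mesh: Mesh, t: np.ndarray | None = None,
                  alpha_endo_deg: float = 60.0, alpha_epi_deg: float = -60.0,
                  threshold: float = DEFAULT_THRESHOLD,
                  smooth_passes: int = 2) -> FiberField:
    """Fiber/sheet/normal triads for every node of the mesh.

    If ``t`` is not supplied it is computed from the transmural gradient
    with the default threshold (gradient converted to per-mm units) and
    smoothed by ``smooth_passes`` neighbor-averaging sweeps, which keeps
    the helix angle continuous across the trabecula-wall junction on
    coarse meshes.
    """
    gphi = transmural_gradient(mesh)
    gnorm = np.linalg.norm(gphi, axis=1)
    if t is None:
        t = detect_trabeculae(gnorm * _CM_PER_MM, threshold)
        if smooth_passes > 0:
            t = np.clip(_smooth_nodal(mesh, t, smooth_passes), 0.0, 1.0)
    t = np.asarray(t, dtype=float)

    gz = apicobasal_gradient(mesh)

    n = mesh.n_nodes
    eps = 1e-8
    # transmural (sheet) direction; fall back to a radial guess where flat
    e0 = np.zeros((n, 3))
    ok = gnorm > eps
    e0[ok] = gphi[ok] / gnorm[ok, None]
    fallback = ~ok
    if fallback.any():
        r = mesh.nodes[fallback].copy()
        r[:, 2] = 0.0
        nr = np.linalg.norm(r, axis=1)
        r[nr < eps] = (1.0, 0.0, 0.0)
        e0[fallback] = r / np.maximum(np.linalg.norm(r, axis=1), eps)[:, None]

    # longitudinal in-wall direction; sub-structures use their stored axis
    e2 = gz.copy()
    if mesh.structure_axis is not None:
        has_axis = np.isfinite(mesh.structure_axis).all(axis=1) & (t < 1.0)
        e2[has_axis] = mesh.structure_axis[has_axis]
    nflat = int(np.sum((t < 0.5) & ~(np.isfinite(mesh.structure_axis).all(axis=1)
                                     if mesh.structure_axis is not None
                                     else np.zeros(n, dtype=bool))))
    if nflat:
        log.warning("%d sub-structure nodes have no stored long axis; "
                    "using the apicobasal direction", nflat)
    e2 -= np.einsum("ij,ij->i", e2, e0)[:, None] * e0
    nrm = np.linalg.norm(e2, axis=1)
    deg = nrm < eps
    if deg.any():
        alt = np.cross(e0[deg], np.tile((0.0, 1.0, 0.0), (int(deg.sum()), 1)))
        low = np.linalg.norm(alt, axis=1) < eps
        alt[low] = np.cross(e0[deg][low], np.tile((1.0, 0.0, 0.0), (int(low.sum()), 1)))
        e2[deg] = alt
        nrm = np.linalg.norm(e2, axis=1)
    e2 /= nrm[:, None]
    e1 = np.cross(e2, e0)  # circumferential

    alpha_wall = alpha_endo_deg + (alpha_epi_deg - alpha_endo_deg) * mesh.phi
    alpha = 90.0 * (1.0 - t) + alpha_wall * t
    a = np.deg2rad(alpha)
    f = np.cos(a)[:, None] * e1 + np.sin(a)[:, None] * e2
    f /= np.linalg.norm(f, axis=1, keepdims=True)
    s = e0 - np.einsum("ij,ij->i", e0, f)[:, None] * f
    s /= np.linalg.norm(s, axis=1, keepdims=True)
    nvec = np.cross(f, s)
    return FiberField(f=f, s=s, n=nvec, t=t, alpha=alpha, beta=np.zeros(n))


def uniform_fibers(mesh: Mesh, direction=(1.0, 0.0, 0.0),
                   sheet=(0.0, 0.0, 1.0)) -> FiberField:
    """Constant fiber field (cable/slab fixtures)."""
    f = np.asarray(direction, dtype=float)
    f = f / np.linalg.norm(f)
    s = np.asarray(sheet, dtype=float)
    s = s - (s @ f) * f
    if np.linalg.norm(s) < 1e-8:
        raise ConfigurationError("sheet direction parallel to fiber direction")
    s /= np.linalg.norm(s)
    n = np.cross(f, s)
    one = np.ones(mesh.n_nodes)
    return FiberField(f=np.outer(one, f), s=np.outer(one, s), n=np.outer(one, n),
                      t=one.copy(), alpha=np.zeros(mesh.n_nodes),
                      beta=np.zeros(mesh.n_nodes))
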