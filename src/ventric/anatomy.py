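"""Synthetic desk-scale cardiac anatomies.

Generates tetrahedral test geometries emulating the structure of paired
detailed/smoothed ex-vivo biventricular models:

* a pseudo-1D **cable** and an axis-aligned **slab** for conduction-velocity
  calibration, anisotropy and reentry fixtures;
* an idealized truncated-ellipsoid **biventricular pair** — a smoothed
  two-cavity shell and a detailed twin that adds endocardial trabecular
  ridges and free-running false-tendon bridges whose added volume is tuned
  to a target trabecular fraction;
* a transmural **scar** with a border-zone channel (isthmus) for
  tachycardia-inducibility studies.

Every mesh carries a transmural Laplace coordinate phi (0 endo, 1 epi), an
apicobasal coordinate z (0 apex, 1 base), per-node transmural layer labels
partitioning the wall 30/40/30, and per-element region labels.  Units: cm.
"""

from dataclasses import dataclass, field, replace

import numpy as np
import scipy.sparse as sp

from ventric import fem
from ventric.errors import AnalysisError, ConfigurationError, GenerationError

# element region labels
MYOCARDIUM, FAST_ENDO, TRABECULA, FALSE_TENDON, BORDER_ZONE, DENSE_SCAR = range(6)
REGION_NAMES = ("myocardium", "fast_endo", "trabecula", "false_tendon",
                "border_zone", "dense_scar")
#: regions whose nodes carry active membrane kinetics
EXCITABLE_REGIONS = (MYOCARDIUM, FAST_ENDO, TRABECULA, FALSE_TENDON, BORDER_ZONE)

# node layer labels
LAYER_ENDO, LAYER_MID, LAYER_EPI = 0, 1, 2
LAYER_NAMES = ("endo", "mid", "epi")

IAR_LABELS = ("IAR1", "IAR2", "IAR3", "IAR4", "IAR5")
PACING_LABELS = ("LV_apex", "RV_apex", "RVOT")


@dataclass
class Mesh:
    """Labeled tetrahedral mesh with transmural/apicobasal coordinates."""

    nodes: np.ndarray            # (n, 3) cm
    tets: np.ndarray             # (m, 4) int
    region: np.ndarray           # (m,) int element labels
    phi: np.ndarray              # (n,) transmural coordinate, 0 endo -> 1 epi
    z: np.ndarray                # (n,) apicobasal coordinate, 0 apex -> 1 base
    layer: np.ndarray            # (n,) int transmural layer label
    structure_axis: np.ndarray | None = None  # (n, 3) long axis on sub-structures
    metadata: dict = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_elements(self) -> int:
        return self.tets.shape[0]

    def volumes(self) -> np.ndarray:
        return fem.tet_volumes(self.nodes, self.tets)

    def total_volume(self) -> float:
        return float(self.volumes().sum())

    def centroids(self) -> np.ndarray:
        return self.nodes[self.tets].mean(axis=1)

    def boundary_faces(self) -> np.ndarray:
        """Faces belonging to exactly one tetrahedron, shape (k, 3)."""
        faces = np.vstack([self.tets[:, idx] for idx in
                           ((0, 1, 2), (0, 1, 3), (0, 2, 3), (1, 2, 3))])
        key = np.sort(faces, axis=1)
        _, first, counts = np.unique(key, axis=0, return_index=True, return_counts=True)
        return faces[first[counts == 1]]

    def boundary_nodes(self) -> np.ndarray:
        return np.unique(self.boundary_faces())

    def node_regions(self) -> np.ndarray:
        """Minimum region label over the elements touching each node."""
        out = np.full(self.n_nodes, 99, dtype=int)
        for a in range(4):
            np.minimum.at(out, self.tets[:, a], self.region)
        return out

    def excitable_nodes(self) -> np.ndarray:
        """Boolean mask of nodes attached to at least one excitable element."""
        mask = np.zeros(self.n_nodes, dtype=bool)
        exc = np.isin(self.region, EXCITABLE_REGIONS)
        for a in range(4):
            mask[self.tets[exc, a]] = True
        return mask

    def element_adjacency(self) -> sp.csr_matrix:
        """Element-to-element adjacency through shared faces."""
        faces = np.vstack([self.tets[:, idx] for idx in
                           ((0, 1, 2), (0, 1, 3), (0, 2, 3), (1, 2, 3))])
        owner = np.tile(np.arange(self.n_elements), 4)
        key = np.sort(faces, axis=1)
        order = np.lexsort(key.T)
        key = key[order]
        owner = owner[order]
        same = np.all(key[1:] == key[:-1], axis=1)
        a = owner[:-1][same]
        b = owner[1:][same]
        m = self.n_elements
        A = sp.coo_matrix((np.ones(a.size), (a, b)), shape=(m, m))
        return (A + A.T).tocsr()


@dataclass(frozen=True)
class StimulusSite:
    """A set of nodes stimulated together."""

    label: str
    nodes: np.ndarray
    onset_ms: float = 0.0
    amplitude: float = -150.0  # uA/uF (tissue patches need twice-threshold drive)
    duration_ms: float = 3.0

    def __post_init__(self):
        if np.asarray(self.nodes).size == 0:
            raise ConfigurationError(f"stimulus site {self.label!r} has no nodes")


# ---------------------------------------------------------------------------
# structured box meshing

# Freudenthal split of a hexahedron into six tetrahedra sharing the main
# diagonal; corner index = i + 2j + 4k over the unit cell
_HEX_TETS = np.array([
    [0, 1, 3, 7], [0, 3, 2, 7], [0, 2, 6, 7],
    [0, 6, 4, 7], [0, 4, 5, 7], [0, 5, 1, 7],
])


def _box_grid(ns, h, origin=(0.0, 0.0, 0.0)):
    nx, ny, nz = ns
    xs = origin[0] + np.arange(nx + 1) * h[0]
    ys = origin[1] + np.arange(ny + 1) * h[1]
    zs = origin[2] + np.arange(nz + 1) * h[2]
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    nodes = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])

    def nid(i, j, k):
        return (i * (ny + 1) + j) * (nz + 1) + k

    i, j, k = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij")
    i, j, k = i.ravel(), j.ravel(), k.ravel()
    corners = np.stack([nid(i + di, j + dj, k + dk)
                        for dk in (0, 1) for dj in (0, 1) for di in (0, 1)], axis=1)
    # corners column order is di + 2*dj + 4*dk as required by _HEX_TETS
    tets = corners[:, _HEX_TETS].reshape(-1, 4)
    return nodes, tets


def _orient_positive(nodes, tets):
    v = fem.tet_volumes(nodes, tets)
    neg = v < 0
    tets = tets.copy()
    tets[neg, 0], tets[neg, 1] = tets[neg, 1].copy(), tets[neg, 0].copy()
    return tets


def _compress(nodes, tets):
    used, inv = np.unique(tets, return_inverse=True)
    return nodes[used], inv.reshape(tets.shape), used


def make_cable(length_cm: float, dx_cm: float) -> Mesh:
    """Pseudo-1D tetrahedralized strand along x, one element across."""
    if dx_cm <= 0:
        raise ConfigurationError("dx must be positive")
    if length_cm < 20 * dx_cm:
        raise ConfigurationError("cable must span at least 20 elements")
    nx = int(round(length_cm / dx_cm))
    nodes, tets = _box_grid((nx, 1, 1), (length_cm / nx, dx_cm, dx_cm))
    tets = _orient_positive(nodes, tets)
    phi = nodes[:, 2] / dx_cm
    z = nodes[:, 0] / length_cm
    layer = np.digitize(phi, (0.3, 0.7))
    return Mesh(nodes, tets, np.full(tets.shape[0], MYOCARDIUM), phi, z, layer,
                metadata={"kind": "cable", "length_cm": length_cm, "dx_cm": dx_cm})


def make_slab(lx: float, ly: float, lz: float, dx: float) -> Mesh:
    """Axis-aligned slab; transmural coordinate runs along z, apicobasal along x."""
    if min(lx, ly, lz) <= 0 or dx <= 0:
        raise ConfigurationError("degenerate slab extents")
    ns = (max(1, int(round(lx / dx))), max(1, int(round(ly / dx))),
          max(1, int(round(lz / dx))))
    h = (lx / ns[0], ly / ns[1], lz / ns[2])
    nodes, tets = _box_grid(ns, h)
    tets = _orient_positive(nodes, tets)
    phi = nodes[:, 2] / lz
    z = nodes[:, 0] / lx
    layer = np.digitize(phi, (0.3, 0.7))
    return Mesh(nodes, tets, np.full(tets.shape[0], MYOCARDIUM), phi, z, layer,
                metadata={"kind": "slab", "extents": (lx, ly, lz), "dx_cm": dx})


# ---------------------------------------------------------------------------
# idealized biventricular pair

@dataclass(frozen=True)
class BiventricularConfig:
    """Truncated-ellipsoid two-cavity geometry parameters (cm).

    The left ventricle is an ellipsoid of revolution truncated at the base
    plane; the right ventricle is a thinner crescent wrapped around it.
    The detailed twin adds ``n_trabeculae`` endocardial ridges and
    ``n_false_tendons`` free-running bridges (>= ``ft_min_length``) until
    their volume reaches ``trabecular_fraction_target`` of the detailed
    myocardial volume.
    """

    lv_radius: float = 0.8
    lv_height: float = 1.5
    lv_wall: float = 0.28
    rv_center_x: float = 0.65
    rv_radius_x: float = 1.3
    rv_radius_y: float = 0.95
    rv_height: float = 1.32
    rv_wall: float = 0.2
    resolution: float = 0.075
    n_trabeculae: int = 18
    trabecular_fraction_target: float = 0.10
    n_false_tendons: int = 2
    ft_min_length: float = 1.0
    fast_endo_extent: float = 2.0 / 3.0  # apicobasal fraction carrying the fast layer
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.trabecular_fraction_target <= 0.25):
            raise ConfigurationError("trabecular_fraction_target must be in [0, 0.25]")
        if self.resolution <= 0:
            raise ConfigurationError("resolution must be positive")


def _ellipsoid(p, cx, a, b, hz, H):
    """Implicit value of an ellipsoid centered at (cx, 0, H); <= 1 inside."""
    return ((p[:, 0] - cx) / a) ** 2 + (p[:, 1] / b) ** 2 + ((p[:, 2] - H) / hz) ** 2


class _BivImplicit:
    """Implicit-geometry helper shared by masking and node classification."""

    def __init__(self, cfg: BiventricularConfig):
        self.cfg = cfg
        c = cfg
        self.lv_out = lambda p: _ellipsoid(p, 0.0, c.lv_radius, c.lv_radius,
                                           c.lv_height, c.lv_height)
        self.lv_cav = lambda p: _ellipsoid(p, 0.0, c.lv_radius - c.lv_wall,
                                           c.lv_radius - c.lv_wall,
                                           c.lv_height - c.lv_wall, c.lv_height)
        self.rv_out = lambda p: _ellipsoid(p, c.rv_center_x, c.rv_radius_x,
                                           c.rv_radius_y, c.rv_height, c.lv_height)
        self.rv_cav = lambda p: _ellipsoid(p, c.rv_center_x,
                                           c.rv_radius_x - c.rv_wall,
                                           c.rv_radius_y - c.rv_wall,
                                           c.rv_height - c.rv_wall, c.lv_height)

    def solid(self, p):
        lo, lc = self.lv_out(p) <= 1, self.lv_cav(p) <= 1
        ro, rc = self.rv_out(p) <= 1, self.rv_cav(p) <= 1
        return (lo & ~lc) | (ro & ~lo & ~rc)

    def in_lv_cavity(self, p):
        return self.lv_cav(p) <= 1

    def in_rv_cavity(self, p):
        return (self.rv_cav(p) <= 1) & (self.lv_out(p) > 1)

    def cavity_surface_point(self, chamber: str, theta: float, z_ab: float):
        """Point on a cavity endocardial surface at angle theta.

        ``z_ab`` is the fraction of the full apex-base height; it is
        clamped to the extent of the chamber's cavity.
        """
        c = self.cfg
        H = c.lv_height
        if chamber == "lv":
            a, b, hz = c.lv_radius - c.lv_wall, c.lv_radius - c.lv_wall, c.lv_height - c.lv_wall
            cx = 0.0
            zmin = H - hz
        else:
            a, b, hz = c.rv_radius_x - c.rv_wall, c.rv_radius_y - c.rv_wall, c.rv_height - c.rv_wall
            cx = c.rv_center_x
            zmin = H - hz
        zz = float(np.clip(z_ab * H, zmin + 0.02, H - 0.02))
        s = np.sqrt(max(0.0, 1.0 - ((zz - H) / hz) ** 2))
        return np.array([cx + a * s * np.cos(theta), b * s * np.sin(theta), zz])


def _trabecula_masks(imp, cents, rng, n_trab, depth, cavity="lv"):
    """Ridge mask plus per-ridge tangent axes; depth in implicit units."""
    c = imp.cfg
    if cavity == "lv":
        f = imp.lv_cav(cents)
        inside = imp.in_lv_cavity(cents)
        ang = np.arctan2(cents[:, 1], cents[:, 0])
    else:
        f = imp.rv_cav(cents)
        inside = imp.in_rv_cavity(cents)
        ang = np.arctan2(cents[:, 1], cents[:, 0] - c.rv_center_x)
    mask = np.zeros(cents.shape[0], dtype=bool)
    z = cents[:, 2]
    H = c.lv_height
    wscale = 0.6 + depth  # wider ridges as they deepen, so the achievable
    for _ in range(n_trab):  # trabecular fraction spans the observed range
        th = rng.uniform(-np.pi, np.pi)
        w = rng.uniform(0.15, 0.35) * wscale
        z0 = rng.uniform(0.05, 0.35) * H
        z1 = z0 + rng.uniform(0.4, 0.7) * H
        dth = np.abs((ang - th + np.pi) % (2 * np.pi) - np.pi)
        mask |= inside & (f >= 1.0 - depth) & (dth <= w) & (z >= z0) & (z <= z1)
    return mask


def _false_tendon_mask(imp, cents, rng, n_ft, radius, min_length):
    """Cylindrical chords spanning the LV cavity; returns mask and axes."""
    mask = np.zeros(cents.shape[0], dtype=bool)
    axes = []
    inside = imp.in_lv_cavity(cents)
    for _ in range(n_ft):
        for _attempt in range(50):
            th = rng.uniform(-np.pi, np.pi)
            za = rng.uniform(0.25, 0.5)
            zb = rng.uniform(0.5, 0.8)
            p0 = imp.cavity_surface_point("lv", th, za)
            p1 = imp.cavity_surface_point("lv", th + np.pi + rng.uniform(-0.5, 0.5), zb)
            if np.linalg.norm(p1 - p0) >= min_length:
                break
        d = p1 - p0
        L = np.linalg.norm(d)
        u = d / L
        rel = cents - p0
        t = rel @ u
        perp = np.linalg.norm(rel - np.outer(t, u), axis=1)
        seg = inside & (t >= -radius) & (t <= L + radius) & (perp <= radius)
        mask |= seg
        axes.append((seg, u))
    return mask, axes


def make_biventricular_pair(config: BiventricularConfig):
    """Build the (detailed, smoothed) mesh pair on a shared grid.

    Both meshes share the epicardial outline; the detailed twin adds
    trabecular ridges and false tendons whose volume is tuned by bisection
    on the ridge protrusion depth to hit the target trabecular fraction
    within two percentage points.
    """
    c = config
    h = c.resolution
    imp = _BivImplicit(c)
    pad = h
    x0 = -c.lv_radius - pad
    x1 = c.rv_center_x + c.rv_radius_x + pad
    y1 = max(c.lv_radius, c.rv_radius_y) + pad
    ns = (int(np.ceil((x1 - x0) / h)), int(np.ceil(2 * y1 / h)),
          int(np.ceil(c.lv_height / h)))
    nodes, tets = _box_grid(ns, (h, h, h), origin=(x0, -y1, 0.0))
    tets = _orient_positive(nodes, tets)
    cents = nodes[tets].mean(axis=1)

    solid = imp.solid(cents)
    rng = np.random.default_rng(c.seed)
    # draw the random ridge/bridge layout once so bisection only scales depth
    layout_seed = int(rng.integers(0, 2 ** 31 - 1))
    ft_radius = 1.2 * h

    def detail_masks(depth):
        r = np.random.default_rng(layout_seed)
        trab = _trabecula_masks(imp, cents, r, c.n_trabeculae, depth, "lv")
        trab |= _trabecula_masks(imp, cents, r, max(0, c.n_trabeculae // 2),
                                 depth * 0.8, "rv")
        if c.n_false_tendons > 0:
            ft, axes = _false_tendon_mask(imp, cents, r, c.n_false_tendons,
                                          ft_radius, c.ft_min_length)
        else:
            ft, axes = np.zeros(cents.shape[0], dtype=bool), []
        return trab & ~solid, ft & ~solid & ~trab, axes

    n_solid = int(solid.sum())
    target = c.trabecular_fraction_target

    def fraction(depth):
        trab, ft, _ = detail_masks(depth)
        n_extra = int(trab.sum() + ft.sum())
        return n_extra / max(1, n_solid + n_extra)

    if target == 0 and c.n_false_tendons == 0:
        depth = 0.0
    else:
        lo, hi = 0.0, 1.0
        if fraction(hi) < target - 0.02:
            raise GenerationError(
                f"cannot reach trabecular fraction {target:.3f}; max achievable "
                f"{fraction(hi):.3f} at this resolution")
        for _ in range(30):
            mid = 0.5 * (lo + hi)
            if fraction(mid) < target:
                lo = mid
            else:
                hi = mid
        depth = hi if abs(fraction(hi) - target) < abs(fraction(lo) - target) else lo
        if abs(fraction(depth) - target) > 0.02:
            raise GenerationError(
                f"achieved trabecular fraction {fraction(depth):.3f} not within "
                f"2 points of target {target:.3f}")

    trab, ft, ft_axes = detail_masks(depth)

    detailed = _finalize_biv(nodes, tets, solid | trab | ft, solid, trab, ft,
                             ft_axes, imp, c, detailed=True)
    smoothed = _finalize_biv(nodes, tets, solid, solid,
                             np.zeros_like(solid), np.zeros_like(solid), [],
                             imp, c, detailed=False)
    return detailed, smoothed


def _finalize_biv(nodes, tets, keep, solid, trab, ft, ft_axes, imp, cfg, detailed):
    kept = np.flatnonzero(keep)
    sub_nodes, sub_tets, used = _compress(nodes, tets[kept])
    region = np.full(kept.size, MYOCARDIUM)
    region[trab[kept]] = TRABECULA
    region[ft[kept]] = FALSE_TENDON

    # drop stray disconnected components (isolated masked cells)
    m = Mesh(sub_nodes, sub_tets, region,
             np.zeros(sub_nodes.shape[0]), np.zeros(sub_nodes.shape[0]),
             np.zeros(sub_nodes.shape[0], dtype=int))
    ncomp, comp = sp.csgraph.connected_components(m.element_adjacency())
    if ncomp > 1:
        main = np.argmax(np.bincount(comp))
        sel = comp == main
        kept = kept[sel]
        sub_nodes, sub_tets, used = _compress(nodes, tets[kept])
        region = region[sel]

    # transmural coordinate: Laplace endo=0 / epi=1
    mesh = Mesh(sub_nodes, sub_tets, region,
                np.zeros(sub_nodes.shape[0]), np.zeros(sub_nodes.shape[0]),
                np.zeros(sub_nodes.shape[0], dtype=int))
    bnodes = mesh.boundary_nodes()
    p = sub_nodes[bnodes]
    fcav = np.minimum(imp.lv_cav(p), np.where(imp.lv_out(p) > 1, imp.rv_cav(p), np.inf))
    fout = np.maximum(np.where(imp.lv_out(p) <= 1.3, imp.lv_out(p), -np.inf),
                      np.where(imp.rv_out(p) <= 1.3, imp.rv_out(p), -np.inf))
    tol = 2.5 * cfg.resolution / cfg.lv_radius
    endo = fcav <= 1.0 + tol
    epi = (~endo) & (fout >= 1.0 - tol)
    dir_nodes = np.concatenate([bnodes[endo], bnodes[epi]])
    dir_vals = np.concatenate([np.zeros(endo.sum()), np.ones(epi.sum())])
    phi = fem.laplace_solve(sub_nodes, sub_tets, dir_nodes, dir_vals)
    phi = np.clip(phi, 0.0, 1.0)

    # apicobasal coordinate: Laplace apex=0 / base=1
    zc = sub_nodes[:, 2]
    apex = np.flatnonzero(zc <= zc.min() + cfg.resolution)
    base = np.flatnonzero(zc >= cfg.lv_height - 0.5 * cfg.resolution)
    dn = np.concatenate([apex, base])
    dv = np.concatenate([np.zeros(apex.size), np.ones(base.size)])
    zab = np.clip(fem.laplace_solve(sub_nodes, sub_tets, dn, dv), 0.0, 1.0)

    layer = np.digitize(phi, (0.3, 0.7))

    # one-element fast-endocardial band over the apical two-thirds
    bfaces = mesh.boundary_faces()
    endo_node = np.zeros(sub_nodes.shape[0], dtype=bool)
    endo_node[bnodes[endo]] = True
    face_endo = endo_node[bfaces].all(axis=1)
    face_owner = _face_owners(sub_tets, bfaces)
    cand = np.unique(face_owner[face_endo])
    elem_zab = zab[sub_tets[cand]].mean(axis=1)
    fast = cand[(elem_zab < cfg.fast_endo_extent)]
    fast = fast[region[fast] == MYOCARDIUM]
    region = region.copy()
    region[fast] = FAST_ENDO

    axis = np.full((sub_nodes.shape[0], 3), np.nan)
    if detailed:
        # false-tendon long axes (per generator chord)
        lut = -np.ones(nodes.shape[0], dtype=int)
        lut[used] = np.arange(used.size)
        for seg_mask, u in ft_axes:
            segel = np.flatnonzero(seg_mask)
            for e in segel:
                for v in tets[e]:
                    if lut[v] >= 0:
                        axis[lut[v]] = u
        # trabecular ridges run apicobasally: unit tangent of the cavity wall
        trab_nodes = np.unique(sub_tets[np.isin(region, (TRABECULA,))])
        axis[trab_nodes] = (0.0, 0.0, 1.0)

    md = {"kind": "biventricular", "detailed": detailed, "config": cfg}
    return Mesh(sub_nodes, sub_tets, region, phi, zab, layer, axis, md)


def _face_owners(tets, faces):
    """Map each (boundary) face to the element owning it."""
    all_faces = np.vstack([tets[:, idx] for idx in
                           ((0, 1, 2), (0, 1, 3), (0, 2, 3), (1, 2, 3))])
    owner = np.tile(np.arange(tets.shape[0]), 4)
    nmax = int(all_faces.max()) + 1
    enc_all = (np.sort(all_faces, axis=1) * np.array([nmax * nmax, nmax, 1])).sum(axis=1)
    enc_q = (np.sort(faces, axis=1) * np.array([nmax * nmax, nmax, 1])).sum(axis=1)
    order = np.argsort(enc_all)
    idx = np.searchsorted(enc_all[order], enc_q)
    return owner[order][idx]


def trabecular_volume_pct(v_detailed_cm3: float, v_smoothed_cm3: float) -> float:
    """Percentage of the detailed myocardial volume occupied by sub-structures."""
    if v_smoothed_cm3 <= 0:
        raise ConfigurationError("volumes must be positive")
    if v_smoothed_cm3 > v_detailed_cm3:
        raise ConfigurationError("smoothed volume exceeds detailed volume")
    return 100.0 * (v_detailed_cm3 - v_smoothed_cm3) / v_detailed_cm3


def insert_scar(mesh: Mesh, center, radius_cm: float, border_width_cm: float,
                channel_width_cm: float = 0.0, channel_axis=(1.0, 0.0, 0.0)) -> Mesh:
    """Spherical transmural dense scar with a border-zone rim and channel.

    Elements within ``radius_cm`` of ``center`` become non-excitable dense
    scar; the surrounding ``border_width_cm`` shell becomes border zone; a
    corridor of ``channel_width_cm`` along ``channel_axis`` crosses the
    dense core as border-zone tissue (the reentry isthmus).
    """
    if radius_cm < 0 or border_width_cm < 0 or channel_width_cm < 0:
        raise ConfigurationError("scar dimensions must be non-negative")
    if channel_width_cm > 2 * radius_cm and radius_cm > 0:
        raise ConfigurationError("channel wider than the dense scar")
    if radius_cm == 0:
        return mesh
    center = np.asarray(center, dtype=float)
    axis = np.asarray(channel_axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    cents = mesh.centroids()
    rel = cents - center
    dist = np.linalg.norm(rel, axis=1)
    region = mesh.region.copy()
    core = dist <= radius_cm
    rim = (dist > radius_cm) & (dist <= radius_cm + border_width_cm)
    region[rim & np.isin(region, (MYOCARDIUM, FAST_ENDO))] = BORDER_ZONE
    region[core] = DENSE_SCAR
    if channel_width_cm > 0:
        t = rel @ axis
        perp = np.linalg.norm(rel - np.outer(t, axis), axis=1)
        corridor = core & (perp <= channel_width_cm / 2.0)
        region[corridor] = BORDER_ZONE
    out = replace(mesh, region=region)
    out.metadata = dict(mesh.metadata, scar={"center": tuple(center),
                                             "radius_cm": radius_cm,
                                             "border_width_cm": border_width_cm,
                                             "channel_width_cm": channel_width_cm})
    return out


def make_ridge_slab(lx: float = 1.2, ly: float = 0.6, wall: float = 0.3,
                    cavity: float = 0.2, ridge_radius: float = 0.12,
                    h: float = 0.04) -> Mesh:
    """Slab wall with one semi-cylindrical endocardial ridge (trabecula).

    A compact wall occupies ``cavity <= z <= cavity + wall``; a cylindrical
    ridge of the given radius runs along x at the endocardial surface,
    protruding into the cavity space below.  The transmural coordinate is
    a Laplace solve with the cavity-facing surface (including the ridge) at
    phi = 0, so the ridge interior has a vanishing transmural gradient —
    the trabecula-detection fixture.
    """
    lz = cavity + wall
    ns = (int(round(lx / h)), int(round(ly / h)), int(round(lz / h)))
    nodes, tets = _box_grid(ns, (lx / ns[0], ly / ns[1], lz / ns[2]))
    tets = _orient_positive(nodes, tets)
    cents = nodes[tets].mean(axis=1)
    solid = cents[:, 2] >= cavity
    yc, x0, x1 = ly / 2.0, 0.15 * lx, 0.85 * lx
    ridge = (np.hypot(cents[:, 1] - yc, cents[:, 2] - cavity) <= ridge_radius) \
        & (cents[:, 0] >= x0) & (cents[:, 0] <= x1) & (cents[:, 2] < cavity)
    keep = solid | ridge
    sub_nodes, sub_tets, used = _compress(nodes, tets[keep])
    region = np.full(int(keep.sum()), MYOCARDIUM)
    region[ridge[keep]] = TRABECULA

    mesh = Mesh(sub_nodes, sub_tets, region,
                np.zeros(sub_nodes.shape[0]), np.zeros(sub_nodes.shape[0]),
                np.zeros(sub_nodes.shape[0], dtype=int))
    b = mesh.boundary_nodes()
    zb = sub_nodes[b, 2]
    endo = b[zb <= cavity + 0.51 * h]
    epi = b[zb >= lz - 0.01 * h]
    phi = fem.laplace_solve(sub_nodes, sub_tets,
                            np.concatenate([endo, epi]),
                            np.concatenate([np.zeros(endo.size), np.ones(epi.size)]))
    phi = np.clip(phi, 0.0, 1.0)
    zab = sub_nodes[:, 0] / lx
    layer = np.digitize(phi, (0.3, 0.7))
    axis = np.full((sub_nodes.shape[0], 3), np.nan)
    ridge_nodes = np.unique(sub_tets[region == TRABECULA])
    axis[ridge_nodes] = (1.0, 0.0, 0.0)
    return Mesh(sub_nodes, sub_tets, region, phi, zab, layer, axis,
                metadata={"kind": "ridge_slab", "h": h})


# ---------------------------------------------------------------------------
# activation sites

#: (chamber, theta, apicobasal height) for the five sinus initial-activation
#: regions: two RV free-wall areas near the anterior papillary-muscle
#: insertion, the high anterior para-septal LV below the base, the central
#: left septal surface, and the posterior para-septal LV at one third of the
#: apex-base distance.
_IAR_SPEC = {
    "IAR1": ("rv", 0.55, 0.40),
    "IAR2": ("rv", -0.55, 0.55),
    "IAR3": ("lv", 1.05, 0.80),
    "IAR4": ("lv", 0.0, 0.50),
    "IAR5": ("lv", -1.05, 1.0 / 3.0),
}

_PACING_SPEC = {
    "LV_apex": ("lv", 0.0, 0.03),
    "RV_apex": ("rv", 0.0, 0.05),
    "RVOT": ("rv", 0.9, 0.92),
}


def _select_site(mesh: Mesh, imp: _BivImplicit, chamber, theta, z_ab,
                 radius, label, onset=0.0):
    target = imp.cavity_surface_point(chamber, theta, z_ab)
    bnodes = mesh.boundary_nodes()
    # all endocardial-surface nodes in the patch, including trabecular
    # surfaces: in a heavily structured cavity the fast-conducting
    # trabecular network must be driven directly for the patch to capture
    endo = bnodes[mesh.phi[bnodes] <= 0.05]
    d = np.linalg.norm(mesh.nodes[endo] - target, axis=1)
    sel = endo[d <= radius]
    if sel.size < 4:
        sel = endo[np.argsort(d)[:8]]
    return StimulusSite(label, np.sort(sel), onset_ms=onset)


def place_iars(mesh: Mesh, radius: float | None = None) -> list[StimulusSite]:
    """Five sinus initial-activation regions on the endocardium.

    Site coordinates are computed from the generator configuration, so the
    same physical locations are used for both members of a
    detailed/smoothed pair.
    """
    if mesh.metadata.get("kind") != "biventricular":
        raise ConfigurationError("initial-activation regions require a biventricular mesh")
    cfg = mesh.metadata["config"]
    imp = _BivImplicit(cfg)
    radius = radius if radius is not None else 0.25
    sites = []
    taken = np.zeros(mesh.n_nodes, dtype=bool)
    for label, (ch, th, za) in _IAR_SPEC.items():
        s = _select_site(mesh, imp, ch, th, za, radius, label)
        nodes = s.nodes[~taken[s.nodes]]
        if nodes.size == 0:
            nodes = s.nodes
        taken[nodes] = True
        sites.append(StimulusSite(label, nodes, s.onset_ms))
    return sites


def place_pacing_site(mesh: Mesh, label: str, radius: float | None = None) -> StimulusSite:
    """One of the programmed-stimulation pacing sites (LV/RV apex, RVOT)."""
    if label not in _PACING_SPEC:
        raise ConfigurationError(f"unknown pacing site {label!r}")
    if mesh.metadata.get("kind") != "biventricular":
        raise ConfigurationError("pacing sites require a biventricular mesh")
    cfg = mesh.metadata["config"]
    imp = _BivImplicit(cfg)
    radius = radius if radius is not None else 0.25
    ch, th, za = _PACING_SPEC[label]
    return _select_site(mesh, imp, ch, th, za, radius, label)
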