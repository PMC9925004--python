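"""Linear tetrahedral finite-element primitives.

P1 elements with exact constant gradients per tetrahedron, used both for
the Laplace solves that define the transmural/apicobasal coordinates and
for the anisotropic diffusion operator of the monodomain solver.
"""

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla


def tet_volumes(nodes: np.ndarray, tets: np.ndarray) -> np.ndarray:
    """Signed volumes (cm^3) of each tetrahedron."""
    a = nodes[tets[:, 1]] - nodes[tets[:, 0]]
    b = nodes[tets[:, 2]] - nodes[tets[:, 0]]
    c = nodes[tets[:, 3]] - nodes[tets[:, 0]]
    return np.einsum("ij,ij->i", np.cross(a, b), c) / 6.0


def shape_gradients(nodes: np.ndarray, tets: np.ndarray):
    """Constant P1 shape-function gradients.

    Returns ``(grads, vols)`` with ``grads`` of shape (m, 4, 3): the
    gradient of the barycentric shape function of each local vertex.
    """
    m = tets.shape[0]
    v0 = nodes[tets[:, 0]]
    J = np.stack([nodes[tets[:, i]] - v0 for i in (1, 2, 3)], axis=1)  # (m,3,3)
    vols = np.linalg.det(J) / 6.0
    Jinv = np.linalg.inv(J)  # rows of Jinv.T are grads of local 1..3
    g = np.transpose(Jinv, (0, 2, 1))  # (m, 3, 3): g[:, i-1] = grad N_i
    grads = np.empty((m, 4, 3))
    grads[:, 1:, :] = g
    grads[:, 0, :] = -g.sum(axis=1)
    return grads, vols


def element_gradient(grads: np.ndarray, tets: np.ndarray, u: np.ndarray) -> np.ndarray:
    """Gradient of a nodal scalar field on each element, shape (m, 3)."""
    return np.einsum("maj,ma->mj", grads, u[tets])


def node_average(nodes_count: int, tets: np.ndarray, vols: np.ndarray,
                 elem_field: np.ndarray) -> np.ndarray:
    """Volume-weighted average of an element field onto nodes."""
    w = np.zeros(nodes_count)
    if elem_field.ndim == 1:
        acc = np.zeros(nodes_count)
        for a in range(4):
            np.add.at(acc, tets[:, a], vols * elem_field)
            np.add.at(w, tets[:, a], vols)
        return acc / np.maximum(w, 1e-300)
    acc = np.zeros((nodes_count, elem_field.shape[1]))
    for a in range(4):
        np.add.at(acc, tets[:, a], vols[:, None] * elem_field)
        np.add.at(w, tets[:, a], vols)
    return acc / np.maximum(w, 1e-300)[:, None]


def assemble_stiffness(nodes: np.ndarray, tets: np.ndarray,
                       tensors: np.ndarray | None = None) -> sp.csr_matrix:
    """Assemble K[a,b] = sum_e vol_e * grad N_a . D_e grad N_b.

    ``tensors``: (m, 3, 3) per-element diffusion tensors; identity if None.
    The operator is symmetric positive-semidefinite with zero row sums
    (pure Neumann / zero-flux boundaries).
    """
    grads, vols = shape_gradients(nodes, tets)
    if np.any(vols <= 0):
        raise ValueError("tetrahedra with non-positive volume")
    if tensors is None:
        dg = grads
    else:
        dg = np.einsum("mij,maj->mai", tensors, grads)
    ke = np.einsum("mai,mbi->mab", grads, dg) * vols[:, None, None]
    m = tets.shape[0]
    rows = np.repeat(tets, 4, axis=1).reshape(m, 16)
    cols = np.tile(tets, (1, 4)).reshape(m, 16)
    K = sp.coo_matrix((ke.reshape(m, 16).ravel(),
                       (rows.ravel(), cols.ravel())),
                      shape=(nodes.shape[0], nodes.shape[0]))
    return K.tocsr()


def lumped_mass(nodes: np.ndarray, tets: np.ndarray) -> np.ndarray:
    """Row-sum lumped mass vector: a quarter of each element volume per vertex."""
    vols = tet_volumes(nodes, tets)
    m = np.zeros(nodes.shape[0])
    for a in range(4):
        np.add.at(m, tets[:, a], vols / 4.0)
    return m


def laplace_solve(nodes: np.ndarray, tets: np.ndarray,
                  dirichlet_nodes: np.ndarray, dirichlet_values: np.ndarray) -> np.ndarray:
    """Solve Laplace's equation with Dirichlet data and natural BCs elsewhere."""
    n = nodes.shape[0]
    K = assemble_stiffness(nodes, tets).tolil()
    f = np.zeros(n)
    u = np.zeros(n)
    u[dirichlet_nodes] = dirichlet_values
    f -= K.tocsr() @ u
    fixed = np.zeros(n, dtype=bool)
    fixed[dirichlet_nodes] = True
    free = ~fixed
    Kc = K.tocsr()
    Kff = Kc[free][:, free]
    sol = spla.spsolve(Kff.tocsc(), f[free])
    u[free] = sol
    return u
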