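"""Static linear-elastic finite elements on the seta mesh.

Small-strain isotropic elasticity, sigma = lambda tr(eps) I + 2 mu eps,
assembled over linear (4-node) or quadratic (10-node, straight-edged)
tetrahedra.  Units: lengths nm, moduli GPa = nN/nm^2, hence stiffness
entries nN/nm and forces nN.

The driver nodes on the top truncation plane carry Dirichlet conditions
(prescribed Y displacement, X and Z fixed).  The bridging-domain nodes carry
Neumann loads (time-averaged anchor-point forces) plus diagonal penalty
springs of stiffness k_FE that anchor each BD node to its position at the
start of the current solve, so the springs restrain per-iteration increments:

    (K + K_FE) u_new = f_ext + K_FE u_prev.

The reduced operator is constant over a run and factorised once.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .geometry import SetaMesh, tet_volumes
from .material import ElasticParams

# 4-point Gauss rule on the reference tet (barycentric), degree 2
_TET4_QP = np.array(
    [
        [0.5854101966249685, 0.1381966011250105, 0.1381966011250105, 0.1381966011250105],
        [0.1381966011250105, 0.5854101966249685, 0.1381966011250105, 0.1381966011250105],
        [0.1381966011250105, 0.1381966011250105, 0.5854101966249685, 0.1381966011250105],
        [0.1381966011250105, 0.1381966011250105, 0.1381966011250105, 0.5854101966249685],
    ]
)


def _elasticity_matrix(params: ElasticParams) -> np.ndarray:
    """6x6 Voigt stiffness (order xx, yy, zz, xy, yz, zx; engineering shear)."""
    lam, mu = params.lam, params.mu
    D = np.zeros((6, 6))
    D[:3, :3] = lam
    D[np.arange(3), np.arange(3)] += 2 * mu
    D[3:, 3:] = np.eye(3) * mu
    return D


def _grad_barycentric(nodes: np.ndarray, corners: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Gradients of the 4 barycentric coordinates per element and volumes."""
    x = nodes[corners]  # (ne, 4, 3)
    vols = tet_volumes(nodes, corners)
    if np.any(vols <= 0):
        bad = np.nonzero(vols <= 0)[0]
        raise ValueError(f"inverted element Jacobian in elements {bad[:10].tolist()}")
    # gradL solves [x1-x0; x2-x0; x3-x0]^T gradL_i = e_i for i=1..3
    J = x[:, 1:] - x[:, :1]  # (ne, 3, 3) rows are edge vectors
    Jinv = np.linalg.inv(J)  # (ne, 3, 3); gradL_i = Jinv[:, :, i-1]
    gradL = np.empty((len(corners), 4, 3))
    gradL[:, 1:] = np.transpose(Jinv, (0, 2, 1))
    gradL[:, 0] = -gradL[:, 1:].sum(axis=1)
    return gradL, vols


def _strain_B(gradN: np.ndarray) -> np.ndarray:
    """Voigt B matrix (ne, 6, 3*nn) from shape gradients (ne, nn, 3)."""
    ne, nn, _ = gradN.shape
    B = np.zeros((ne, 6, 3 * nn))
    gx, gy, gz = gradN[..., 0], gradN[..., 1], gradN[..., 2]
    idx = np.arange(nn)
    B[:, 0, 3 * idx + 0] = gx
    B[:, 1, 3 * idx + 1] = gy
    B[:, 2, 3 * idx + 2] = gz
    B[:, 3, 3 * idx + 0] = gy
    B[:, 3, 3 * idx + 1] = gx
    B[:, 4, 3 * idx + 1] = gz
    B[:, 4, 3 * idx + 2] = gy
    B[:, 5, 3 * idx + 0] = gz
    B[:, 5, 3 * idx + 2] = gx
    return B


def assemble_stiffness(mesh: SetaMesh, params: ElasticParams) -> sp.csr_matrix:
    """Global stiffness matrix (nN/nm), 3 dofs per node."""
    D = _elasticity_matrix(params)
    corners = mesh.corner_tets()
    gradL, vols = _grad_barycentric(mesh.nodes, corners)
    ne = len(corners)

    if mesh.order == 1:
        B = _strain_B(gradL)  # constant strain
        Ke = np.einsum("eia,ij,ejb->eab", B, D, B) * vols[:, None, None]
        conn = corners
    else:
        conn = mesh.tets
        nn = 10
        Ke = np.zeros((ne, 3 * nn, 3 * nn))
        for qp in _TET4_QP:
            # dN/dL for quadratic tet shape functions at this point
            gradN = np.zeros((ne, nn, 3))
            for c in range(4):
                gradN[:, c] = (4 * qp[c] - 1) * gradL[:, c]
            edge_pairs = [(0, 1), (1, 2), (2, 0), (0, 3), (1, 3), (2, 3)]
            for m, (a, b) in enumerate(edge_pairs):
                gradN[:, 4 + m] = 4 * (qp[a] * gradL[:, b] + qp[b] * gradL[:, a])
            B = _strain_B(gradN)
            Ke += np.einsum("eia,ij,ejb->eab", B, D, B) * (vols[:, None, None] / 4.0)

    ndof_el = Ke.shape[1]
    dof = (3 * conn[:, :, None] + np.arange(3)).reshape(ne, ndof_el)
    rows = np.repeat(dof, ndof_el, axis=1).ravel()
    cols = np.tile(dof, (1, ndof_el)).ravel()
    n = 3 * mesh.n_nodes
    K = sp.coo_matrix((Ke.ravel(), (rows, cols)), shape=(n, n)).tocsr()
    return K


@dataclass
class FEMSystem:
    """Assembled seta shaft with driver constraints and BD penalty springs."""

    mesh: SetaMesh
    params: ElasticParams
    k_FE: float  # penalty spring stiffness, nN/nm per BD dof
    K: sp.csr_matrix = field(repr=False, default=None)
    KFE_diag: np.ndarray = field(repr=False, default=None)
    fixed: np.ndarray = field(repr=False, default=None)  # bool mask on dofs
    _solve: object = field(repr=False, default=None)

    @classmethod
    def build(cls, mesh: SetaMesh, params: ElasticParams, k_FE: float) -> "FEMSystem":
        K = assemble_stiffness(mesh, params)
        n = 3 * mesh.n_nodes
        kfe = np.zeros(n)
        for idx in mesh.bd_nodes:
            dofs = (3 * idx[:, None] + np.arange(3)).ravel()
            kfe[dofs] = k_FE
        fixed = np.zeros(n, dtype=bool)
        ddofs = (3 * mesh.driver_nodes[:, None] + np.arange(3)).ravel()
        fixed[ddofs] = True
        sys = cls(mesh=mesh, params=params, k_FE=k_FE, K=K, KFE_diag=kfe, fixed=fixed)
        A = (K + sp.diags(kfe)).tocsc()
        free = ~fixed
        sys._Aff = A[free][:, free].tocsc()
        sys._Afc = A[free][:, fixed].tocsc()
        sys._free = free
        if k_FE <= 0 and not fixed.any():
            raise ValueError("singular system: no constraints and k_FE = 0")
        sys._solve = spla.factorized(sys._Aff)
        return sys

    def solve_static(
        self,
        u_driver: np.ndarray,
        U_prev: np.ndarray | None = None,
        loads: np.ndarray | None = None,
    ) -> tuple[np.ndarray, np.ndarray]:
        """Solve (K + K_FE) u = f_ext + K_FE u_prev with prescribed driver
        displacements.

        Parameters
        ----------
        u_driver : (3,) or (n_driver, 3) prescribed total driver displacement.
        U_prev : (n_nodes, 3) displacement at the start of this iteration
            (penalty reference); zeros if None.
        loads : (n_nodes, 3) external nodal forces in nN (anchor-point loads
            on the BD nodes); zeros if None.

        Returns
        -------
        U : (n_nodes, 3) total nodal displacement.
        reactions : (n_driver, 3) constraint forces exerted on the mesh at
            the driver nodes (nN).
        """
        n = 3 * self.mesh.n_nodes
        f = np.zeros(n) if loads is None else np.asarray(loads, float).ravel().copy()
        up = np.zeros(n) if U_prev is None else np.asarray(U_prev, float).ravel()
        rhs = f + self.KFE_diag * up

        u = np.zeros(n)
        ud = np.broadcast_to(np.asarray(u_driver, float),
                             (len(self.mesh.driver_nodes), 3))
        u[self.fixed] = ud.ravel()
        b = rhs[self._free] - self._Afc @ u[self.fixed]
        u[self._free] = self._solve(b)

        A_u = self.K @ u + self.KFE_diag * u
        residual = A_u - rhs
        reactions = residual[self.fixed].reshape(-1, 3)
        return u.reshape(-1, 3), reactions


def driver_reaction(reactions: np.ndarray) -> np.ndarray:
    """Total constraint force on the driver cross-section (nN)."""
    return reactions.sum(axis=0)


def driver_force_reported(reactions: np.ndarray) -> float:
    """Driver force with the run convention: compression (preload) positive,
    tension (adhesion) negative; the negative Y sum of constraint forces."""
    return -float(reactions[:, 1].sum())
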