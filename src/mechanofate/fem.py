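"""Linear-elastic substrate on a regular hexahedral grid.

The substrate is a box meshed by 8-node trilinear hexahedra (2x2x2 Gauss
quadrature).  All boundary surfaces are traction-free; the six rigid-body
modes are suppressed by a 3-2-1 corner constraint so the stiffness operator
can be factorised once per scenario and reused for every sensing solve.

Units: geometry in micrometres, stress in kPa, force in nN (kPa*um^2 = nN).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import splu


class OutOfDomainError(ValueError):
    """A queried point or load lies outside the substrate box."""


class InvalidConfigError(ValueError):
    """Mesh or material parameters violate their preconditions."""


# Local node coordinates of the reference hexahedron, VTK ordering:
# bottom face counter-clockwise, then top face.
_XI_NODES = np.array(
    [
        [-1.0, -1.0, -1.0],
        [+1.0, -1.0, -1.0],
        [+1.0, +1.0, -1.0],
        [-1.0, +1.0, -1.0],
        [-1.0, -1.0, +1.0],
        [+1.0, -1.0, +1.0],
        [+1.0, +1.0, +1.0],
        [-1.0, +1.0, +1.0],
    ]
)


@dataclass(frozen=True)
class MaterialProps:
    """Isotropic substrate material.

    E : Young's modulus (kPa); nu : Poisson ratio; eta : viscosity (Pa*s),
    used only by the Stokes drag of the migration module.
    """

    E: float
    nu: float = 0.3
    eta: float = 1000.0

    def __post_init__(self) -> None:
        if not self.E > 0:
            raise InvalidConfigError(f"Young's modulus must be positive, got {self.E}")
        if not (0.0 <= self.nu < 0.5):
            raise InvalidConfigError(f"Poisson ratio must lie in [0, 0.5), got {self.nu}")
        if not self.eta > 0:
            raise InvalidConfigError(f"viscosity must be positive, got {self.eta}")


@dataclass(frozen=True)
class SubstrateMesh:
    """Regular grid of 8-node hexahedra covering ``[0,Lx]x[0,Ly]x[0,Lz]``.

    Node (ix, iy, iz) has index ``ix + iy*(nx+1) + iz*(nx+1)*(ny+1)``
    (x fastest).  Element connectivity follows the VTK hexahedron
    convention.
    """

    node_coords: np.ndarray  # (n_nodes, 3) um
    hex_connectivity: np.ndarray  # (n_elems, 8) int
    dims: tuple[float, float, float]
    n_div: tuple[int, int, int]

    @property
    def n_nodes(self) -> int:
        return self.node_coords.shape[0]

    @property
    def n_elems(self) -> int:
        return self.hex_connectivity.shape[0]

    @property
    def spacing(self) -> np.ndarray:
        return np.asarray(self.dims, dtype=float) / np.asarray(self.n_div, dtype=float)

    def contains(self, points: np.ndarray, tol: float = 1e-9) -> np.ndarray:
        p = np.atleast_2d(points)
        lo = p >= -tol
        hi = p <= np.asarray(self.dims) + tol
        return (lo & hi).all(axis=1)

    def locate(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Containing element index and local coordinates in [-1,1]^3.

        Raises OutOfDomainError if any point lies outside the box.
        """
        p = np.atleast_2d(np.asarray(points, dtype=float))
        if not self.contains(p).all():
            bad = p[~self.contains(p)][0]
            raise OutOfDomainError(f"point {bad} outside substrate box {self.dims}")
        h = self.spacing
        nd = np.asarray(self.n_div)
        idx = np.clip((p // h).astype(int), 0, nd - 1)
        elem = idx[:, 0] + idx[:, 1] * nd[0] + idx[:, 2] * nd[0] * nd[1]
        # local coordinate in [-1, 1] within the containing element
        xi = 2.0 * (p - idx * h) / h - 1.0
        return elem, np.clip(xi, -1.0, 1.0)


def build_hex_mesh(
    dims: tuple[float, float, float], n_div: tuple[int, int, int]
) -> SubstrateMesh:
    """Mesh a box by a regular grid of hexahedra.

    The default simulation domain, 400x200x200 um divided 40x20x20, yields
    16,000 elements and 18,081 nodes.
    """
    dims = tuple(float(d) for d in dims)
    n_div = tuple(int(n) for n in n_div)
    if any(d <= 0 for d in dims) or any(n <= 0 for n in n_div):
        raise InvalidConfigError(f"dims and n_div must be positive, got {dims}, {n_div}")
    nx, ny, nz = n_div
    xs = np.linspace(0.0, dims[0], nx + 1)
    ys = np.linspace(0.0, dims[1], ny + 1)
    zs = np.linspace(0.0, dims[2], nz + 1)
    Z, Y, X = np.meshgrid(zs, ys, xs, indexing="ij")
    coords = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])

    def nid(ix, iy, iz):
        return ix + iy * (nx + 1) + iz * (nx + 1) * (ny + 1)

    iz, iy, ix = np.meshgrid(np.arange(nz), np.arange(ny), np.arange(nx), indexing="ij")
    ix, iy, iz = ix.ravel(), iy.ravel(), iz.ravel()
    conn = np.column_stack(
        [
            nid(ix, iy, iz),
            nid(ix + 1, iy, iz),
            nid(ix + 1, iy + 1, iz),
            nid(ix, iy + 1, iz),
            nid(ix, iy, iz + 1),
            nid(ix + 1, iy, iz + 1),
            nid(ix + 1, iy + 1, iz + 1),
            nid(ix, iy + 1, iz + 1),
        ]
    )
    return SubstrateMesh(coords, conn.astype(np.int64), dims, n_div)


def shape_functions(xi: np.ndarray) -> np.ndarray:
    """Trilinear shape functions N_a(xi) for points xi of shape (..., 3)."""
    xi = np.asarray(xi, dtype=float)
    g = _XI_NODES  # (8, 3)
    return 0.125 * np.prod(1.0 + xi[..., None, :] * g, axis=-1)


def shape_gradients(xi: np.ndarray) -> np.ndarray:
    """dN_a/dxi at points xi: shape (..., 8, 3)."""
    xi = np.asarray(xi, dtype=float)
    g = _XI_NODES
    one = 1.0 + xi[..., None, :] * g  # (..., 8, 3)
    grad = np.empty(xi.shape[:-1] + (8, 3))
    grad[..., 0] = 0.125 * g[:, 0] * one[..., 1] * one[..., 2]
    grad[..., 1] = 0.125 * g[:, 1] * one[..., 0] * one[..., 2]
    grad[..., 2] = 0.125 * g[:, 2] * one[..., 0] * one[..., 1]
    return grad


def _elasticity_matrix(E: float, nu: float) -> np.ndarray:
    """6x6 isotropic stiffness in Voigt order (xx, yy, zz, xy, yz, zx)."""
    lam = E * nu / ((1 + nu) * (1 - 2 * nu))
    mu = E / (2 * (1 + nu))
    D = np.zeros((6, 6))
    D[:3, :3] = lam
    D[np.arange(3), np.arange(3)] += 2 * mu
    D[3:, 3:] = mu * np.eye(3)
    return D


def element_stiffness(h: np.ndarray, E: float, nu: float) -> np.ndarray:
    """24x24 stiffness of one regular hexahedron with edge lengths h.

    2x2x2 Gauss quadrature; exact for the regular (affine) geometry.
    DOF order: (node0 ux uy uz, node1 ux uy uz, ...).
    """
    D = _elasticity_matrix(E, nu)
    gp = np.array([-1.0, 1.0]) / np.sqrt(3.0)
    J = np.diag(np.asarray(h, dtype=float) / 2.0)
    detJ = np.prod(h) / 8.0
    Jinv = np.linalg.inv(J)
    ke = np.zeros((24, 24))
    for a in gp:
        for b in gp:
            for c in gp:
                dN = shape_gradients(np.array([a, b, c])) @ Jinv.T  # (8,3) d/dx
                B = np.zeros((6, 24))
                for n in range(8):
                    dx, dy, dz = dN[n]
                    B[0, 3 * n] = dx
                    B[1, 3 * n + 1] = dy
                    B[2, 3 * n + 2] = dz
                    B[3, 3 * n] = dy
                    B[3, 3 * n + 1] = dx
                    B[4, 3 * n + 1] = dz
                    B[4, 3 * n + 2] = dy
                    B[5, 3 * n] = dz
                    B[5, 3 * n + 2] = dx
                ke += B.T @ D @ B * detJ
    return 0.5 * (ke + ke.T)  # exact symmetry (kills accumulation roundoff)


def assemble_stiffness(mesh: SubstrateMesh, mat: MaterialProps) -> sparse.csc_matrix:
    """Global stiffness (unconstrained, symmetric PSD with 6 rigid modes)."""
    ke = element_stiffness(mesh.spacing, mat.E, mat.nu)
    conn = mesh.hex_connectivity
    edofs = (3 * conn[:, :, None] + np.arange(3)[None, None, :]).reshape(
        mesh.n_elems, 24
    )
    rows = np.repeat(edofs, 24, axis=1).ravel()
    cols = np.tile(edofs, (1, 24)).ravel()
    data = np.broadcast_to(ke.ravel(), (mesh.n_elems, 576)).ravel()
    n = 3 * mesh.n_nodes
    K = sparse.coo_matrix((data, (rows, cols)), shape=(n, n)).tocsc()
    K.sum_duplicates()
    # summation order differs between (i,j) and (j,i) duplicates; restore
    # exact symmetry of the elasticity operator
    return ((K + K.T) * 0.5).tocsc()


def _constraint_dofs(mesh: SubstrateMesh) -> np.ndarray:
    """3-2-1 rigid-body constraints.

    All three components at the origin corner, the two transverse
    components at the (Lx,0,0) corner, and the z component at the
    (0,Ly,0) corner.  Self-equilibrated sensing load sets make the
    solution insensitive to this choice.
    """
    nx, ny, _ = mesh.n_div
    n0 = 0
    n1 = nx
    n2 = ny * (nx + 1)
    return np.array(
        [3 * n0, 3 * n0 + 1, 3 * n0 + 2, 3 * n1 + 1, 3 * n1 + 2, 3 * n2 + 2]
    )


@dataclass
class FEOperator:
    """Factorised, rigid-body-constrained stiffness with point-load helpers."""

    mesh: SubstrateMesh
    mat: MaterialProps
    constrained_dofs: np.ndarray
    _free: np.ndarray = field(repr=False)
    _lu: object = field(repr=False)

    def point_load_vector(
        self, points: np.ndarray, forces: np.ndarray
    ) -> np.ndarray:
        """Consistent nodal force vector for point loads.

        Each load is spread to its containing element's 8 nodes by the
        trilinear shape-function values at the load point.
        """
        points = np.atleast_2d(np.asarray(points, dtype=float))
        forces = np.atleast_2d(np.asarray(forces, dtype=float))
        elem, xi = self.mesh.locate(points)
        N = shape_functions(xi)  # (npts, 8)
        conn = self.mesh.hex_connectivity[elem]  # (npts, 8)
        f = np.zeros(3 * self.mesh.n_nodes)
        contrib = N[:, :, None] * forces[:, None, :]  # (npts, 8, 3)
        dofs = 3 * conn[:, :, None] + np.arange(3)[None, None, :]
        np.add.at(f, dofs.ravel(), contrib.ravel())
        return f

    def solve(self, rhs: np.ndarray) -> np.ndarray:
        """Displacements (n_nodes, 3) [or (n_nodes, 3, k)] for nodal RHS."""
        rhs = np.asarray(rhs, dtype=float)
        single = rhs.ndim == 1
        rhs = rhs.reshape(3 * self.mesh.n_nodes, -1)
        x = np.zeros_like(rhs)
        x[self._free] = self._lu.solve(rhs[self._free])
        out = x.reshape(self.mesh.n_nodes, 3, -1)
        return out[..., 0] if single else out


def assemble_operator(mesh: SubstrateMesh, mat: MaterialProps) -> FEOperator:
    """Assemble, constrain and factorise the substrate stiffness."""
    K = assemble_stiffness(mesh, mat)
    fixed = _constraint_dofs(mesh)
    free = np.setdiff1d(np.arange(K.shape[0]), fixed)
    Kff = K[free][:, free].tocsc()
    try:
        lu = splu(Kff, permc_spec="MMD_AT_PLUS_A")
    except RuntimeError as exc:  # pragma: no cover - defensive
        raise InvalidConfigError(f"stiffness factorisation failed: {exc}") from exc
    return FEOperator(mesh=mesh, mat=mat, constrained_dofs=fixed, _free=free, _lu=lu)


def solve_displacements(
    op: FEOperator, points: np.ndarray, forces: np.ndarray
) -> np.ndarray:
    """Displacement field (n_nodes, 3) um under point forces (nN)."""
    return op.solve(op.point_load_vector(points, forces))


def strain_at_points(
    mesh: SubstrateMesh, disp: np.ndarray, points: np.ndarray
) -> np.ndarray:
    """Small-strain tensors (npts, 3, 3) at arbitrary points.

    Strains come from the trilinear shape-function gradients of the
    containing element evaluated at the point's local coordinates, so an
    affine displacement field is reproduced exactly.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    elem, xi = mesh.locate(points)
    Jinv = np.diag(2.0 / mesh.spacing)
    dN = shape_gradients(xi) @ Jinv.T  # (npts, 8, 3) d/dx
    u_e = disp[mesh.hex_connectivity[elem]]  # (npts, 8, 3)
    grad = np.einsum("pnj,pni->pij", dN, u_e)  # du_i/dx_j
    return 0.5 * (grad + np.swapaxes(grad, 1, 2))


def strain_at_point(mesh: SubstrateMesh, disp: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Symmetric 3x3 small-strain tensor at a single point."""
    return strain_at_points(mesh, disp, np.atleast_2d(p))[0]
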