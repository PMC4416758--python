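"""Single-cell mechano-sensing, traction generation and migration kinematics.

The cell is a rigid sphere of radius ``r_cell`` with ``n_mem`` membrane
nodes.  Each step it (i) pulls every membrane node toward its centroid with
a stress given by the actin-myosin/microtubule law, reads back the substrate
deformation (mechano-sensing), (ii) converts the sensed internal strain into
nodal traction forces weighted by front/back adhesivity, (iii) adds a random
protrusion force and (iv) moves by Stokes drag force balance.

Sign convention: the stored per-node internal strain ``eps_i`` (the ratio
MN/OM of the node's inward displacement to the cell radius) is positive
under contraction; the 1-D stress law is evaluated on the signed axial
strain ``-eps_i`` (compression negative).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .fem import FEOperator, MaterialProps, shape_functions, strain_at_points

MSC = "MSC"
OSTEOBLAST = "osteoblast"
CHONDROCYTE = "chondrocyte"
NEUROBLAST = "neuroblast"
PHENOTYPES = (MSC, OSTEOBLAST, CHONDROCYTE, NEUROBLAST)

#: conversion: eta [Pa*s] * r [um] -> nN*s/um  (1 Pa = 1e-3 kPa, kPa*um^2 = nN)
_PA_S_TO_NN = 1e-3
_SECONDS_PER_HOUR = 3600.0


@dataclass(frozen=True)
class MechanicalParams:
    """Cell mechanical constants (defaults are the model's standard set).

    Stresses in kPa, lengths in um, time step ``tau`` in hours.  ``k_f``,
    ``k_b`` (1/mol), ``n_rf``, ``n_rb`` (receptor counts) and ``psi`` (mol)
    enter only through the dimensionless adhesivity zeta = k*n_r*psi.
    """

    K_pas: float = 2.8
    K_act: float = 2.0
    eps_min: float = -0.9
    eps_max: float = 0.9
    sigma_max: float = 0.1
    k_f: float = 1e8
    k_b: float = 1e8
    n_rf: float = 1.5e5
    n_rb: float = 1e5
    psi: float = 1e-5
    r_cell: float = 20.0
    n_mem: int = 24
    tau: float = 6.0

    def __post_init__(self) -> None:
        if not (self.eps_min < 0.0 < self.sigma_max / self.K_act < self.eps_max):
            raise ValueError("require eps_min < 0 < sigma_max/K_act < eps_max")
        if not self.r_cell > 0:
            raise ValueError("r_cell must be positive")
        if self.n_mem < 4:
            raise ValueError("need at least 4 membrane nodes")

    @property
    def eps_tilde(self) -> float:
        """Strain at peak active stress, sigma_max / K_act."""
        return self.sigma_max / self.K_act

    @property
    def S_node(self) -> float:
        """Membrane area carried by one node, 4*pi*r^2 / n_mem (um^2)."""
        return 4.0 * np.pi * self.r_cell**2 / self.n_mem

    @property
    def zeta_front(self) -> float:
        return adhesivity(self.k_f, self.n_rf, self.psi)

    @property
    def zeta_back(self) -> float:
        return adhesivity(self.k_b, self.n_rb, self.psi)


def _rhombicuboctahedron() -> np.ndarray:
    """24 vertices of a rhombicuboctahedron, normalised.

    Centrosymmetric (sum is exactly zero), minimum pairwise angle ~41.9 deg
    and covering radius ~30.3 deg — small enough that two touching cells
    always share between 1 and 4 "common" nodes under the default contact
    tolerance of the population module.
    """
    a = 1.0 + np.sqrt(2.0)
    pts = []
    for perm in [(0, 1, 2), (0, 2, 1), (2, 0, 1)]:
        for sx in (1.0, -1.0):
            for sy in (1.0, -1.0):
                for sz in (1.0, -1.0):
                    pts.append(np.array([1.0, 1.0, a])[list(perm)] * [sx, sy, sz])
    pts = np.unique(np.round(np.array(pts), 12), axis=0)
    return pts / np.linalg.norm(pts, axis=1, keepdims=True)


def _fibonacci_sphere(n: int) -> np.ndarray:
    i = np.arange(n) + 0.5
    phi = np.pi * (1.0 + np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    rho = np.sqrt(1.0 - z * z)
    return np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])


def membrane_template(n_mem: int) -> np.ndarray:
    """Deterministic well-spread outward unit vectors for the membrane nodes.

    24 nodes (the default) use the rhombicuboctahedron vertices (sum is
    exactly zero); 6 nodes use the octahedron; other even counts use
    antipodal Fibonacci pairs (sum exactly zero); odd counts fall back to
    a plain Fibonacci lattice.
    """
    if n_mem < 4:
        raise ValueError("need at least 4 membrane nodes")
    if n_mem == 24:
        return _rhombicuboctahedron()
    if n_mem == 6:
        return np.array(
            [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]],
            dtype=float,
        )
    if n_mem % 2 == 0:
        half = _fibonacci_sphere(n_mem // 2)
        return np.concatenate([half, -half])
    return _fibonacci_sphere(n_mem)


@dataclass
class CellState:
    """One migrating cell agent."""

    id: int
    phenotype: str
    centroid: np.ndarray
    dirs: np.ndarray  # (n_mem, 3) outward unit vectors; e_i (inward) = -dirs
    node_active: np.ndarray = field(default=None)  # False at cell-cell common nodes
    node_strain: np.ndarray = field(default=None)  # eps_i, + under contraction
    node_tensor: np.ndarray = field(default=None)  # substrate strain (n_mem, 3, 3)
    MI: float = 0.0
    age_in_phenotype: float = 0.0  # hours
    alive: bool = True
    e_pol: np.ndarray = field(default=None)  # persisted polarisation direction
    sense_converged: bool = True
    u_field: np.ndarray = field(default=None, repr=False)  # last sensing field

    def __post_init__(self) -> None:
        if self.phenotype not in PHENOTYPES:
            raise ValueError(f"unknown phenotype {self.phenotype!r}")
        self.centroid = np.asarray(self.centroid, dtype=float)
        n = self.dirs.shape[0]
        if self.node_active is None:
            self.node_active = np.ones(n, dtype=bool)
        if self.node_strain is None:
            self.node_strain = np.zeros(n)
        if self.node_tensor is None:
            self.node_tensor = np.zeros((n, 3, 3))
        if self.e_pol is None:
            self.e_pol = np.array([1.0, 0.0, 0.0])

    def membrane_points(self, r_cell: float) -> np.ndarray:
        return self.centroid[None, :] + r_cell * self.dirs


@dataclass(frozen=True)
class ForceBalance:
    """Resolved per-step force balance and resulting kinematics."""

    F_trac_net: np.ndarray  # nN
    F_prot: np.ndarray  # nN
    F_drag: np.ndarray  # nN
    e_pol: np.ndarray
    v: float  # um/h
    d: np.ndarray  # um


def cell_stress(eps, p: MechanicalParams):
    """Cell stress (kPa) transmitted to the substrate at signed strain eps.

    Piecewise passive/active law: purely passive outside [eps_min, eps_max],
    passive plus an active actin-myosin branch inside, continuous at
    eps_min, eps_tilde = sigma_max/K_act and eps_max.
    """
    eps = np.asarray(eps, dtype=float)
    a1, s1 = _branch_coeffs(1, p)
    a2, s2 = _branch_coeffs(2, p)
    a3, s3 = _branch_coeffs(3, p)
    out = np.where(
        (eps < p.eps_min) | (eps > p.eps_max),
        a1 + s1 * eps,
        np.where(eps <= p.eps_tilde, a2 + s2 * eps, a3 + s3 * eps),
    )
    return out if out.ndim else float(out)


def _branch_coeffs(branch: int, p: MechanicalParams) -> tuple[float, float]:
    """Intercept/slope of the stress law on one of its affine branches."""
    if branch == 1:
        return 0.0, p.K_pas
    if branch == 2:
        den = p.K_act * p.eps_min - p.sigma_max
        return p.K_act * p.sigma_max * p.eps_min / den, -p.K_act * p.sigma_max / den + p.K_pas
    den = p.K_act * p.eps_max - p.sigma_max
    return p.K_act * p.sigma_max * p.eps_max / den, -p.K_act * p.sigma_max / den + p.K_pas


def _branch_of(eps: np.ndarray, p: MechanicalParams) -> np.ndarray:
    return np.where(
        (eps < p.eps_min) | (eps > p.eps_max), 1, np.where(eps <= p.eps_tilde, 2, 3)
    )


def adhesivity(k: float, n_r: float, psi: float) -> float:
    """Dimensionless adhesivity zeta = k * n_r * psi."""
    return k * n_r * psi


def _scatter_point_forces(
    ndof: int, conn: np.ndarray, N: np.ndarray, forces: np.ndarray
) -> np.ndarray:
    """Nodal RHS from per-point force vectors via trilinear weights."""
    rhs = np.zeros(ndof)
    contrib = N[:, :, None] * forces[:, None, :]  # (npts, 8, 3)
    dofs = 3 * conn[:, :, None] + np.arange(3)[None, None, :]
    np.add.at(rhs, dofs.ravel(), contrib.ravel())
    return rhs


def _branch_tables(x: np.ndarray, p: MechanicalParams) -> tuple[np.ndarray, np.ndarray]:
    """Per-node intercept/slope of sigma as a function of the stored strain
    x (+ under contraction): sigma_i = a_i - s_i * x_i."""
    branch = _branch_of(-x, p)
    a = np.empty_like(x)
    s = np.empty_like(x)
    for b in (1, 2, 3):
        ab, sb = _branch_coeffs(b, p)
        mask = branch == b
        a[mask], s[mask] = ab, sb
    return a, s


def compliance_matrix(
    op: FEOperator,
    pts: np.ndarray,
    inward: np.ndarray,
    r_cell: float,
    cols: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Membrane compliance C and the raw unit-force solutions U.

    C[i, j] is the inward strain read at membrane point i per unit force
    applied inward at membrane point j (columns restricted to ``cols``).
    """
    mesh = op.mesh
    n = pts.shape[0]
    cols = np.arange(n) if cols is None else cols
    elem, xi = mesh.locate(pts)
    N = shape_functions(xi)
    conn = mesh.hex_connectivity[elem]
    ndof = 3 * mesh.n_nodes
    rhs = np.empty((ndof, cols.size))
    for k, j in enumerate(cols):
        rhs[:, k] = _scatter_point_forces(ndof, conn[[j]], N[[j]], inward[[j]])
    U = op.solve(rhs)  # (n_nodes, 3, n_cols)
    u_pts = np.einsum("pa,pacs->pcs", N, U[conn])
    C = np.einsum("pcs,pc->ps", u_pts, inward) / r_cell
    return C, U


class _ComplianceField:
    """Membrane compliance C(centroid) tabulated on a coarse grid of cell
    positions and interpolated trilinearly.

    C varies smoothly with the centroid (it only feels the distance to the
    free surfaces), so a ~40 um grid gives a Jacobian good to a few percent
    everywhere — enough for the quasi-Newton sensing iteration, whose
    convergence check always uses exact FE sweeps.
    """

    def __init__(self, op: FEOperator, p: MechanicalParams, spacing: float = 40.0):
        self.dirs = membrane_template(p.n_mem)
        r = p.r_cell
        dims = np.asarray(op.mesh.dims)
        self.axes = [
            np.linspace(r, d - r, max(2, int(round((d - 2 * r) / spacing)) + 1))
            for d in dims
        ]
        shape = tuple(len(a) for a in self.axes)
        self.grid = np.empty(shape + (p.n_mem, p.n_mem))
        for i, xv in enumerate(self.axes[0]):
            for j, yv in enumerate(self.axes[1]):
                for k, zv in enumerate(self.axes[2]):
                    pts = np.array([xv, yv, zv]) + r * self.dirs
                    C, _ = compliance_matrix(op, pts, -self.dirs, r)
                    self.grid[i, j, k] = 0.5 * (C + C.T)  # Betti reciprocity

    def __call__(self, centroid: np.ndarray) -> np.ndarray:
        idx = []
        wts = []
        for a, c in zip(self.axes, centroid):
            i = int(np.clip(np.searchsorted(a, c) - 1, 0, len(a) - 2))
            t = np.clip((c - a[i]) / (a[i + 1] - a[i]), 0.0, 1.0)
            idx.append(i)
            wts.append(t)
        C = np.zeros_like(self.grid[0, 0, 0])
        for di in (0, 1):
            for dj in (0, 1):
                for dk in (0, 1):
                    w = (
                        (wts[0] if di else 1 - wts[0])
                        * (wts[1] if dj else 1 - wts[1])
                        * (wts[2] if dk else 1 - wts[2])
                    )
                    if w:
                        C += w * self.grid[idx[0] + di, idx[1] + dj, idx[2] + dk]
        return C


def _jacobian_compliance(
    op: FEOperator, p: MechanicalParams, centroid: np.ndarray
) -> np.ndarray:
    """Approximate membrane compliance at the given centroid, cached.

    On stiff substrates (cell/substrate stiffness ratio well below one) the
    box-centre compliance is an adequate Jacobian everywhere; on soft ones
    the position-tabulated field is built (lazily, once per operator) so
    the sensing iteration also converges against the free surfaces.
    """
    cache = getattr(op, "_sense_cache", None)
    if cache is None:
        cache = {}
        op._sense_cache = cache
    key = (p.r_cell, p.n_mem)
    info = cache.get(key)
    if info is None:
        dirs = membrane_template(p.n_mem)
        centre = 0.5 * np.asarray(op.mesh.dims)
        C0, _ = compliance_matrix(op, centre[None, :] + p.r_cell * dirs, -dirs, p.r_cell)
        C0 = 0.5 * (C0 + C0.T)
        _, s2 = _branch_coeffs(2, p)
        rho = float(np.linalg.eigvalsh(p.S_node * s2 * C0).max())
        info = {"C0": C0, "rho": rho, "field": None}
        cache[key] = info
    if info["rho"] < 0.4:
        return info["C0"]
    if info["field"] is None:
        info["field"] = _ComplianceField(op, p)
    return info["field"](centroid)


def mechanosense(
    cell: CellState,
    op: FEOperator,
    p: MechanicalParams,
    tol: float = 1e-6,
    max_iter: int = 50,
) -> None:
    """Self-consistent sensing solve; updates node_strain and node_tensor.

    Every active membrane node pulls the substrate toward the centroid with
    force ``cell_stress(-eps_i) * S_node``; the resulting inward displacement
    divided by the radius is ``eps_i`` again.  The fixed point is found by a
    quasi-Newton iteration (warm-started from the previous step) whose
    Jacobian uses a cached reference compliance matrix; this stays robust on
    very soft substrates, where the naive force<->strain sweep diverges
    because the cell/substrate stiffness ratio exceeds one.  If the
    iteration stalls, the exact membrane compliance at the current position
    is assembled and the piecewise-affine system is solved directly.
    """
    mesh = op.mesh
    pts = cell.membrane_points(p.r_cell)
    inward = -cell.dirs
    active = np.asarray(cell.node_active, dtype=bool)
    n = pts.shape[0]

    if not active.any():
        cell.node_strain = np.zeros(n)
        cell.node_tensor = np.zeros((n, 3, 3))
        cell.u_field = np.zeros((mesh.n_nodes, 3))
        cell.sense_converged = True
        return

    elem, xi = mesh.locate(pts)  # raises OutOfDomainError if outside
    N = shape_functions(xi)  # (n, 8)
    conn = mesh.hex_connectivity[elem]  # (n, 8)
    act = np.flatnonzero(active)
    ndof = 3 * mesh.n_nodes
    S = p.S_node
    C_ref = _jacobian_compliance(op, p, cell.centroid)

    def g(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """One exact sensing sweep: strains measured under forces sigma(x)*S."""
        a, s = _branch_tables(x, p)
        f = S * (a - s * x)
        f[~active] = 0.0
        rhs = _scatter_point_forces(ndof, conn, N, f[:, None] * inward)
        u = op.solve(rhs)  # (n_nodes, 3)
        u_pts = np.einsum("pa,pac->pc", N, u[conn])
        return np.einsum("pc,pc->p", u_pts, inward) / p.r_cell, u

    x = np.asarray(cell.node_strain, dtype=float).copy()  # warm start
    converged = False
    u = None
    stall_cap = min(12, max_iter)
    for it in range(max_iter):
        x_meas, u = g(x)
        resid = x_meas - x
        if np.max(np.abs(resid)) <= tol:
            # keep the pre-image: |g(x) - x| <= tol holds for the stored x,
            # so a repeated sweep changes the strains by at most tol
            converged = True
            break
        if it >= stall_cap:
            break
        _, s = _branch_tables(x, p)
        J = np.eye(act.size) + C_ref[np.ix_(act, act)] * (S * s[act])[None, :]
        x[act] += np.linalg.solve(J, resid[act])
        x[~active] = x_meas[~active]

    if not converged:
        # exact path: assemble the true compliance and solve the
        # piecewise-affine system directly, iterating on branch changes only
        C, _ = compliance_matrix(op, pts, inward, p.r_cell, cols=act)
        for _ in range(max_iter):
            a, s = _branch_tables(x, p)
            A = np.eye(act.size) + C[act] * (S * s[act])[None, :]
            x_act = np.linalg.solve(A, C[act] @ (S * a[act]))
            x_new = C @ (S * (a[act] - s[act] * x_act))
            if np.max(np.abs(x_new - x)) <= tol:
                x = x_new
                converged = True
                break
            x = x_new
        _, u = g(x)
    if not converged:
        warnings.warn("mechano-sensing fixed point did not converge; using last iterate")
    cell.sense_converged = converged
    cell.node_strain = x
    cell.node_tensor = strain_at_points(mesh, u, pts)
    cell.u_field = u


def traction_forces(
    cell: CellState, p: MechanicalParams, e_pol_prev: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-node traction forces (nN) and their vector sum.

    Each node carries ``cell_stress(-eps_i) * S_node * zeta_i`` along its
    inward direction; nodes whose outward direction has non-negative
    projection on the previous polarisation use the front adhesivity,
    the rest the back one.  Contact-suppressed nodes still carry traction
    (only their sensing force is switched off).
    """
    sigma = np.atleast_1d(cell_stress(-cell.node_strain, p))
    front = cell.dirs @ e_pol_prev >= 0.0
    zeta = np.where(front, p.zeta_front, p.zeta_back)
    F_nodes = (sigma * p.S_node * zeta)[:, None] * (-cell.dirs)
    return F_nodes, F_nodes.sum(axis=0)


def protrusion_force(F_trac_net: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Random protrusion: magnitude kappa*|F_trac_net| (kappa ~ U[0,1)),
    direction uniform on the unit sphere.  Draw order (kappa, direction)
    is fixed for reproducibility."""
    kappa = rng.random()
    vec = rng.normal(size=3)
    nrm = np.linalg.norm(vec)
    if nrm == 0.0:  # pragma: no cover - probability zero
        vec, nrm = np.array([1.0, 0.0, 0.0]), 1.0
    mag = np.linalg.norm(F_trac_net)
    if mag == 0.0:
        return np.zeros(3)
    return kappa * mag * vec / nrm


def resolve_motion(
    F_trac_net: np.ndarray,
    F_prot: np.ndarray,
    p: MechanicalParams,
    mat: MaterialProps,
    e_pol_prev: np.ndarray,
) -> ForceBalance:
    """Close the force balance and derive polarisation, speed and step.

    F_drag = -(F_trac_net + F_prot); e_pol = -F_drag/|F_drag|;
    v = |F_drag| / (6 pi r eta) (Stokes), d = v tau e_pol.  A zero drag
    force keeps the previous polarisation and does not move the cell.
    """
    F_drag = -(np.asarray(F_trac_net, dtype=float) + np.asarray(F_prot, dtype=float))
    mag = np.linalg.norm(F_drag)
    if mag == 0.0:
        return ForceBalance(
            F_trac_net=np.asarray(F_trac_net, dtype=float),
            F_prot=np.asarray(F_prot, dtype=float),
            F_drag=F_drag,
            e_pol=np.asarray(e_pol_prev, dtype=float),
            v=0.0,
            d=np.zeros(3),
        )
    e_pol = -F_drag / mag
    drag_coef = 6.0 * np.pi * p.r_cell * mat.eta * _PA_S_TO_NN  # nN*s/um
    v = mag / drag_coef * _SECONDS_PER_HOUR  # um/h
    d = v * p.tau * e_pol
    return ForceBalance(
        F_trac_net=np.asarray(F_trac_net, dtype=float),
        F_prot=np.asarray(F_prot, dtype=float),
        F_drag=F_drag,
        e_pol=e_pol,
        v=v,
        d=d,
    )
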