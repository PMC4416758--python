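"""Substrate finite-element module: mesh topology, stiffness assembly,
point-load solves and strain recovery."""

import numpy as np
import pytest

import mechanofate as mf
from mechanofate import fem


# ---------------------------------------------------------------- oracles
def dense_hex_stiffness_oracle(h, E, nu):
    """Independent single-hex assembly: explicit 4th-order isotropic tensor
    contracted with shape-function gradients under 3x3x3 Gauss quadrature
    (exact for the trilinear integrand on an affine element)."""
    lam = E * nu / ((1 + nu) * (1 - 2 * nu))
    mu = E / (2 * (1 + nu))
    delta = np.eye(3)
    Ct = (
        lam * np.einsum("ij,kl->ijkl", delta, delta)
        + mu * (np.einsum("ik,jl->ijkl", delta, delta) + np.einsum("il,jk->ijkl", delta, delta))
    )
    gp, gw = np.polynomial.legendre.leggauss(3)
    K = np.zeros((24, 24))
    Jinv = np.diag(2.0 / np.asarray(h))
    detJ = np.prod(h) / 8.0
    for a, wa in zip(gp, gw):
        for b, wb in zip(gp, gw):
            for c, wc in zip(gp, gw):
                dN = fem.shape_gradients(np.array([a, b, c])) @ Jinv.T  # (8,3)
                w = wa * wb * wc * detJ
                for na in range(8):
                    for nb in range(8):
                        # K[na_i, nb_j] = int C_ikjl dN_na/dx_k dN_nb/dx_l
                        blk = np.einsum("ikjl,k,l->ij", Ct, dN[na], dN[nb])
                        K[3 * na:3 * na + 3, 3 * nb:3 * nb + 3] += w * blk
    return K


def uniaxial_bar_loads(mesh, sigma):
    """Consistent nodal forces for uniform +/-sigma tractions on the x faces."""
    L = mesh.dims
    h = mesh.spacing
    coords = mesh.node_coords
    f = np.zeros(3 * mesh.n_nodes)
    cell_area = h[1] * h[2]
    for xval, sgn in [(0.0, -1.0), (L[0], 1.0)]:
        on = np.isclose(coords[:, 0], xval)
        w = np.ones(on.sum())
        ys, zs = coords[on, 1], coords[on, 2]
        w *= np.where(np.isclose(ys, 0) | np.isclose(ys, L[1]), 0.5, 1.0)
        w *= np.where(np.isclose(zs, 0) | np.isclose(zs, L[2]), 0.5, 1.0)
        f[3 * np.flatnonzero(on)] += sgn * sigma * cell_area * w
    return f


# ------------------------------------------------------------------ mesh
@pytest.mark.parametrize(
    "dims, n_div, n_elems, n_nodes",
    [
        ((400, 200, 200), (40, 20, 20), 16_000, 18_081),  # reference domain
        ((10, 10, 10), (1, 1, 1), 1, 8),
        ((200, 100, 100), (20, 10, 10), 2_000, 2_541),
    ],
)
def test_mesh_counts(dims, n_div, n_elems, n_nodes):
    mesh = mf.build_hex_mesh(dims, n_div)
    assert mesh.n_elems == n_elems
    assert mesh.n_nodes == n_nodes


def test_mesh_positive_jacobian_and_ordering(small_mesh):
    # VTK ordering on a regular grid: constant positive Jacobian everywhere
    for conn in small_mesh.hex_connectivity:
        verts = small_mesh.node_coords[conn]
        e1 = verts[1] - verts[0]
        e2 = verts[3] - verts[0]
        e3 = verts[4] - verts[0]
        assert np.dot(np.cross(e1, e2), e3) > 0


@pytest.mark.parametrize("bad", [(0, 1, 1), (-2, 1, 1)])
def test_mesh_invalid_divisions(bad):
    with pytest.raises(mf.InvalidConfigError):
        mf.build_hex_mesh((10, 10, 10), bad)


# ------------------------------------------------------------- stiffness
def test_element_stiffness_matches_independent_assembly():
    h = np.array([10.0, 10.0, 10.0])
    ke = fem.element_stiffness(h, E=1.0, nu=0.0)
    oracle = dense_hex_stiffness_oracle(h, E=1.0, nu=0.0)
    assert np.linalg.norm(ke - oracle) <= 1e-10 * np.linalg.norm(oracle)
    # and with a nonzero Poisson ratio / anisotropic edge lengths
    h2 = np.array([10.0, 5.0, 4.0])
    ke2 = fem.element_stiffness(h2, E=3.0, nu=0.3)
    oracle2 = dense_hex_stiffness_oracle(h2, E=3.0, nu=0.3)
    assert np.linalg.norm(ke2 - oracle2) <= 1e-10 * np.linalg.norm(oracle2)


def test_global_stiffness_symmetric_and_six_rigid_modes(small_mesh):
    K = fem.assemble_stiffness(small_mesh, mf.MaterialProps(E=5.0, nu=0.3))
    assert abs(K - K.T).max() == 0.0
    w = np.linalg.eigvalsh(K.toarray())
    assert (np.abs(w) < 1e-8 * w.max()).sum() == 6


def test_operator_invertible_after_constraints(small_mesh):
    op = mf.assemble_operator(small_mesh, mf.MaterialProps(E=5.0))
    u = op.solve(np.zeros(3 * small_mesh.n_nodes))
    assert np.all(u == 0.0)


# ---------------------------------------------------------------- solves
def test_zero_loads_zero_displacement(cube_op, cube_mesh):
    u = mf.solve_displacements(cube_op, np.array([[40.0, 40.0, 40.0]]), np.zeros((1, 3)))
    assert np.allclose(u, 0.0)


def test_load_point_outside_box_raises(cube_op):
    with pytest.raises(mf.OutOfDomainError):
        mf.solve_displacements(cube_op, np.array([[90.0, 40.0, 40.0]]), np.ones((1, 3)))


def test_dipole_field_antisymmetric_about_midpoint(cube_op, cube_mesh):
    """Equal-opposite collinear forces: u(x) + u(2c - x) is a constant
    (rigid translation), so the deformation field is antisymmetric."""
    c = np.array([40.0, 40.0, 40.0])
    pts = np.array([c - [10, 0, 0], c + [10, 0, 0]])
    F = 5.0
    u = mf.solve_displacements(cube_op, pts, np.array([[F, 0, 0], [-F, 0, 0]]))
    coords = cube_mesh.node_coords
    # mirror node lookup through the box centre (mesh is symmetric)
    order = {tuple(np.round(xyz, 6)): i for i, xyz in enumerate(coords)}
    mirror = np.array([order[tuple(np.round(2 * c - xyz, 6))] for xyz in coords])
    s = u + u[mirror]
    peak = np.abs(u).max()
    assert np.abs(s - s.mean(axis=0)).max() <= 1e-6 * peak


def test_patch_test_uniaxial_bar():
    mesh = mf.build_hex_mesh((40.0, 20.0, 20.0), (4, 2, 2))
    mat = mf.MaterialProps(E=10.0, nu=0.3)
    op = mf.assemble_operator(mesh, mat)
    sigma = 2.0
    u = op.solve(uniaxial_bar_loads(mesh, sigma))
    probes = np.array([[17.0, 9.0, 11.0], [5.0, 5.0, 5.0], [33.0, 13.0, 7.0]])
    eps = mf.strain_at_points(mesh, u, probes)
    assert np.abs(eps[:, 0, 0] - sigma / mat.E).max() <= 1e-8
    assert np.abs(eps[:, 1, 1] + mat.nu * sigma / mat.E).max() <= 1e-8
    assert np.abs(eps[:, 2, 2] + mat.nu * sigma / mat.E).max() <= 1e-8
    off = eps.copy()
    off[:, [0, 1, 2], [0, 1, 2]] = 0.0
    assert np.abs(off).max() <= 1e-8


def test_constraint_corner_insensitivity_for_self_equilibrated_loads(cube_mesh):
    """With free surfaces the two constraint choices may differ only by a
    rigid-body motion; strains are identical."""
    mat = mf.MaterialProps(E=10.0)
    op1 = mf.assemble_operator(cube_mesh, mat)
    # alternative 3-2-1 set anchored at the opposite corner
    nx, ny, nz = cube_mesh.n_div
    nid = lambda ix, iy, iz: ix + iy * (nx + 1) + iz * (nx + 1) * (ny + 1)
    nA, nB, nC = nid(nx, ny, nz), nid(0, ny, nz), nid(nx, 0, nz)
    alt = np.array([3 * nA, 3 * nA + 1, 3 * nA + 2, 3 * nB + 1, 3 * nB + 2, 3 * nC + 2])
    K = fem.assemble_stiffness(cube_mesh, mat)
    free = np.setdiff1d(np.arange(K.shape[0]), alt)
    from scipy.sparse.linalg import splu
    op2 = fem.FEOperator(mesh=cube_mesh, mat=mat, constrained_dofs=alt,
                         _free=free, _lu=splu(K[free][:, free].tocsc()))
    c = np.array([40.0, 40.0, 40.0])
    pts = np.array([c - [10, 0, 0], c + [10, 0, 0]])
    loads = np.array([[3.0, 0, 0], [-3.0, 0, 0]])
    u1 = mf.solve_displacements(op1, pts, loads)
    u2 = mf.solve_displacements(op2, pts, loads)
    probes = np.array([[35.0, 35.0, 35.0], [45.0, 52.0, 38.0], [22.0, 41.0, 47.0]])
    e1 = mf.strain_at_points(cube_mesh, u1, probes)
    e2 = mf.strain_at_points(cube_mesh, u2, probes)
    peak = np.abs(e1).max()
    assert np.abs(e1 - e2).max() <= 0.01 * peak


def test_factorize_once_reuse_contract(cube_mesh):
    mat = mf.MaterialProps(E=7.0)
    op = mf.assemble_operator(cube_mesh, mat)
    pts = np.array([[30.0, 40.0, 40.0], [50.0, 40.0, 40.0]])
    loads = np.array([[1.0, 0, 0], [-1.0, 0, 0]])
    u_first = mf.solve_displacements(op, pts, loads)
    for _ in range(3):  # interleave other solves
        mf.solve_displacements(op, pts[::-1], loads[::-1])
    u_again = mf.solve_displacements(op, pts, loads)
    fresh = mf.assemble_operator(cube_mesh, mat)
    u_fresh = mf.solve_displacements(fresh, pts, loads)
    assert np.array_equal(u_first, u_again)
    assert np.abs(u_again - u_fresh).max() <= 1e-12 * max(np.abs(u_fresh).max(), 1.0)


def test_mesh_refinement_consistency():
    """Displacement under a fixed self-equilibrated dipole converges with
    refinement: change norm decreases across 3 levels."""
    c = np.array([20.0, 20.0, 20.0])
    pts = np.array([c - [5, 0, 0], c + [5, 0, 0]])
    loads = np.array([[2.0, 0, 0], [-2.0, 0, 0]])
    probes = np.array([[10.0, 10.0, 10.0], [30.0, 25.0, 15.0], [20.0, 32.0, 20.0]])
    sols = []
    for n in (4, 8, 16):
        mesh = mf.build_hex_mesh((40.0, 40.0, 40.0), (n, n, n))
        op = mf.assemble_operator(mesh, mf.MaterialProps(E=10.0))
        u = mf.solve_displacements(op, pts, loads)
        elem, xi = mesh.locate(probes)
        N = fem.shape_functions(xi)
        up = np.einsum("pa,pac->pc", N, u[mesh.hex_connectivity[elem]])
        up -= up.mean(axis=0)  # discard the constraint-dependent rigid part
        sols.append(up)
    d1 = np.linalg.norm(sols[1] - sols[0])
    d2 = np.linalg.norm(sols[2] - sols[1])
    assert d2 < d1


# ---------------------------------------------------------------- strain
def test_strain_rigid_translation_is_zero(cube_mesh):
    disp = np.tile([1.0, -2.0, 0.5], (cube_mesh.n_nodes, 1))
    eps = mf.strain_at_point(cube_mesh, disp, [33.0, 41.0, 27.0])
    assert np.abs(eps).max() <= 1e-12


def test_strain_affine_field_reproduced_exactly(cube_mesh, rng):
    A = rng.normal(size=(3, 3))
    A = 0.5 * (A + A.T) * 1e-3
    disp = cube_mesh.node_coords @ A.T
    probes = rng.uniform(5, 75, size=(10, 3))
    eps = mf.strain_at_points(cube_mesh, disp, probes)
    assert np.abs(eps - A[None]).max() <= 1e-12


def test_strain_point_outside_raises(cube_mesh):
    disp = np.zeros((cube_mesh.n_nodes, 3))
    with pytest.raises(mf.OutOfDomainError):
        mf.strain_at_point(cube_mesh, disp, [100.0, 10.0, 10.0])
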