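"""Multi-cell bookkeeping: contact detection, common-node suppression and
minimum-separation enforcement.

Cells are impenetrable spheres: after every completed step the pairwise
centroid distance is at least one cell diameter (2r) and every centroid
stays at least one radius inside the substrate box.  Touching cells share
"common" membrane nodes which stop exerting sensing forces (but keep their
traction contribution) until the pair separates again.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fem import SubstrateMesh
from .mechanics import CellState

#: contact tolerance as a fraction of the cell radius; with the default
#: 24-node template two touching cells share between 1 and 4 common nodes
DELTA_C_FACTOR = 0.25


@dataclass
class PopulationState:
    """All live cells plus the simulation clock."""

    cells: list[CellState]
    time: float = 0.0  # hours
    substrate: SubstrateMesh | None = None
    next_id: int = field(default=None)

    def __post_init__(self) -> None:
        if self.next_id is None:
            self.next_id = 1 + max((c.id for c in self.cells), default=-1)

    @property
    def centroids(self) -> np.ndarray:
        return np.array([c.centroid for c in self.cells]).reshape(-1, 3)


def centroid_vector(ci: CellState, cj: CellState) -> np.ndarray:
    """Vector from cell i to cell j, x_ij = x_j - x_i (um)."""
    return np.asarray(cj.centroid, dtype=float) - np.asarray(ci.centroid, dtype=float)


def detect_contacts(pop: PopulationState, r_cell: float) -> None:
    """Recompute each cell's inactive (common) membrane nodes.

    For every pair closer than 2r + delta_c, the membrane nodes of one cell
    lying within r + delta_c of the other cell's centroid are suppressed.
    Flags are rebuilt from scratch, so nodes reactivate automatically when
    a pair separates.
    """
    delta = DELTA_C_FACTOR * r_cell
    cells = pop.cells
    for c in cells:
        c.node_active = np.ones(c.dirs.shape[0], dtype=bool)
    for i, ci in enumerate(cells):
        for cj in cells[i + 1:]:
            x_ij = centroid_vector(ci, cj)
            if np.linalg.norm(x_ij) > 2.0 * r_cell + delta:
                continue
            pi = ci.membrane_points(r_cell)
            pj = cj.membrane_points(r_cell)
            ci.node_active &= (
                np.linalg.norm(pi - cj.centroid, axis=1) > r_cell + delta
            )
            cj.node_active &= (
                np.linalg.norm(pj - ci.centroid, axis=1) > r_cell + delta
            )


def enforce_separation(
    pop: PopulationState,
    proposed_moves: np.ndarray,
    r_cell: float,
    dims: tuple[float, float, float],
    max_sweeps: int = 20,
) -> tuple[np.ndarray, bool]:
    """Apply translocations, then restore the hard constraints.

    Centroids are clamped to stay at least r_cell from every box face;
    overlapping pairs are pushed apart symmetrically along their centroid
    line until the distance is exactly 2r, sweeping pairs in cell-id order
    (deterministic).  If the packing cannot be resolved within max_sweeps
    the original (pre-move) positions are kept for this step.

    Returns (new_positions, frozen) where frozen marks an unresolvable
    packing.
    """
    old = pop.centroids
    lo = np.full(3, r_cell)
    hi = np.asarray(dims, dtype=float) - r_cell
    if np.any(lo > hi):
        raise ValueError("substrate box too small for the cell radius")
    pos = np.clip(old + np.atleast_2d(proposed_moves), lo, hi)
    n = pos.shape[0]
    if n <= 1:
        return pos, False
    for _ in range(max_sweeps):
        clean = True
        for i in range(n):
            for j in range(i + 1, n):
                x_ij = pos[j] - pos[i]
                dist = np.linalg.norm(x_ij)
                if dist >= 2.0 * r_cell - 1e-12:
                    continue
                clean = False
                axis = x_ij / dist if dist > 1e-12 else np.array([1.0, 0.0, 0.0])
                mid = 0.5 * (pos[i] + pos[j])
                pos[i] = mid - r_cell * axis
                pos[j] = mid + r_cell * axis
        pos = np.clip(pos, lo, hi)
        if clean:
            return pos, False
    # give the post-sweep state one last chance before freezing
    d = pos[None, :, :] - pos[:, None, :]
    mind = np.linalg.norm(d, axis=-1)[~np.eye(n, dtype=bool)].min()
    if mind >= 2.0 * r_cell - 1e-9:
        return pos, False
    return old, True


def min_pairwise_distance(pop: PopulationState) -> float:
    pos = pop.centroids
    n = pos.shape[0]
    if n < 2:
        return np.inf
    d = np.linalg.norm(pos[None, :, :] - pos[:, None, :], axis=-1)
    return float(d[~np.eye(n, dtype=bool)].min())
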