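"""Mechanical signal, maturation and the differentiation / proliferation /
apoptosis rules.

The decision variable is the mechanical signal ``gamma``: the cell's summed
substrate strain at its membrane nodes projected on the polarisation
direction.  Stiff substrates deform little (small gamma, osteogenic band),
soft ones deform a lot (large gamma, neurogenic band).  gamma also sets the
maturation time t_mat = t_min + t_p * gamma, so stiffer substrates mature
their cells faster.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mechanics import CHONDROCYTE, MSC, NEUROBLAST, OSTEOBLAST, PHENOTYPES, CellState

#: how simultaneous MSC differentiation + proliferation is resolved
CONCURRENT_MODES = ("divide_differentiate", "differentiate_only", "probabilistic")

HOURS_PER_DAY = 24.0


@dataclass(frozen=True)
class FateParams:
    """Signal thresholds (dimensionless) and maturation times (days).

    The differentiation bands partition (gamma_l, gamma_u]:
    osteoblast (gamma_l, gamma_s], chondrocyte (gamma_s, gamma_c],
    neuroblast (gamma_c, gamma_u]; gamma > gamma_apop kills the cell.
    ``gamma_prof`` holds the per-phenotype proliferation limits; only the
    MSC value is part of the standard parameter set, the differentiated
    phenotypes default to the same limit.
    """

    t_min: float = 4.0
    t_p: float = 200.0
    gamma_l: float = 0.005
    gamma_s: float = 0.04
    gamma_c: float = 0.1
    gamma_u: float = 0.5
    gamma_apop: float = 1.0
    gamma_prof: dict = field(
        default_factory=lambda: {
            MSC: 0.2,
            OSTEOBLAST: 0.2,
            CHONDROCYTE: 0.2,
            NEUROBLAST: 0.2,
        }
    )
    concurrent_mode: str = "divide_differentiate"

    def __post_init__(self) -> None:
        if not (self.gamma_l < self.gamma_s < self.gamma_c < self.gamma_u <= self.gamma_apop):
            raise ValueError("require gamma_l < gamma_s < gamma_c < gamma_u <= gamma_apop")
        if not self.t_min > 0:
            raise ValueError("t_min must be positive")
        for phen, g in self.gamma_prof.items():
            if phen not in PHENOTYPES:
                raise ValueError(f"unknown phenotype {phen!r} in gamma_prof")
            if not g < self.gamma_u:
                raise ValueError("proliferation limits must satisfy gamma_prof < gamma_u")
        if self.concurrent_mode not in CONCURRENT_MODES:
            raise ValueError(f"concurrent_mode must be one of {CONCURRENT_MODES}")


@dataclass(frozen=True)
class FateEvent:
    """One recorded fate event.

    kind is one of none, differentiate_osteoblast, differentiate_chondrocyte,
    differentiate_neuroblast, proliferate, apoptosis (plus the bookkeeping
    kind "matured" emitted by the runner when MI first reaches 1).
    """

    kind: str
    time: float  # hours
    cell_id: int
    gamma: float = np.nan
    phenotype_before: str = ""
    phenotype_after: str = ""


def mechanical_signal(
    node_tensors: np.ndarray, node_active: np.ndarray, e_pol: np.ndarray
) -> float:
    """gamma = |sum_i e_pol . eps_i . e_pol| over all membrane nodes.

    The raw sum is negative under contraction with the usual small-strain
    sign convention; its absolute value is compared against the (positive)
    fate thresholds.  Contact-suppressed nodes contribute whatever substrate
    strain was stored for them.
    """
    e = np.asarray(e_pol, dtype=float)
    return float(abs(np.einsum("i,nij,j->", e, np.asarray(node_tensors), e)))


def maturation_time(gamma: float, fp: FateParams) -> float:
    """t_mat = t_min + t_p * gamma (days): stronger deformation, slower maturation."""
    if gamma < 0:
        raise ValueError("gamma must be non-negative")
    return fp.t_min + fp.t_p * gamma


def update_MI(cell: CellState, gamma: float, tau: float, fp: FateParams) -> float:
    """Accrue maturation irreversibly: dMI = tau / t_mat(gamma), capped at 1.

    For constant gamma this reproduces MI = t / t_mat exactly; for
    time-varying gamma the increments accumulate, honouring the
    irreversibility of maturation.  tau is in hours, t_mat in days.
    """
    dmi = (tau / HOURS_PER_DAY) / maturation_time(gamma, fp)
    cell.MI = min(1.0, cell.MI + dmi)
    return cell.MI


def _differentiation_target(gamma: float, fp: FateParams) -> str | None:
    if fp.gamma_l < gamma <= fp.gamma_s:
        return OSTEOBLAST
    if fp.gamma_s < gamma <= fp.gamma_c:
        return CHONDROCYTE
    if fp.gamma_c < gamma <= fp.gamma_u:
        return NEUROBLAST
    return None


def decide_fate(
    cell: CellState, gamma: float, fp: FateParams, rng: np.random.Generator
) -> list[FateEvent]:
    """Apply the fate rules; returns 0-2 events (not yet applied to state).

    Apoptosis fires whenever gamma exceeds gamma_apop, regardless of
    maturation.  Otherwise a fully mature (MI = 1) MSC differentiates if
    gamma falls in a lineage band, and any fully mature cell proliferates
    if gamma is at or below its phenotype's proliferation limit.  When an
    MSC satisfies both, the concurrent_mode decides: by default it divides
    and both daughters carry the differentiated phenotype.
    """
    if not cell.alive:
        raise ValueError("decide_fate called on a dead cell")
    if cell.phenotype not in PHENOTYPES:
        raise ValueError(f"unknown phenotype {cell.phenotype!r}")
    t = np.nan  # stamped by the runner
    if gamma > fp.gamma_apop:
        return [FateEvent("apoptosis", t, cell.id, gamma, cell.phenotype, "")]
    if cell.MI < 1.0:
        return []
    target = _differentiation_target(gamma, fp) if cell.phenotype == MSC else None
    proliferate = gamma <= fp.gamma_prof[cell.phenotype]
    events: list[FateEvent] = []
    if target is not None and proliferate:
        mode = fp.concurrent_mode
        if mode == "probabilistic" and rng.random() < 0.5:
            mode = "differentiate_only"
        if mode == "differentiate_only":
            proliferate = False
    if target is not None:
        events.append(
            FateEvent(f"differentiate_{target}", t, cell.id, gamma, cell.phenotype, target)
        )
    if proliferate:
        after = target if target is not None else cell.phenotype
        events.append(FateEvent("proliferate", t, cell.id, gamma, cell.phenotype, after))
    return events


def apply_proliferation(
    mother: CellState,
    rng: np.random.Generator,
    r_cell: float,
    dims: tuple[float, float, float],
    other_centroids: np.ndarray,
    max_tries: int = 100,
) -> np.ndarray | None:
    """Position for the second daughter: mother + 2r * e_rand.

    The first daughter keeps the mother's position.  The random direction
    is re-drawn (up to max_tries) until the new centroid lies at least
    r_cell inside the box and at least 2r from every other cell; None means
    no admissible placement was found and division is deferred.
    """
    if mother.MI < 1.0:
        raise ValueError("only a fully mature cell can divide")
    lo = np.full(3, r_cell)
    hi = np.asarray(dims, dtype=float) - r_cell
    others = np.atleast_2d(other_centroids) if np.size(other_centroids) else None
    for _ in range(max_tries):
        vec = rng.normal(size=3)
        nrm = np.linalg.norm(vec)
        if nrm == 0.0:  # pragma: no cover
            continue
        pos = mother.centroid + 2.0 * r_cell * vec / nrm
        if np.any(pos < lo) or np.any(pos > hi):
            continue
        if others is not None and np.linalg.norm(others - pos, axis=1).min() < 2.0 * r_cell:
            continue
        return pos
    return None
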