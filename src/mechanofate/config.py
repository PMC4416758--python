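"""Run configuration: a flat, versioned, human-editable YAML mapping.

Keys keep the standard parameter-table names (nu, eta, K_pas, ...,
gamma_m_prof).  Defaults reproduce the reference setup: a 400x200x200 um
substrate meshed 40x20x20, one MSC seeded at a corner, a 6 h step and 20
replicates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from .fem import InvalidConfigError, MaterialProps
from .fate import CONCURRENT_MODES, FateParams
from .mechanics import CHONDROCYTE, MSC, NEUROBLAST, OSTEOBLAST, MechanicalParams

SCHEMA_VERSION = 1

#: the six stiffness scenarios (kPa): soft, intermediate and hard substrates
SCENARIOS = {
    "soft-0.1": 0.1,
    "soft-1": 1.0,
    "intermediate-20": 20.0,
    "intermediate-25": 25.0,
    "hard-30": 30.0,
    "hard-45": 45.0,
}


@dataclass
class SimulationConfig:
    # substrate
    dims: tuple = (400.0, 200.0, 200.0)
    n_div: tuple = (40, 20, 20)
    E: float = 45.0
    nu: float = 0.3
    eta: float = 1000.0
    # cell mechanics
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
    # fate
    t_min: float = 4.0
    t_p: float = 200.0
    gamma_l: float = 0.005
    gamma_s: float = 0.04
    gamma_c: float = 0.1
    gamma_u: float = 0.5
    gamma_apop: float = 1.0
    gamma_m_prof: float = 0.2
    gamma_s_prof: float | None = None  # default: same as gamma_m_prof
    gamma_c_prof: float | None = None
    gamma_l_prof: float | None = None
    concurrent_mode: str = "divide_differentiate"
    # scenario
    initial_cells: object = "corner"  # "corner", "center" or list of [x, y, z]
    initial_phenotype: str = MSC
    n_steps: int = 252
    record_every: int = 1
    seed: int = 0
    replicates: int = 20
    schema_version: int = SCHEMA_VERSION

    def __post_init__(self) -> None:
        self.dims = tuple(float(v) for v in self.dims)
        self.n_div = tuple(int(v) for v in self.n_div)
        if self.n_steps < 1 or self.replicates < 1 or self.record_every < 1:
            raise InvalidConfigError("n_steps, replicates and record_every must be >= 1")
        if self.concurrent_mode not in CONCURRENT_MODES:
            raise InvalidConfigError(f"concurrent_mode must be one of {CONCURRENT_MODES}")
        # fail early on inconsistent physical parameters
        self.material()
        self.mechanical()
        self.fate()
        self.initial_positions()

    # ----- typed views -------------------------------------------------
    def material(self) -> MaterialProps:
        return MaterialProps(E=self.E, nu=self.nu, eta=self.eta)

    def mechanical(self) -> MechanicalParams:
        return MechanicalParams(
            K_pas=self.K_pas, K_act=self.K_act, eps_min=self.eps_min,
            eps_max=self.eps_max, sigma_max=self.sigma_max, k_f=self.k_f,
            k_b=self.k_b, n_rf=self.n_rf, n_rb=self.n_rb, psi=self.psi,
            r_cell=self.r_cell, n_mem=self.n_mem, tau=self.tau,
        )

    def fate(self) -> FateParams:
        prof = {
            MSC: self.gamma_m_prof,
            OSTEOBLAST: self.gamma_s_prof if self.gamma_s_prof is not None else self.gamma_m_prof,
            CHONDROCYTE: self.gamma_c_prof if self.gamma_c_prof is not None else self.gamma_m_prof,
            NEUROBLAST: self.gamma_l_prof if self.gamma_l_prof is not None else self.gamma_m_prof,
        }
        return FateParams(
            t_min=self.t_min, t_p=self.t_p, gamma_l=self.gamma_l,
            gamma_s=self.gamma_s, gamma_c=self.gamma_c, gamma_u=self.gamma_u,
            gamma_apop=self.gamma_apop, gamma_prof=prof,
            concurrent_mode=self.concurrent_mode,
        )

    def initial_positions(self) -> np.ndarray:
        r = self.r_cell
        if isinstance(self.initial_cells, str):
            if self.initial_cells == "corner":
                return np.array([[r, r, r]])
            if self.initial_cells == "center":
                return np.array([[d / 2.0 for d in self.dims]])
            raise InvalidConfigError(f"unknown placement {self.initial_cells!r}")
        pos = np.atleast_2d(np.asarray(self.initial_cells, dtype=float))
        lo = np.full(3, r)
        hi = np.asarray(self.dims) - r
        if np.any(pos < lo) or np.any(pos > hi):
            raise InvalidConfigError("initial cells must lie at least r_cell inside the box")
        if len(pos) > 1:
            d = np.linalg.norm(pos[None] - pos[:, None], axis=-1)
            if d[~np.eye(len(pos), dtype=bool)].min() < 2 * r:
                raise InvalidConfigError("initial cells must be at least 2*r_cell apart")
        return pos

    # ----- (de)serialisation ------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["dims"] = list(self.dims)
        d["n_div"] = list(self.n_div)
        if not isinstance(d["initial_cells"], str):
            d["initial_cells"] = np.asarray(d["initial_cells"], dtype=float).tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        version = d.pop("schema_version", SCHEMA_VERSION)
        if version != SCHEMA_VERSION:
            raise InvalidConfigError(f"unsupported schema_version {version}")
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise InvalidConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        import hashlib
        payload = yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


def scenario_config(name: str, **overrides) -> SimulationConfig:
    """Preset configuration for one of the six named stiffness scenarios.

    Presets differ only in the substrate Young's modulus.
    """
    if name not in SCENARIOS:
        raise InvalidConfigError(
            f"unknown scenario {name!r}; choose from {sorted(SCENARIOS)}"
        )
    return SimulationConfig(E=SCENARIOS[name], **overrides)
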