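"""Time-stepping driver, replicate management, summaries and file output.

Each step runs, per cell in id order: mechano-sensing, traction forces,
random protrusion, force balance/translocation, mechanical signal,
maturation accrual and the fate decision; then the population constraints
are restored, fate events applied and the clock advanced by tau.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import vtkio
from .config import SimulationConfig
from .fate import (
    FateEvent,
    apply_proliferation,
    decide_fate,
    mechanical_signal,
    update_MI,
)
from .fem import FEOperator, assemble_operator, build_hex_mesh
from .mechanics import (
    CellState,
    PHENOTYPES,
    membrane_template,
    mechanosense,
    protrusion_force,
    resolve_motion,
    traction_forces,
)
from .population import PopulationState, detect_contacts, enforce_separation

RECORD_COLUMNS = [
    "time_h", "time_d", "cell_id", "phenotype", "x", "y", "z",
    "MI", "gamma", "F_trac_net", "v", "events",
]
EVENT_COLUMNS = ["time_h", "time_d", "cell_id", "kind", "gamma",
                 "phenotype_before", "phenotype_after"]


@dataclass
class StepRecord:
    """State written after one completed step."""

    time: float  # hours, end of step
    rows: list = field(default_factory=list)  # one dict per processed cell
    aggregates: dict = field(default_factory=dict)


def step(
    pop: PopulationState,
    op: FEOperator,
    cfg: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[StepRecord, list[FateEvent]]:
    """Advance the population by one time step (tau hours), in place."""
    p = cfg.mechanical()
    mat = cfg.material()
    fp = cfg.fate()
    tau = p.tau
    t_end = pop.time + tau

    detect_contacts(pop, p.r_cell)

    cells = sorted(pop.cells, key=lambda c: c.id)
    moves = np.zeros((len(cells), 3))
    pending: list[tuple[CellState, list[FateEvent]]] = []
    rows = []
    matured: list[CellState] = []
    for k, cell in enumerate(cells):
        mechanosense(cell, op, p)
        _, F_net = traction_forces(cell, p, cell.e_pol)
        F_prot = protrusion_force(F_net, rng)
        fb = resolve_motion(F_net, F_prot, p, mat, cell.e_pol)
        residual = np.linalg.norm(fb.F_trac_net + fb.F_prot + fb.F_drag)
        if residual > 1e-9 * max(1.0, np.linalg.norm(fb.F_trac_net)):
            warnings.warn(f"force balance residual {residual:.2e} nN")
        cell.e_pol = fb.e_pol
        moves[k] = fb.d
        gamma = mechanical_signal(cell.node_tensor, cell.node_active, cell.e_pol)
        was_mature = cell.MI >= 1.0
        update_MI(cell, gamma, tau, fp)
        if not was_mature and cell.MI >= 1.0:
            matured.append(cell)
        events = decide_fate(cell, gamma, fp, rng)
        if events:
            pending.append((cell, events))
        rows.append(
            dict(
                time_h=t_end, time_d=t_end / 24.0, cell_id=cell.id,
                phenotype=cell.phenotype,
                x=cell.centroid[0], y=cell.centroid[1], z=cell.centroid[2],
                MI=cell.MI, gamma=gamma,
                F_trac_net=float(np.linalg.norm(F_net)), v=fb.v, events="",
            )
        )
        cell.age_in_phenotype += tau

    pos, frozen = enforce_separation(pop, moves, p.r_cell, cfg.dims)
    for k, cell in enumerate(cells):
        cell.centroid = pos[k]
        rows[k]["x"], rows[k]["y"], rows[k]["z"] = pos[k]  # end-of-step position

    # apply fate events (id order): differentiation first, then division
    applied: list[FateEvent] = []
    for cell in matured:
        applied.append(
            FateEvent("matured", t_end, cell.id, np.nan, cell.phenotype, cell.phenotype)
        )
    for cell, events in pending:
        flags = []
        for ev in events:
            ev = FateEvent(ev.kind, t_end, ev.cell_id, ev.gamma,
                           ev.phenotype_before, ev.phenotype_after)
            if ev.kind == "apoptosis":
                cell.alive = False
                applied.append(ev)
                flags.append(ev.kind)
                continue
            if ev.kind.startswith("differentiate_"):
                cell.phenotype = ev.phenotype_after
                cell.MI = 0.0
                cell.age_in_phenotype = 0.0
                applied.append(ev)
                flags.append(ev.kind)
                continue
            # proliferation: the mother becomes daughter 1 in place
            others = np.array(
                [c.centroid for c in pop.cells if c.id != cell.id and c.alive]
            )
            new_pos = apply_proliferation(
                cell if cell.MI >= 1.0 else _as_mature(cell),
                rng, p.r_cell, cfg.dims, others,
            )
            if new_pos is None:
                applied.append(
                    FateEvent("proliferation_deferred", t_end, cell.id, ev.gamma,
                              ev.phenotype_before, ev.phenotype_after)
                )
                flags.append("proliferation_deferred")
                continue
            cell.phenotype = ev.phenotype_after
            cell.MI = 0.0
            cell.age_in_phenotype = 0.0
            daughter = CellState(
                id=pop.next_id, phenotype=ev.phenotype_after, centroid=new_pos,
                dirs=cell.dirs, e_pol=cell.e_pol.copy(),
            )
            pop.next_id += 1
            pop.cells.append(daughter)
            applied.append(ev)
            flags.append(ev.kind)
        for row in rows:
            if row["cell_id"] == cell.id:
                row["events"] = ";".join(flags)

    pop.cells = [c for c in pop.cells if c.alive]
    pop.time = t_end

    counts = {ph: sum(c.phenotype == ph for c in pop.cells) for ph in PHENOTYPES}
    agg = dict(
        n_cells=len(pop.cells),
        mean_F_trac=float(np.mean([r["F_trac_net"] for r in rows])) if rows else np.nan,
        mean_MI=float(np.mean([r["MI"] for r in rows])) if rows else np.nan,
        frozen=frozen,
        **{f"n_{ph}": n for ph, n in counts.items()},
    )
    return StepRecord(time=t_end, rows=rows, aggregates=agg), applied


def _as_mature(cell: CellState) -> CellState:
    # a differentiation applied in the same step reset MI; division is still
    # legitimate because the decision was taken at MI = 1
    import copy
    c = copy.copy(cell)
    c.MI = 1.0
    return c


class Simulation:
    """A configured scenario; `run` produces one replicate's result.

    The substrate stiffness is assembled and factorised once at
    construction and reused by every sensing solve of every step.
    """

    def __init__(self, config: SimulationConfig):
        self.config = config
        self.mesh = build_hex_mesh(config.dims, config.n_div)
        self.operator = assemble_operator(self.mesh, config.material())

    def initial_population(self) -> PopulationState:
        cfg = self.config
        dirs = membrane_template(cfg.n_mem)
        cells = [
            CellState(id=i, phenotype=cfg.initial_phenotype, centroid=pos, dirs=dirs)
            for i, pos in enumerate(cfg.initial_positions())
        ]
        return PopulationState(cells=cells, time=0.0, substrate=self.mesh)

    def run(
        self,
        seed: int | None = None,
        n_steps: int | None = None,
        early_stop=None,
        out_dir: str | Path | None = None,
        replicate: int = 0,
    ) -> "SimulationResult":
        cfg = self.config
        rng = np.random.default_rng(cfg.seed if seed is None else seed)
        pop = self.initial_population()
        records: list[StepRecord] = []
        events: list[FateEvent] = []
        n_steps = cfg.n_steps if n_steps is None else n_steps
        out = Path(out_dir) if out_dir is not None else None
        if out is not None:
            out.mkdir(parents=True, exist_ok=True)
        for k in range(n_steps):
            rec, evs = step(pop, self.operator, cfg, rng)
            records.append(rec)
            events.extend(evs)
            if out is not None and (k + 1) % cfg.record_every == 0:
                self._snapshot(out, replicate, k + 1, pop)
            if not pop.cells:  # extinction: nothing left to simulate
                break
            if early_stop is not None and early_stop(events, pop):
                break
        return SimulationResult(
            config=cfg, seed=seed, records=records, events=events, population=pop,
            replicate=replicate,
        )

    def _snapshot(self, out: Path, replicate: int, k: int, pop: PopulationState) -> None:
        pts = pop.centroids
        data = dict(
            phenotype=np.array([PHENOTYPES.index(c.phenotype) for c in pop.cells], float),
            MI=np.array([c.MI for c in pop.cells]),
        )
        vtkio.write_point_cloud(out / f"cells_r{replicate:03d}_s{k:05d}.vtk", pts, data)
        # substrate + superposed sensing displacement field of all cells
        u = np.zeros((self.mesh.n_nodes, 3))
        for c in pop.cells:
            if c.u_field is not None:
                u += c.u_field
        vtkio.write_unstructured_grid(
            out / f"substrate_r{replicate:03d}_s{k:05d}.vtk", self.mesh, {"u": u}
        )


@dataclass
class SimulationResult:
    """One replicate: per-step records, the event log and the final state."""

    config: SimulationConfig
    seed: int | None
    records: list
    events: list
    population: PopulationState
    replicate: int = 0

    def records_frame(self) -> pd.DataFrame:
        rows = [row for rec in self.records for row in rec.rows]
        return pd.DataFrame(rows, columns=RECORD_COLUMNS)

    def events_frame(self) -> pd.DataFrame:
        rows = [
            dict(time_h=e.time, time_d=e.time / 24.0, cell_id=e.cell_id, kind=e.kind,
                 gamma=e.gamma, phenotype_before=e.phenotype_before,
                 phenotype_after=e.phenotype_after)
            for e in self.events
        ]
        return pd.DataFrame(rows, columns=EVENT_COLUMNS)

    # ----- headline scalar outcomes -----------------------------------
    def first_event_time_d(self, kind_prefix: str, phenotype: str | None = None) -> float:
        """Time (days) of the first event whose kind starts with the prefix,
        optionally restricted to a mother/previous phenotype; NaN if absent."""
        for e in self.events:
            if not e.kind.startswith(kind_prefix):
                continue
            if phenotype is not None and e.phenotype_before != phenotype:
                continue
            return e.time / 24.0
        return np.nan

    def first_maturation_time_d(self, phenotype: str) -> float:
        for e in self.events:
            if e.kind == "matured" and e.phenotype_before == phenotype:
                return e.time / 24.0
        return np.nan

    def summary(self) -> dict:
        ev = self.events_frame()
        counts = {
            f"final_{ph}": sum(c.phenotype == ph for c in self.population.cells)
            for ph in PHENOTYPES
        }
        diff = ev[ev.kind.str.startswith("differentiate_")]
        return dict(
            replicate=self.replicate,
            seed=self.seed,
            steps=len(self.records),
            first_differentiation_d=self.first_event_time_d("differentiate_"),
            first_differentiation_target=(
                diff.iloc[0].phenotype_after if len(diff) else ""
            ),
            first_MSC_maturation_d=self.first_maturation_time_d("MSC"),
            **{
                f"first_proliferation_{ph}_d": self.first_event_time_d("proliferate", ph)
                for ph in PHENOTYPES
            },
            **{
                f"first_maturation_{ph}_d": self.first_maturation_time_d(ph)
                for ph in PHENOTYPES
            },
            **counts,
        )

    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        tag = f"r{self.replicate:03d}"
        self.records_frame().to_csv(out / f"records_{tag}.csv", index=False)
        self.events_frame().to_csv(out / f"events_{tag}.csv", index=False)
        log = dict(
            seed=self.seed,
            config_hash=self.config.config_hash(),
            steps=len(self.records),
            convergence_warnings=sum(
                not c.sense_converged for c in self.population.cells
            ),
        )
        (out / f"log_{tag}.json").write_text(json.dumps(log, indent=2))


def run_scenario(
    cfg: SimulationConfig,
    out_dir: str | Path | None = None,
    early_stop=None,
    n_steps: int | None = None,
) -> dict:
    """Run `cfg.replicates` independent seeded replicates and summarise.

    Returns a dict with the per-replicate summaries and cross-replicate
    mean/sd of the headline times; writes CSV/VTK/JSON when out_dir is
    given.
    """
    ss = np.random.SeedSequence(cfg.seed)
    rep_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(cfg.replicates)]
    sim = Simulation(cfg)
    results = []
    for rep, seed in enumerate(rep_seeds):
        res = sim.run(seed=seed, early_stop=early_stop, n_steps=n_steps,
                      out_dir=out_dir, replicate=rep)
        if out_dir is not None:
            res.save(out_dir)
        results.append(res)
    summaries = pd.DataFrame([r.summary() for r in results])
    numeric = summaries.select_dtypes(include=[np.number])
    cross = {
        col: dict(
            mean=float(np.nanmean(numeric[col])) if numeric[col].notna().any() else np.nan,
            sd=float(np.nanstd(numeric[col], ddof=1)) if numeric[col].notna().sum() > 1 else np.nan,
            n=int(numeric[col].notna().sum()),
        )
        for col in numeric.columns
        if col not in ("replicate", "seed", "steps")
    }
    out = dict(
        E=cfg.E,
        replicates=cfg.replicates,
        per_replicate=summaries.to_dict(orient="records"),
        cross_replicate=cross,
    )
    if out_dir is not None:
        path = Path(out_dir) / "summary.json"
        path.write_text(json.dumps(out, indent=2, default=_json_default))
    out["results"] = results
    return out


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    raise TypeError(f"not JSON serialisable: {type(o)}")


def summarize_traction(
    records: list[StepRecord] | pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Population-mean traction trace with fate-event markers.

    Returns (trace, markers): trace has time_d and mean |F_trac_net| per
    step; markers lists the instants at which differentiation or
    proliferation events fired.
    """
    if isinstance(records, list):
        if not records:
            raise ValueError("no records to summarise")
        df = pd.DataFrame([row for rec in records for row in rec.rows])
    else:
        df = records
    if df.empty:
        raise ValueError("no records to summarise")
    trace = (
        df.groupby("time_d", sort=True)["F_trac_net"].mean().rename("mean_F_trac").reset_index()
    )
    ev = df[df.events.astype(str).str.len() > 0][["time_d", "cell_id", "events"]]
    return trace, ev.reset_index(drop=True)


def detect_discontinuities(trace: pd.DataFrame, factor: float = 3.0) -> pd.DataFrame:
    """Steps where the trace jumps by more than `factor` x median |delta|."""
    y = trace["mean_F_trac"].to_numpy()
    dy = np.diff(y)
    med = np.median(np.abs(dy))
    if med == 0:
        jumps = np.abs(dy) > 0
    else:
        jumps = np.abs(dy) > factor * med
    return pd.DataFrame(
        dict(
            time_d=trace["time_d"].to_numpy()[1:][jumps],
            delta=dy[jumps],
        )
    )
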