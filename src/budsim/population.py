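"""Population-level simulation protocols with lineage tracking.

A protocol grows an initial population of cells, optionally subsamples it
mid-course (to keep exponential growth tractable), and continues with a new
inducer level.  The two standard protocols mirror common induction-experiment
designs:

* ``twenty_two_hour``: 1000 cells, inducer on from t=0, 11 h of growth, a
  uniform random sample of 2000 cells, then 11 h more (final population
  ~84,000 cells at a 120-min doubling time).
* ``five_hour``: 20,000 cells grown 5 h in basal (zero-inducer) conditions,
  a sample of 20,000, then 5 h of induction.

Cells are simulated independently between divisions.  Each cell owns a random
stream seeded deterministically from ``(master seed, cell_id)``, so results
are bit-reproducible regardless of scheduling order.  Divisions and optional
per-cell time series are appended to a :class:`LineageLog`, from which the
descendant tree of any cell can be reconstructed.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .cell_cycle import (
    DIVISION,
    CellCycleParams,
    CellCyclePopulationParams,
    CyclePosition,
    divide,
    grow,
    new_cycle,
    position_at_age,
    volume_at,
)
from .gene_network import (
    PROCESS_CATEGORIES,
    NetworkSpec,
    RateTable,
    basal_steady_state,
)
from .ssa import (
    CellState,
    SimOptions,
    advance_cell,
    effective_rates,
    partition_at_division,
    replicate_promoters,
)

__all__ = [
    "ProtocolSpec",
    "PopulationSnapshot",
    "LineageLog",
    "ProtocolResult",
    "LineageNode",
    "init_population",
    "run_protocol",
    "trace_lineage",
]


@dataclass
class ProtocolSpec:
    """Two-phase induction protocol with an optional mid-course subsample."""

    protocol: str = "custom"          # "22h" | "5h" | "custom"
    n_initial: int = 1000
    pre_duration: float = 660.0       # min
    inducer_pre: float = 0.0          # galactose % w/v during the first phase
    sample_size: int | None = 2000    # None: no subsampling between phases
    post_duration: float = 660.0      # min
    inducer_post: float = 0.0
    snapshot_interval: float | None = None  # min; None records endpoints only
    chemistry: bool = True            # False: growth/division only

    def __post_init__(self) -> None:
        if self.n_initial < 1:
            raise ValueError("n_initial must be >= 1")
        if self.pre_duration < 0 or self.post_duration < 0:
            raise ValueError("durations must be >= 0")
        if self.snapshot_interval is not None and self.snapshot_interval <= 0:
            raise ValueError("snapshot_interval must be > 0")

    @classmethod
    def twenty_two_hour(cls, galactose: float, **overrides) -> "ProtocolSpec":
        kw = dict(
            protocol="22h",
            n_initial=1000,
            pre_duration=660.0,
            inducer_pre=galactose,
            sample_size=2000,
            post_duration=660.0,
            inducer_post=galactose,
        )
        kw.update(overrides)
        return cls(**kw)

    @classmethod
    def five_hour(cls, galactose: float, **overrides) -> "ProtocolSpec":
        kw = dict(
            protocol="5h",
            n_initial=20_000,
            pre_duration=300.0,
            inducer_pre=0.0,
            sample_size=20_000,
            post_duration=300.0,
            inducer_post=galactose,
        )
        kw.update(overrides)
        return cls(**kw)


@dataclass
class PopulationSnapshot:
    """One row per live cell at a fixed time."""

    time: float
    cells: pd.DataFrame

    def reporter_counts(self) -> np.ndarray:
        col = [c for c in self.cells.columns if c.startswith("protein_")]
        if not col:
            raise ValueError("snapshot carries no molecular state")
        return self.cells[col[0]].to_numpy()


@dataclass
class LineageLog:
    """Division records and per-cell time series."""

    divisions: list[tuple] = field(default_factory=list)  # (time, mother, daughter, V_m, V_d)
    births: dict = field(default_factory=dict)            # cell_id -> (parent_id, birth_time)
    traces: dict = field(default_factory=dict)            # cell_id -> [(t, V, reporter_count)]
    Vref: float = 1.0

    def record_division(self, time, mother, daughter, V_m, V_d) -> None:
        self.divisions.append((time, mother, daughter, V_m, V_d))
        self.births[daughter] = (mother, time)

    def record_point(self, cell: CellState) -> None:
        rep = int(cell.protein[0]) if cell.n_genes else 0
        self.traces.setdefault(cell.cell_id, []).append((cell.t, cell.V, rep))


@dataclass
class LineageNode:
    """Subtree of descendants with per-cell (time, volume, concentration) series."""

    cell_id: int
    series: list[tuple]  # (time, volume, reporter concentration = count*Vref/V)
    children: list["LineageNode"] = field(default_factory=list)

    def node_count(self) -> int:
        return 1 + sum(c.node_count() for c in self.children)


@dataclass
class ProtocolResult:
    final_snapshot: PopulationSnapshot
    lineage: LineageLog
    snapshots: list[PopulationSnapshot]
    population: list[CellState]


def _sample_noise(cv: float, rng: np.random.Generator) -> np.ndarray:
    """One multiplicative Normal(1, cv) factor per process category,
    redrawn while non-positive."""
    out = rng.normal(1.0, cv, size=len(PROCESS_CATEGORIES))
    while np.any(out <= 0):
        bad = out <= 0
        out[bad] = rng.normal(1.0, cv, size=int(bad.sum()))
    return out


def _noisy_rate_table(rt: RateTable, noise: np.ndarray) -> RateTable:
    idx = {name: i for i, name in enumerate(PROCESS_CATEGORIES)}
    return RateTable(
        r_act=rt.r_act * noise[idx["promoter"]],
        r_off=rt.r_off * noise[idx["promoter"]],
        rm_true=rt.rm_true * noise[idx["transcription"]],
        b_true=rt.b_true,
        r_p=rt.r_p * noise[idx["translation"]],
        d_m=rt.d_m * noise[idx["mrna_decay"]],
        d_p=rt.d_p * noise[idx["protein_decay"]],
        n_promoter=rt.n_promoter,
    )


def init_population(
    n: int,
    spec: NetworkSpec | None,
    popn: CellCyclePopulationParams,
    rng: np.random.Generator,
    options: SimOptions | None = None,
) -> list[CellState]:
    """Initialize ``n`` cells with per-cell parameters, exponential ages and
    basal-steady-state molecular content.

    Each cell draws its cycle parameters from the population distributions
    and one extrinsic noise factor per process category (Normal(1, CV),
    shared across genes).  Cell age is sampled Exponential(mean doubling
    time), reduced modulo the cell's own cycle length, and mapped to the
    deterministic volume trajectory; mRNA/protein counts are the rounded
    basal fixed point of the cell's own (noise-perturbed) rates, with each
    promoter copy ON with the fixed-point probability.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    options = options or SimOptions()
    base_rt = spec.rate_table() if spec is not None else None
    n_genes = spec.n_genes if spec is not None else 0
    cells: list[CellState] = []
    for cid in range(n):
        params = popn.sample(rng)
        noise = (
            _sample_noise(spec.noise_cv, rng)
            if spec is not None
            else np.ones(len(PROCESS_CATEGORIES))
        )
        age = rng.exponential(popn.mean_cycle_length)
        position = position_at_age(age, params, popn.t1_combiner)
        V = volume_at(position, params)
        if spec is not None:
            rt = _noisy_rate_table(base_rt, noise)
            mrna_mean, protein_mean, phi = basal_steady_state(spec, rt)
            mrna = np.rint(mrna_mean).astype(np.int64)
            protein = np.rint(protein_mean).astype(np.int64)
            pr_on = rng.binomial(rt.n_promoter, phi).astype(np.int64)
            pr_off = rt.n_promoter - pr_on
        else:
            mrna = np.zeros(0, dtype=np.int64)
            protein = np.zeros(0, dtype=np.int64)
            pr_on = np.zeros(0, dtype=np.int64)
            pr_off = np.zeros(0, dtype=np.int64)
        cell = CellState(
            cell_id=cid,
            parent_id=-1,
            birth_time=0.0,
            generation=0,
            t=0.0,
            V=V,
            position=position,
            params=params,
            noise=noise,
            pr_on=pr_on,
            pr_off=pr_off,
            mrna=mrna,
            protein=protein,
            replicated=False,
        )
        if position.block == "T3" and n_genes:
            replicate_promoters(cell)  # cells embedded past S entry carry 2n promoters
        cells.append(cell)
    return cells


def _advance_growth_only(cell: CellState, t_end: float) -> str | None:
    """Deterministic volume/cycle advance; returns DIVISION if reached."""
    eps = 1e-12
    if cell.t >= t_end - eps:
        return None
    _, pos, events = grow(cell.position, cell.params, t_end - cell.t)
    for ev in events:
        if ev.kind == DIVISION:
            cell.t += ev.time
            # stop the position exactly at the division point
            _, pos_div, _ = grow(cell.position, cell.params, ev.time)
            cell.position = pos_div
            cell.V = volume_at(pos_div, cell.params)
            return DIVISION
    cell.position = pos
    cell.V = volume_at(pos, cell.params)
    cell.t = t_end
    return None


class _Runner:
    """Single-threaded deterministic population scheduler."""

    def __init__(
        self,
        spec: NetworkSpec | None,
        popn: CellCyclePopulationParams,
        seed: int,
        options: SimOptions,
        noise_inheritance: bool = False,
    ) -> None:
        self.spec = spec
        self.popn = popn
        self.seed = int(seed)
        self.options = options
        self.noise_inheritance = noise_inheritance
        self.log = LineageLog(Vref=spec.Vref if spec is not None else 1.0)
        self._rngs: dict[int, np.random.Generator] = {}
        self._rates: dict[int, object] = {}
        self._next_id = 0
        self._base_rt = spec.rate_table() if spec is not None else None

    def new_id(self) -> int:
        cid = self._next_id
        self._next_id += 1
        return cid

    def rng_for(self, cell_id: int) -> np.random.Generator:
        if cell_id not in self._rngs:
            self._rngs[cell_id] = np.random.Generator(
                np.random.PCG64(np.random.SeedSequence((self.seed, cell_id)))
            )
        return self._rngs[cell_id]

    def rates_for(self, cell: CellState):
        if self.spec is None:
            return None
        r = self._rates.get(cell.cell_id)
        if r is None:
            r = effective_rates(self._base_rt, cell.noise)
            self._rates[cell.cell_id] = r
        return r

    def forget(self, cell_id: int) -> None:
        self._rngs.pop(cell_id, None)
        self._rates.pop(cell_id, None)

    def _divide_cell(self, cell: CellState) -> tuple[CellState, CellState]:
        rng = self.rng_for(cell.cell_id)
        V_m, V_d = divide(cell.V, cell.params)
        d_params = self.popn.inherit(cell.params, rng)
        if self.spec is not None and not self.noise_inheritance:
            d_noise = _sample_noise(self.spec.noise_cv, rng)
        else:
            d_noise = cell.noise.copy()
        mother, daughter = partition_at_division(
            cell,
            V_m,
            V_d,
            rng,
            daughter_params=d_params,
            daughter_noise=d_noise,
            daughter_id=self.new_id(),
            t1_combiner=self.popn.t1_combiner,
        )
        self._rates.pop(mother.cell_id, None)  # noise unchanged but keep map tidy
        self.log.record_division(mother.t, mother.cell_id, daughter.cell_id, V_m, V_d)
        return mother, daughter

    def advance_population(
        self, cells: list[CellState], t_end: float, inducer: float
    ) -> list[CellState]:
        queue = deque(cells)
        out: list[CellState] = []
        while queue:
            cell = queue.popleft()
            while True:
                if self.spec is not None:
                    res = advance_cell(
                        cell,
                        self.spec,
                        inducer,
                        t_end,
                        self.rng_for(cell.cell_id),
                        rates=self.rates_for(cell),
                        options=self.options,
                    )
                else:
                    res = _advance_growth_only(cell, t_end)
                if res != DIVISION:
                    break
                cell, daughter = self._divide_cell(cell)
                queue.append(daughter)
            out.append(cell)
        out.sort(key=lambda c: c.cell_id)
        return out


def _snapshot(cells: list[CellState], time: float, spec: NetworkSpec | None) -> PopulationSnapshot:
    rec: dict[str, list] = {
        "cell_id": [c.cell_id for c in cells],
        "parent_id": [c.parent_id for c in cells],
        "volume": [c.V for c in cells],
        "block": [c.position.block for c in cells],
        "generation": [c.generation for c in cells],
        "birth_time": [c.birth_time for c in cells],
    }
    if spec is not None:
        for i, name in enumerate(spec.gene_names):
            rec[f"mrna_{name}"] = [int(c.mrna[i]) for c in cells]
            rec[f"protein_{name}"] = [int(c.protein[i]) for c in cells]
    return PopulationSnapshot(time=time, cells=pd.DataFrame(rec))


def run_protocol(
    protocol: ProtocolSpec,
    network: NetworkSpec | None,
    popn: CellCyclePopulationParams,
    seed: int = 0,
    options: SimOptions | None = None,
    noise_inheritance: bool = False,
) -> ProtocolResult:
    """Run a two-phase induction protocol.

    ``network=None`` (or ``protocol.chemistry=False``) runs the growth and
    division machinery alone, which is orders of magnitude faster and
    sufficient for demographic questions (population counts, generation
    census).  Identical ``seed`` and configuration reproduce the output
    bit-exactly.
    """
    options = options or SimOptions()
    spec = network if protocol.chemistry else None
    runner = _Runner(spec, popn, seed, options)
    init_rng = np.random.Generator(
        np.random.PCG64(np.random.SeedSequence((int(seed), 0x5EED)))
    )
    cells = init_population(protocol.n_initial, spec, popn, init_rng, options)
    runner._next_id = len(cells)
    for c in cells:
        runner.log.births[c.cell_id] = (-1, 0.0)

    snapshots: list[PopulationSnapshot] = [_snapshot(cells, 0.0, spec)]
    if protocol.snapshot_interval is not None:
        for c in cells:
            runner.log.record_point(c)

    def run_phase(cells: list[CellState], t0: float, t1: float, inducer: float):
        if t1 <= t0:
            return cells
        if protocol.snapshot_interval is None:
            cells = runner.advance_population(cells, t1, inducer)
            snapshots.append(_snapshot(cells, t1, spec))
            return cells
        t = t0
        while t < t1 - 1e-9:
            t_next = min(t1, t + protocol.snapshot_interval)
            cells = runner.advance_population(cells, t_next, inducer)
            for c in cells:
                runner.log.record_point(c)
            t = t_next
        snapshots.append(_snapshot(cells, t1, spec))
        return cells

    cells = run_phase(cells, 0.0, protocol.pre_duration, protocol.inducer_pre)
    if not cells:
        raise RuntimeError("population went extinct")

    if protocol.sample_size is not None and protocol.post_duration > 0:
        if protocol.sample_size > len(cells):
            raise ValueError(
                f"sample size {protocol.sample_size} exceeds population size {len(cells)}"
            )
        sample_rng = np.random.Generator(
            np.random.PCG64(np.random.SeedSequence((int(seed), 0x5A3D)))
        )
        keep = sample_rng.choice(len(cells), size=protocol.sample_size, replace=False)
        keep.sort()
        kept = [cells[i] for i in keep]
        dropped = set(c.cell_id for c in cells) - set(c.cell_id for c in kept)
        for cid in dropped:
            runner.forget(cid)
        cells = kept

    cells = run_phase(
        cells,
        protocol.pre_duration,
        protocol.pre_duration + protocol.post_duration,
        protocol.inducer_post,
    )
    if not cells:
        raise RuntimeError("population went extinct")

    return ProtocolResult(
        final_snapshot=snapshots[-1],
        lineage=runner.log,
        snapshots=snapshots,
        population=cells,
    )


def trace_lineage(log: LineageLog, root_cell_id: int) -> LineageNode:
    """Descendant tree of a cell with per-cell (time, volume, concentration)
    series; concentration is the reporter count scaled to the reference
    volume, ``count * Vref / V``."""
    ids = set(log.traces.keys()) | set(log.births.keys())
    for t, m, d, *_ in log.divisions:
        ids.add(m)
        ids.add(d)
    if root_cell_id not in ids:
        raise KeyError(f"unknown cell id {root_cell_id}")
    children: dict[int, list[int]] = {}
    for t, m, d, *_ in log.divisions:
        children.setdefault(m, []).append(d)

    def build(cid: int) -> LineageNode:
        series = [
            (t, V, (rep * log.Vref / V if V > 0 else 0.0))
            for (t, V, rep) in log.traces.get(cid, [])
        ]
        return LineageNode(
            cell_id=cid,
            series=series,
            children=[build(d) for d in sorted(children.get(cid, []))],
        )

    return build(root_cell_id)
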