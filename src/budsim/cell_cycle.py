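"""Asymmetric cell growth and division model for budding yeast.

The cell cycle is split into two volume-growth stages — G1 (linear growth at
rate ``r1``) and S/G2/M (linear growth at rate ``r2``) — and three time blocks:

* **T1**: from cycle start (birth, or re-entry after division) until *start*,
  the size-licensed G1 commitment point.  *Start* is reached at volume
  ``Vs = k*r1 + b``; ``T1min`` bounds the block from below for cells born
  large enough to pass the threshold immediately.
* **T2**: the brief interval from *start* to S-phase entry, still growing at
  ``r1``.
* **T3**: all of S/G2/M, growing at ``r2``.  Of this growth, ``r2m`` is
  attributable to the mother compartment and ``r2 - r2m`` to the bud, which
  becomes the daughter at division.

Divisions are asymmetric: the daughter receives the bud volume
``(r2 - r2m) * T3`` and begins its own cycle at T1, while the mother keeps the
remainder and immediately re-enters T1.  Per-cell growth parameters are drawn
from population normal distributions and partially inherited by daughters
through a convex combination controlled by ``c_inherit``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterator

import numpy as np

__all__ = [
    "CellCycleParams",
    "CellCyclePopulationParams",
    "CyclePosition",
    "CycleEvent",
    "Normal",
    "START_REACHED",
    "S_ENTRY",
    "DIVISION",
    "volume_at_start",
    "t1_duration",
    "grow",
    "divide",
    "inherit_params",
    "new_cycle",
    "position_at_age",
    "volume_at",
    "time_to_division",
]

# Event kinds emitted by grow() at block boundaries.
START_REACHED = "START_REACHED"  # T1 -> T2
S_ENTRY = "S_ENTRY"              # T2 -> T3 (promoter replication point)
DIVISION = "DIVISION"            # end of T3

#: Per-cell parameters drawn from a population distribution.
DISTRIBUTED_FIELDS = ("Vi", "r1", "r2", "r2m", "T1min", "T2", "T3")


@dataclass(frozen=True)
class CellCycleParams:
    """Growth and division parameters of a single cell.

    Units: volumes in fL, rates in fL/min, durations in min.
    """

    Vi: float        # volume at birth of a founder cell
    r1: float        # G1 (T1+T2) volume growth rate
    r2: float        # overall S/G2/M growth rate
    r2m: float       # mother-compartment share of r2; bud grows at r2 - r2m
    T1min: float     # lower bound on the T1 block
    T2: float        # start -> S-entry duration
    T3: float        # S/G2/M duration
    k: float         # slope of the start-size rule Vs = k*r1 + b
    b: float         # intercept of the start-size rule
    c_inherit: float  # daughter inheritance weight in [0, 1]

    def __post_init__(self) -> None:
        for name in (*DISTRIBUTED_FIELDS, "k", "b"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        if not 0.0 <= self.c_inherit <= 1.0:
            raise ValueError(f"c_inherit must lie in [0, 1], got {self.c_inherit}")
        if self.r2m > self.r2:
            raise ValueError(
                f"r2m ({self.r2m}) exceeds r2 ({self.r2}): bud growth would be negative"
            )


@dataclass(frozen=True)
class Normal:
    """A (mean, sd) pair; sampling redraws until the value is non-negative."""

    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError(f"sd must be >= 0, got {self.sd}")

    def sample(self, rng: np.random.Generator) -> float:
        x = rng.normal(self.mean, self.sd)
        while x < 0:
            x = rng.normal(self.mean, self.sd)
        return x


@dataclass(frozen=True)
class CellCyclePopulationParams:
    """Population-level distributions of the per-cell growth parameters.

    Each distributed parameter follows a truncated (non-negative) normal;
    ``k``, ``b`` and ``c_inherit`` are shared constants.  ``t1_combiner``
    selects how the size-threshold time and ``T1min`` are combined into T1
    (``"max"``: T1min is a lower bound; ``"min"``: literal minimum).
    """

    Vi: Normal
    r1: Normal
    r2: Normal
    r2m: Normal
    T1min: Normal
    T2: Normal
    T3: Normal
    k: float
    b: float
    c_inherit: float
    t1_combiner: str = "max"

    def __post_init__(self) -> None:
        if self.t1_combiner not in ("max", "min"):
            raise ValueError(f"t1_combiner must be 'max' or 'min', got {self.t1_combiner!r}")
        if not 0.0 <= self.c_inherit <= 1.0:
            raise ValueError(f"c_inherit must lie in [0, 1], got {self.c_inherit}")

    @property
    def mean_cycle_length(self) -> float:
        """Mean T1min + T2 + T3: the nominal doubling time when the size rule
        is satisfied at birth (min)."""
        return self.T1min.mean + self.T2.mean + self.T3.mean

    def sample(self, rng: np.random.Generator) -> CellCycleParams:
        """Draw a fresh, uncorrelated parameter set for a founder cell."""
        draws = {name: getattr(self, name).sample(rng) for name in DISTRIBUTED_FIELDS}
        draws["r2m"] = min(draws["r2m"], draws["r2"])  # keep bud growth >= 0
        return CellCycleParams(k=self.k, b=self.b, c_inherit=self.c_inherit, **draws)

    def inherit(self, parent: CellCycleParams, rng: np.random.Generator) -> CellCycleParams:
        return inherit_params(parent, self, rng)


def volume_at_start(r1: float, k: float, b: float) -> float:
    """Volume ``Vs = k*r1 + b`` at which *start* is licensed."""
    if r1 < 0:
        raise ValueError(f"r1 must be >= 0, got {r1}")
    vs = k * r1 + b
    if vs < 0:
        raise ValueError(f"start volume k*r1 + b = {vs} is negative; parameters inconsistent")
    return vs


def t1_duration(
    V0: float, Vs: float, r1: float, T1min: float, combiner: str = "max"
) -> float:
    """Duration of the T1 block for a cell starting its cycle at volume ``V0``.

    The size-threshold time is ``(Vs - V0)/r1`` (0 when the cell is already
    past the start size).  With ``combiner="max"`` (default) ``T1min`` acts as
    a lower bound on T1; ``combiner="min"`` applies a literal minimum of the
    two instead.
    """
    if V0 >= Vs:
        t_size = 0.0
    else:
        if r1 <= 0:
            raise ValueError("r1 = 0 with V0 < Vs: start size is never reached")
        t_size = (Vs - V0) / r1
    if combiner == "max":
        return max(T1min, t_size)
    if combiner == "min":
        return min(T1min, t_size)
    raise ValueError(f"unknown T1 combiner {combiner!r}")


@dataclass(frozen=True)
class CyclePosition:
    """Where a cell is within its current cycle.

    ``T1`` is the realized duration of the first block for this cycle, fixed
    at cycle start from the cell's ``V0`` and growth rate.
    """

    block: str       # "T1" | "T2" | "T3"
    clock: float     # time elapsed within the current block (min)
    V0: float        # volume at the start of this cycle (fL)
    T1: float        # realized T1 duration for this cycle (min)

    def __post_init__(self) -> None:
        if self.block not in ("T1", "T2", "T3"):
            raise ValueError(f"unknown block {self.block!r}")
        if self.clock < 0:
            raise ValueError(f"clock must be >= 0, got {self.clock}")


@dataclass(frozen=True)
class CycleEvent:
    kind: str    # START_REACHED | S_ENTRY | DIVISION
    time: float  # offset from the beginning of the grow() call (min)


def new_cycle(V0: float, params: CellCycleParams, combiner: str = "max") -> CyclePosition:
    """Position at the very beginning of a fresh cycle with start volume V0."""
    vs = volume_at_start(params.r1, params.k, params.b)
    t1 = t1_duration(V0, vs, params.r1, params.T1min, combiner)
    return CyclePosition(block="T1", clock=0.0, V0=V0, T1=t1)


def _block_duration(position: CyclePosition, params: CellCycleParams, block: str) -> float:
    if block == "T1":
        return position.T1
    if block == "T2":
        return params.T2
    return params.T3


def _growth_rate(block: str, params: CellCycleParams) -> float:
    return params.r1 if block in ("T1", "T2") else params.r2


def volume_at(position: CyclePosition, params: CellCycleParams) -> float:
    """Deterministic volume implied by a cycle position."""
    v = position.V0
    if position.block == "T1":
        return v + params.r1 * position.clock
    v += params.r1 * position.T1
    if position.block == "T2":
        return v + params.r1 * position.clock
    v += params.r1 * params.T2
    return v + params.r2 * position.clock


def time_to_division(position: CyclePosition, params: CellCycleParams) -> float:
    """Remaining time until the end of T3 from the given position."""
    if position.block == "T1":
        return (position.T1 - position.clock) + params.T2 + params.T3
    if position.block == "T2":
        return (params.T2 - position.clock) + params.T3
    return params.T3 - position.clock


_NEXT_BLOCK = {"T1": "T2", "T2": "T3"}
_BOUNDARY_EVENT = {"T1": START_REACHED, "T2": S_ENTRY, "T3": DIVISION}


def grow(
    position: CyclePosition, params: CellCycleParams, dt: float
) -> tuple[float, CyclePosition, list[CycleEvent]]:
    """Advance a cell deterministically by ``dt`` minutes.

    Returns the new volume, the new position and the list of boundary events
    crossed, each stamped with its exact offset from the start of the call.
    Advancement stops at DIVISION (any remaining ``dt`` is not consumed); the
    caller is expected to divide the cell and resume from the post-division
    state.
    """
    if dt < 0:
        raise ValueError(f"dt must be >= 0, got {dt}")
    events: list[CycleEvent] = []
    block, clock = position.block, position.clock
    elapsed = 0.0
    remaining = dt
    while True:
        dur = _block_duration(position, params, block)
        to_boundary = dur - clock
        if remaining < to_boundary:
            clock += remaining
            break
        # cross the boundary (equality included, so zero-length blocks advance)
        elapsed += to_boundary
        remaining -= to_boundary
        events.append(CycleEvent(_BOUNDARY_EVENT[block], elapsed))
        if block == "T3":
            clock = dur  # stop exactly at division
            break
        block = _NEXT_BLOCK[block]
        clock = 0.0
    new_position = replace(position, block=block, clock=clock)
    return volume_at(new_position, params), new_position, events


def divide(V_total: float, params: CellCycleParams) -> tuple[float, float]:
    """Split the pre-division volume between mother and daughter.

    The daughter is the bud grown over S/G2/M: ``V_daughter = (r2 - r2m)*T3``.
    Volume is conserved exactly.
    """
    v_daughter = (params.r2 - params.r2m) * params.T3
    if v_daughter <= 0:
        raise ValueError(
            f"daughter volume (r2-r2m)*T3 = {v_daughter} is not positive (r2={params.r2}, "
            f"r2m={params.r2m}, T3={params.T3})"
        )
    if v_daughter >= V_total:
        raise ValueError(
            f"daughter volume {v_daughter} is not smaller than the total volume {V_total}"
        )
    return V_total - v_daughter, v_daughter


def inherit_params(
    parent: CellCycleParams,
    popn: CellCyclePopulationParams,
    rng: np.random.Generator,
) -> CellCycleParams:
    """Daughter parameters: ``c*parent + (1-c)*fresh`` per distributed field.

    ``fresh`` values are independent truncated-normal draws from the
    population distributions; ``k``, ``b`` and ``c_inherit`` pass through
    unchanged.
    """
    c = parent.c_inherit
    draws = {}
    for name in DISTRIBUTED_FIELDS:
        fresh = getattr(popn, name).sample(rng)
        draws[name] = c * getattr(parent, name) + (1 - c) * fresh
    draws["r2m"] = min(draws["r2m"], draws["r2"])
    return CellCycleParams(k=parent.k, b=parent.b, c_inherit=c, **draws)


def position_at_age(
    age: float, params: CellCycleParams, combiner: str = "max"
) -> CyclePosition:
    """Embed a sampled age into a cycle position.

    The age is reduced modulo the cell's own realized cycle length
    (T1 + T2 + T3 from a fresh cycle at ``V0 = Vi``) and the position advanced
    deterministically to that point.
    """
    if age < 0:
        raise ValueError(f"age must be >= 0, got {age}")
    pos = new_cycle(params.Vi, params, combiner)
    cycle_len = pos.T1 + params.T2 + params.T3
    phase = age % cycle_len if cycle_len > 0 else 0.0
    _, pos, _ = grow(pos, params, phase)
    return pos
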