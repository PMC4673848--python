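"""Exact stochastic simulation of a gene network inside a growing cell.

Each gene contributes seven reaction channels (promoter activation and
inactivation, basal and full transcription, mRNA decay, translation, protein
decay); cell volume growth is an eighth, shared channel that fires at rate
``growth_rate / dV`` and adds a fixed quantum ``dV`` to the volume, so the
realized trajectory converges to the deterministic piecewise-linear growth
curve as ``dV -> 0``.  Concentration-dependent propensities carry a
``Vref / V`` factor, which makes synthesis and decay track the cell's dilution
state as it grows.

Deterministic cell-cycle events (start, S entry, division) are interleaved
with the chemistry by the next-event-time method: a sampled reaction that
would land past the next scheduled boundary is rejected, the state is advanced
to the boundary, and propensities are recomputed.  At S entry every promoter
copy replicates in place, preserving its ON/OFF state; at division mRNA and
protein are partitioned binomially with p = V_daughter / V_total and promoter
copies are dealt out state-preservingly, n copies to each cell.

The inner reaction loop is JIT-compiled (numba) and operates on flat per-cell
arrays; the pure-Python :func:`compute_propensities` / :func:`step` pair
expresses the same reaction semantics one event at a time and is used for
direct unit-level verification.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from numba import njit

from .cell_cycle import (
    DIVISION,
    S_ENTRY,
    START_REACHED,
    CellCycleParams,
    CyclePosition,
    grow,
)
from .gene_network import PROCESS_CATEGORIES, NetworkSpec, RateTable

__all__ = [
    "CellState",
    "SimOptions",
    "EffectiveRates",
    "compute_propensities",
    "step",
    "advance_cell",
    "replicate_promoters",
    "partition_at_division",
    "CHANNELS_PER_GENE",
]

#: Reaction channels per gene, in propensity-vector order.
CHANNELS_PER_GENE = 7
_CH_ACT, _CH_INACT, _CH_BASAL_TX, _CH_FULL_TX, _CH_MRNA_DECAY, _CH_TRANSLATION, _CH_PROT_DECAY = range(7)


@dataclass
class SimOptions:
    """Numerical knobs of the stochastic engine."""

    dV: float = 0.02                     # volume quantum (fL)
    scale_first_order: str = "scaled"    # "scaled": decay carries Vref/V; "conventional": it does not
    t1_combiner: str = "max"             # see cell_cycle.t1_duration

    def __post_init__(self) -> None:
        if self.dV <= 0:
            raise ValueError(f"dV must be > 0, got {self.dV}")
        if self.scale_first_order not in ("scaled", "conventional"):
            raise ValueError(f"unknown scale_first_order {self.scale_first_order!r}")


@dataclass
class CellState:
    """Full state of one simulated cell."""

    cell_id: int
    parent_id: int            # -1 for founders
    birth_time: float         # min
    generation: int           # replicative age: divisions completed as a mother
    t: float                  # current simulation time (min)
    V: float                  # volume (fL)
    position: CyclePosition
    params: CellCycleParams
    noise: np.ndarray         # one factor per PROCESS_CATEGORIES entry
    pr_on: np.ndarray         # per-gene ON promoter copies (int64)
    pr_off: np.ndarray        # per-gene OFF promoter copies (int64)
    mrna: np.ndarray          # per-gene mRNA counts (int64)
    protein: np.ndarray       # per-gene protein counts (int64)
    replicated: bool = False  # promoters doubled this cycle

    def copy(self) -> "CellState":
        return replace(
            self,
            noise=self.noise.copy(),
            pr_on=self.pr_on.copy(),
            pr_off=self.pr_off.copy(),
            mrna=self.mrna.copy(),
            protein=self.protein.copy(),
        )

    @property
    def n_genes(self) -> int:
        return len(self.mrna)

    def growth_rate(self) -> float:
        return self.params.r1 if self.position.block in ("T1", "T2") else self.params.r2


@dataclass(frozen=True)
class EffectiveRates:
    """Per-cell mechanistic rates with the extrinsic noise factors folded in."""

    r_act: np.ndarray
    r_off: np.ndarray
    rm_basal: np.ndarray   # rm_true * b_true, transcription noise applied
    rm_full: np.ndarray    # rm_true, transcription noise applied
    r_p: np.ndarray
    d_m: np.ndarray
    d_p: np.ndarray


def effective_rates(rt: RateTable, noise: np.ndarray) -> EffectiveRates:
    """Fold one cell's per-process noise factors into the network rate table."""
    idx = {name: i for i, name in enumerate(PROCESS_CATEGORIES)}
    return EffectiveRates(
        r_act=rt.r_act * noise[idx["promoter"]],
        r_off=rt.r_off * noise[idx["promoter"]],
        rm_basal=rt.rm_true * rt.b_true * noise[idx["transcription"]],
        rm_full=rt.rm_true * noise[idx["transcription"]],
        r_p=rt.r_p * noise[idx["translation"]],
        d_m=rt.d_m * noise[idx["mrna_decay"]],
        d_p=rt.d_p * noise[idx["protein_decay"]],
    )


def compute_propensities(
    state: CellState,
    spec: NetworkSpec,
    inducer: float,
    rates: EffectiveRates | None = None,
    options: SimOptions | None = None,
) -> np.ndarray:
    """Propensity vector: 7 channels per gene followed by the volume channel."""
    options = options or SimOptions()
    if rates is None:
        rates = effective_rates(spec.rate_table(), state.noise)
    n = state.n_genes
    scale = spec.Vref / state.V
    dscale = scale if options.scale_first_order == "scaled" else 1.0
    F = spec.activity(state.protein, state.V, inducer)
    a = np.empty(CHANNELS_PER_GENE * n + 1)
    for x in range(n):
        base = CHANNELS_PER_GENE * x
        a[base + _CH_ACT] = rates.r_act[x] * F * state.pr_off[x]
        a[base + _CH_INACT] = rates.r_off[x] * state.pr_on[x]
        a[base + _CH_BASAL_TX] = rates.rm_basal[x] * state.pr_off[x] * scale
        a[base + _CH_FULL_TX] = rates.rm_full[x] * state.pr_on[x] * scale
        a[base + _CH_MRNA_DECAY] = rates.d_m[x] * state.mrna[x] * dscale
        a[base + _CH_TRANSLATION] = rates.r_p[x] * state.mrna[x] * scale
        a[base + _CH_PROT_DECAY] = rates.d_p[x] * state.protein[x] * dscale
    a[-1] = state.growth_rate() / options.dV
    return a


def _apply_channel(state: CellState, channel: int, options: SimOptions) -> None:
    if channel == CHANNELS_PER_GENE * state.n_genes:  # volume channel
        state.V += options.dV
        return
    x, ch = divmod(channel, CHANNELS_PER_GENE)
    if ch == _CH_ACT:
        state.pr_off[x] -= 1
        state.pr_on[x] += 1
    elif ch == _CH_INACT:
        state.pr_on[x] -= 1
        state.pr_off[x] += 1
    elif ch in (_CH_BASAL_TX, _CH_FULL_TX):
        state.mrna[x] += 1
    elif ch == _CH_MRNA_DECAY:
        state.mrna[x] -= 1
    elif ch == _CH_TRANSLATION:
        state.protein[x] += 1
    else:
        state.protein[x] -= 1


def _time_to_next_boundary(state: CellState) -> float:
    pos, p = state.position, state.params
    if pos.block == "T1":
        return pos.T1 - pos.clock
    if pos.block == "T2":
        return p.T2 - pos.clock
    return p.T3 - pos.clock


def _advance_clock(state: CellState, dt: float) -> list:
    """Move the cycle clock forward by dt (no boundary processing beyond the
    position bookkeeping); returns the crossed boundary events."""
    _, pos, events = grow(state.position, state.params, dt)
    state.position = pos
    return events


def step(
    state: CellState,
    spec: NetworkSpec,
    inducer: float,
    rng: np.random.Generator,
    rates: EffectiveRates | None = None,
    options: SimOptions | None = None,
) -> tuple[CellState, float, int | str]:
    """One hybrid step: either a single SSA reaction fires, or the state is
    advanced to the next scheduled cycle boundary, whichever comes first.

    Returns ``(state, elapsed, fired)`` where ``fired`` is the reaction
    channel index, or one of the cycle-event kind strings when a boundary was
    processed instead.  The state is modified in place.  At ``S_ENTRY``
    promoters are replicated; at ``DIVISION`` the caller must partition.
    """
    options = options or SimOptions()
    a = compute_propensities(state, spec, inducer, rates, options)
    total = float(a.sum())
    if total <= 0.0:
        raise ValueError("total propensity is not positive")
    tau = rng.exponential(1.0 / total)
    t_boundary = _time_to_next_boundary(state)
    if tau >= t_boundary:
        # reject the sampled reaction; process the deterministic event
        events = _advance_clock(state, t_boundary)
        state.t += t_boundary
        kind = events[-1].kind if events else START_REACHED
        if kind == S_ENTRY:
            replicate_promoters(state)
        return state, t_boundary, kind
    channel = int(np.searchsorted(np.cumsum(a), rng.random() * total, side="right"))
    channel = min(channel, len(a) - 1)
    _apply_channel(state, channel, options)
    _advance_clock(state, tau)
    state.t += tau
    return state, tau, channel


def replicate_promoters(state: CellState) -> CellState:
    """Double every promoter copy at S entry, preserving ON/OFF states."""
    if state.replicated:
        raise ValueError(
            f"cell {state.cell_id}: promoters already replicated this cycle"
        )
    state.pr_on *= 2
    state.pr_off *= 2
    state.replicated = True
    return state


def partition_at_division(
    state: CellState,
    V_mother: float,
    V_daughter: float,
    rng: np.random.Generator,
    spec: NetworkSpec | None = None,
    daughter_params: CellCycleParams | None = None,
    daughter_noise: np.ndarray | None = None,
    daughter_id: int | None = None,
    t1_combiner: str = "max",
) -> tuple[CellState, CellState]:
    """Split a dividing cell into mother and daughter states.

    mRNA and protein counts are partitioned per species by independent
    binomial draws with p = V_daughter / V_total; the 2n promoter copies per
    gene are dealt n to each cell with ON/OFF state preserved per copy
    (hypergeometric split of the ON copies).  The mother increments its
    generation counter and re-enters T1 at V_mother; the daughter starts at
    generation 0 with the supplied inherited parameters and noise factors.
    """
    V_total = state.V
    if not math.isclose(V_mother + V_daughter, V_total, rel_tol=1e-9, abs_tol=1e-9):
        raise ValueError(
            f"V_mother + V_daughter = {V_mother + V_daughter} != pre-division volume {V_total}"
        )
    if min(V_mother, V_daughter) <= 0:
        raise ValueError("both compartments must have positive volume")
    p_d = V_daughter / V_total
    n = state.n_genes

    d_mrna = rng.binomial(state.mrna, p_d).astype(np.int64)
    d_protein = rng.binomial(state.protein, p_d).astype(np.int64)
    m_mrna = state.mrna - d_mrna
    m_protein = state.protein - d_protein

    n_base = state.pr_on + state.pr_off
    if state.replicated:
        n_per_cell = n_base // 2
    else:  # division without replication: promoters stay with the mother
        n_per_cell = n_base
    d_on = np.empty(n, dtype=np.int64)
    d_off = np.empty(n, dtype=np.int64)
    for x in range(n):
        if state.replicated:
            d_on[x] = rng.hypergeometric(state.pr_on[x], state.pr_off[x], n_per_cell[x])
        else:
            d_on[x] = 0
        d_off[x] = (n_per_cell[x] - d_on[x]) if state.replicated else 0
    m_on = state.pr_on - d_on
    m_off = state.pr_off - d_off

    params = state.params
    from .cell_cycle import new_cycle  # local import to avoid cycle at module load

    mother = replace(
        state,
        t=state.t,
        V=V_mother,
        position=new_cycle(V_mother, params, t1_combiner),
        generation=state.generation + 1,
        pr_on=m_on,
        pr_off=m_off,
        mrna=m_mrna,
        protein=m_protein,
        replicated=False,
    )
    d_params = daughter_params if daughter_params is not None else params
    d_noise = (
        daughter_noise if daughter_noise is not None else np.ones_like(state.noise)
    )
    daughter = CellState(
        cell_id=daughter_id if daughter_id is not None else -1,
        parent_id=state.cell_id,
        birth_time=state.t,
        generation=0,
        t=state.t,
        V=V_daughter,
        position=new_cycle(V_daughter, d_params, t1_combiner),
        params=d_params,
        noise=d_noise,
        pr_on=d_on,
        pr_off=d_off,
        mrna=d_mrna,
        protein=d_protein,
        replicated=False,
    )
    return mother, daughter


# --------------------------------------------------------------------------
# JIT-compiled segment simulator
# --------------------------------------------------------------------------

@njit(fastmath=False)
def _ssa_segment(
    rng,
    t: float,
    t_end: float,
    V: float,
    pr_on, pr_off, mrna, protein,          # int64 arrays, modified in place
    r_act, r_off, rm_basal, rm_full, r_p, d_m, d_p,  # effective per-cell rates
    Vref: float,
    growth_rate: float,
    dV: float,
    scale_decay: bool,
    f_mode: int,                            # 0: constant F, 1: GAL form
    f_const: float,
    S3: float, S1: float, S80: float, alpha: float, beta: float, g: float,
    i3: int, i1: int, i80: int,
):
    """Simulate the chemistry+volume channels over [t, t_end].

    The cycle block (hence growth rate) is constant within the segment; the
    caller slices the timeline at cycle boundaries and snapshot times.
    Returns the final volume.
    """
    nG = pr_on.shape[0]
    nch = 7 * nG
    a = np.empty(nch + 1)
    a_vol = growth_rate / dV
    while True:
        scale = Vref / V
        dscale = scale if scale_decay else 1.0
        if f_mode == 0:
            F = f_const
        else:
            act = (S3 * g * protein[i3] + S1 * g * protein[i1]) * scale
            denom = 1.0 + act ** alpha
            ratio = S80 * protein[i80] * scale / denom
            if ratio <= 0.0:
                F = 1.0
            else:
                lt = beta * np.log(ratio)
                F = 0.0 if lt > 700.0 else 1.0 / (1.0 + np.exp(lt))
        total = a_vol
        for x in range(nG):
            base = 7 * x
            a[base] = r_act[x] * F * pr_off[x]
            a[base + 1] = r_off[x] * pr_on[x]
            a[base + 2] = rm_basal[x] * pr_off[x] * scale
            a[base + 3] = rm_full[x] * pr_on[x] * scale
            a[base + 4] = d_m[x] * mrna[x] * dscale
            a[base + 5] = r_p[x] * mrna[x] * scale
            a[base + 6] = d_p[x] * protein[x] * dscale
            total += (
                a[base] + a[base + 1] + a[base + 2] + a[base + 3]
                + a[base + 4] + a[base + 5] + a[base + 6]
            )
        if total <= 0.0:
            return V  # absorbing: nothing can fire (static, non-growing cell)
        tau = rng.exponential(1.0 / total)
        if t + tau > t_end:
            return V
        t += tau
        u = rng.random() * total
        if u >= total - a_vol:
            V += dV
            continue
        acc = 0.0
        fired = nch - 1
        for c in range(nch):
            acc += a[c]
            if u < acc:
                fired = c
                break
        x = fired // 7
        ch = fired - 7 * x
        if ch == 0:
            pr_off[x] -= 1
            pr_on[x] += 1
        elif ch == 1:
            pr_on[x] -= 1
            pr_off[x] += 1
        elif ch == 2 or ch == 3:
            mrna[x] += 1
        elif ch == 4:
            mrna[x] -= 1
        elif ch == 5:
            protein[x] += 1
        else:
            protein[x] -= 1


def _form_encoding(spec: NetworkSpec, inducer: float):
    """Flatten the functional form into kernel arguments."""
    form = spec.functional_form
    if form.kind == "constant":
        return (0, form.value, 0.0, 0.0, 1.0, 1.0, 1.0, 0.0, 0, 0, 0)
    p = form.params
    i3, i1, i80 = form.regulator_indices(spec.gene_names)
    return (1, 0.0, p.S3, p.S1, p.S80, p.alpha, p.beta, p.g(inducer), i3, i1, i80)


def advance_cell(
    state: CellState,
    spec: NetworkSpec,
    inducer: float,
    t_end: float,
    rng: np.random.Generator,
    rates: EffectiveRates | None = None,
    options: SimOptions | None = None,
) -> str | None:
    """Run one cell forward to ``t_end`` or to its next division.

    Chemistry is simulated with the JIT kernel in segments delimited by cycle
    boundaries.  Returns ``DIVISION`` if the cell reached the end of T3
    (state left exactly at the division point, not yet partitioned), else
    ``None`` when ``t_end`` was reached.
    """
    options = options or SimOptions()
    if rates is None:
        rates = effective_rates(spec.rate_table(), state.noise)
    enc = _form_encoding(spec, inducer)
    scale_decay = options.scale_first_order == "scaled"
    eps = 1e-12
    while state.t < t_end - eps:
        dt_boundary = _time_to_next_boundary(state)
        crossed = state.t + dt_boundary <= t_end
        # advance the clock by the exact boundary increment when the segment
        # ends at a boundary: t + dt_boundary can round back to t for tiny
        # residuals, which would otherwise stall the clock short of the event
        dt_step = dt_boundary if crossed else t_end - state.t
        seg_end = state.t + dt_step
        if dt_step > eps:
            state.V = _ssa_segment(
                rng,
                state.t,
                seg_end,
                state.V,
                state.pr_on, state.pr_off, state.mrna, state.protein,
                rates.r_act, rates.r_off, rates.rm_basal, rates.rm_full,
                rates.r_p, rates.d_m, rates.d_p,
                spec.Vref,
                state.growth_rate(),
                options.dV,
                scale_decay,
                *enc,
            )
        events = _advance_clock(state, dt_step)
        state.t = seg_end
        if crossed and events:
            kind = events[-1].kind
            if kind == S_ENTRY:
                replicate_promoters(state)
            elif kind == DIVISION:
                return DIVISION
    return None
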