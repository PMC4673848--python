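"""Shared fixtures and synthetic-data helpers for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from budsim.cell_cycle import CellCycleParams, CyclePosition, new_cycle
from budsim.config import default_cell_cycle, default_gal_network
from budsim.gene_network import ConstantActivity, GeneSpec, NetworkSpec
from budsim.phenotype import PhenotypeSeries
from budsim.ssa import CellState


@pytest.fixture
def rng():
    return np.random.Generator(np.random.PCG64(12345))


@pytest.fixture
def popn():
    """Default cell-cycle population parameters (120-min mean cycle)."""
    return default_cell_cycle()


@pytest.fixture
def gal_network():
    return default_gal_network()


@pytest.fixture
def base_params():
    """A deterministic parameter set at the population means."""
    return CellCycleParams(
        Vi=30.0, r1=0.25, r2=0.45, r2m=0.15, T1min=30.0, T2=15.0, T3=75.0,
        k=40.0, b=20.0, c_inherit=0.25,
    )


def make_single_gene_network(
    F: float = 1.0,
    r_act_max: float = 0.2,
    f_active: float = 0.5,
    rm_obs: float = 1.0,
    b_obs: float = 0.0,
    r_p: float = 0.5,
    d_m: float = 0.1,
    d_p: float = 0.02,
    Vref: float = 45.0,
) -> NetworkSpec:
    """One-gene network with a constant activity plug-in: the engine then
    reduces to the analytically solvable telegraph/birth-death chain."""
    gene = GeneSpec(
        name="G0", r_act_max=r_act_max, f_active=f_active, rm_obs=rm_obs,
        b_obs=b_obs, r_p=r_p, d_m=d_m, d_p=d_p,
    )
    return NetworkSpec(genes=[gene], functional_form=ConstantActivity(F), Vref=Vref)


def make_cell(
    network: NetworkSpec,
    params: CellCycleParams,
    V: float | None = None,
    pr_on: int = 1,
    pr_off: int = 0,
    mrna: int = 0,
    protein: int = 0,
    cell_id: int = 0,
) -> CellState:
    n = network.n_genes
    position = new_cycle(params.Vi if V is None else V, params)
    return CellState(
        cell_id=cell_id,
        parent_id=-1,
        birth_time=0.0,
        generation=0,
        t=0.0,
        V=params.Vi if V is None else V,
        position=position,
        params=params,
        noise=np.ones(5),
        pr_on=np.full(n, pr_on, dtype=np.int64),
        pr_off=np.full(n, pr_off, dtype=np.int64),
        mrna=np.full(n, mrna, dtype=np.int64),
        protein=np.full(n, protein, dtype=np.int64),
    )


def frozen_cycle_params(T_block: float = 1e9) -> CellCycleParams:
    """Parameters whose T3 is effectively infinite: the cell never divides
    within any finite test horizon (fixed-volume chemistry checks)."""
    return CellCycleParams(
        Vi=45.0, r1=0.0, r2=0.0, r2m=0.0, T1min=T_block, T2=T_block, T3=T_block,
        k=0.0, b=20.0, c_inherit=0.25,
    )


def simulate_telegraph_series(
    n_cells: int,
    k_on_per_h: float,
    k_off_per_h: float,
    T_h: float,
    interval_h: float,
    rng: np.random.Generator,
    het_cv: float = 0.0,
    start_on: bool = False,
) -> PhenotypeSeries:
    """Exact two-state trajectories sampled on a regular grid.

    Times are recorded in minutes (the package-wide unit).  ``het_cv`` adds
    lognormal per-cell rate heterogeneity with that coefficient of variation
    (mean preserved), emulating extrinsic noise.
    """
    series = PhenotypeSeries(threshold=1.0)
    n_steps = int(round(T_h / interval_h))
    for i in range(n_cells):
        if het_cv > 0:
            sig = np.sqrt(np.log(1.0 + het_cv**2))
            ki = k_on_per_h * rng.lognormal(-sig**2 / 2.0, sig)
            ko = k_off_per_h * rng.lognormal(-sig**2 / 2.0, sig)
        else:
            ki, ko = k_on_per_h, k_off_per_h
        state = start_on
        t_next = rng.exponential(1.0 / (ko if state else ki))
        series.add(i, 0.0, state)
        for step_i in range(1, n_steps + 1):
            t_query = step_i * interval_h
            while t_next <= t_query:
                state = not state
                t_next += rng.exponential(1.0 / (ko if state else ki))
            series.add(i, t_query * 60.0, state)
    return series
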