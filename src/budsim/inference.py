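"""Fitting network parameters to single-cell fluorescence distributions.

The free parameters of the GAL instantiation are the promoter kinetics
(``r_act_max`` and ``f_active``) of the three promoter groups — the shared
reporter/GAL1 promoter, GAL3 and GAL80 — plus the functional-form scales
``S3``, ``S1`` and the Hill exponent ``beta``: nine parameters in total
(``S80`` is fixed by convention because only the ratio of scales matters once
the activator term dominates).

An evaluation of a candidate parameter vector runs ``N_R`` independent
simulation repeats (each repeat simulates every experimental condition),
converts reporter counts to fluorescence and scores them against the
experimental histograms via :func:`budsim.fluorescence.fit_conversion_factor`;
the mean over repeats is the score.  Optimization is sweep-seeded
Nelder-Mead: a coarse grid identifies promising (preferably
bimodality-producing) starting points, from which the simplex refines.
Positive scale parameters are optimized in log10 space.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Any, Mapping, Sequence

import numpy as np
from scipy.optimize import minimize
from sklearn.mixture import GaussianMixture

from .fluorescence import fit_conversion_factor
from .gene_network import NetworkSpec
from .population import ProtocolSpec, run_protocol
from .ssa import SimOptions

__all__ = [
    "FreeParameter",
    "Condition",
    "FitConfig",
    "FitResult",
    "set_parameters",
    "get_parameters",
    "simulate_counts",
    "evaluate",
    "sweep",
    "fit",
    "is_bimodal",
]

#: Default box constraints by field kind.
DEFAULT_BOUNDS = {
    "r_act_max": (1e-4, 10.0),
    "f_active": (0.01, 1.0),
    "S3": (1e-3, 1e6),
    "S1": (1e-3, 1e6),
    "beta": (0.5, 8.0),
}
#: Fields optimized as log10(value).
LOG_SCALE_FIELDS = {"r_act_max", "S3", "S1"}


@dataclass(frozen=True)
class FreeParameter:
    """One free parameter: a (target, field) pair with bounds and a sweep grid.

    ``target`` is a gene name, or the string ``"functional_form"``.
    """

    target: str
    fld: str
    bounds: tuple[float, float] | None = None
    grid: tuple[float, ...] = ()

    @property
    def name(self) -> str:
        return f"{self.target}.{self.fld}"

    @property
    def log_scale(self) -> bool:
        return self.fld in LOG_SCALE_FIELDS

    def effective_bounds(self) -> tuple[float, float]:
        if self.bounds is not None:
            return self.bounds
        if self.fld in DEFAULT_BOUNDS:
            return DEFAULT_BOUNDS[self.fld]
        raise ValueError(f"no bounds known for field {self.fld!r}")


@dataclass(frozen=True)
class Condition:
    """One experimental condition: inducer level and induction protocol."""

    galactose: float
    protocol: ProtocolSpec
    label: str = ""

    def key(self) -> str:
        return self.label or f"{self.protocol.protocol}:{self.galactose:g}"


@dataclass
class FitConfig:
    free_parameters: list[FreeParameter]
    conditions: list[Condition]
    n_repeats: int = 4            # N_R: simulation repeats per evaluation
    n_fluor_restarts: int = 8     # background redraws inside the c-fit
    seed: int = 0
    max_evaluations: int = 50     # Nelder-Mead budget per stage
    sweep_repeats: int = 1        # reduced N_R during the sweep
    common_random_numbers: bool = False  # reuse one seed across evaluations

    def __post_init__(self) -> None:
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")
        if not self.conditions:
            raise ValueError("at least one condition is required")


@dataclass
class FitResult:
    parameters: dict[str, float]
    score: float
    c_fluo: float
    score_trajectory: list[float]
    n_evaluations: int
    start_point: dict[str, float]


def set_parameters(
    network: NetworkSpec, free: Sequence[FreeParameter], values: Sequence[float]
) -> None:
    """Write a parameter vector into the network (ties re-applied)."""
    if len(free) != len(values):
        raise ValueError("parameter vector length mismatch")
    for p, v in zip(free, values):
        lo, hi = p.effective_bounds()
        if not lo <= v <= hi:
            raise ValueError(f"{p.name} = {v} outside bounds [{lo}, {hi}]")
        network.set_parameter(p.target, p.fld, float(v))


def get_parameters(network: NetworkSpec, free: Sequence[FreeParameter]) -> np.ndarray:
    out = []
    for p in free:
        if p.target == "functional_form":
            out.append(getattr(network.functional_form.params, p.fld))
        else:
            out.append(getattr(network.gene(p.target), p.fld))
    return np.array(out, dtype=float)


def simulate_counts(
    network: NetworkSpec,
    condition: Condition,
    popn,
    seed: int,
    options: SimOptions | None = None,
) -> np.ndarray:
    """Reporter counts of the final population for one condition."""
    proto = condition.protocol
    if proto.inducer_post != condition.galactose:
        proto = replace(
            proto,
            inducer_post=condition.galactose,
            inducer_pre=(
                condition.galactose if proto.protocol == "22h" else proto.inducer_pre
            ),
        )
    res = run_protocol(proto, network, popn, seed=seed, options=options)
    return res.final_snapshot.reporter_counts()


def evaluate(
    values: Sequence[float],
    config: FitConfig,
    network: NetworkSpec,
    popn,
    data: Mapping[str, np.ndarray],
    rng: np.random.Generator,
    n_repeats: int | None = None,
    options: SimOptions | None = None,
) -> tuple[float, float]:
    """Score one parameter vector: mean over N_R repeats of the maximized
    fluorescence log-likelihood across all conditions.

    Returns ``(score, best c)``.  A repeat whose simulation fails is dropped
    with a warning; if every repeat fails the evaluation errors out.
    """
    import warnings

    set_parameters(network, config.free_parameters, values)
    reps = n_repeats if n_repeats is not None else config.n_repeats
    scores, cs = [], []
    for _ in range(reps):
        rep_seed = (
            config.seed if config.common_random_numbers else int(rng.integers(2**31 - 1))
        )
        try:
            R_sets, E_sets = [], []
            for cond in config.conditions:
                key = cond.key()
                if key not in data:
                    raise KeyError(f"no experimental data for condition {key!r}")
                R_sets.append(simulate_counts(network, cond, popn, rep_seed, options))
                E_sets.append(np.asarray(data[key], dtype=float))
            c_best, ll = fit_conversion_factor(
                R_sets, E_sets, rng, n_restarts=config.n_fluor_restarts
            )
        except (RuntimeError, FloatingPointError) as exc:  # simulation failure
            warnings.warn(f"repeat discarded: {exc}")
            continue
        scores.append(ll)
        cs.append(c_best)
    if not scores:
        raise RuntimeError("all simulation repeats failed")
    best = int(np.argmax(scores))
    return float(np.mean(scores)), float(cs[best])


def is_bimodal(counts: np.ndarray, margin: float = 10.0) -> bool:
    """Crude bimodality flag on log reporter counts.

    True when a two-component Gaussian mixture improves the total
    log-likelihood over one component by more than ``margin`` and the two
    component means are separated by at least one decade in natural log
    (~0.43 decades in log10).
    """
    x = np.log(np.asarray(counts, dtype=float) + 1.0).reshape(-1, 1)
    if len(np.unique(x)) < 3:
        return False
    gm1 = GaussianMixture(1, random_state=0).fit(x)
    gm2 = GaussianMixture(2, random_state=0, n_init=3).fit(x)
    gain = (gm2.score(x) - gm1.score(x)) * len(x)
    means = np.sort(gm2.means_.ravel())
    return bool(gain > margin and (means[1] - means[0]) > 1.0)


def _to_internal(p: FreeParameter, v: float) -> float:
    return math.log10(v) if p.log_scale else v


def _from_internal(p: FreeParameter, u: float) -> float:
    lo, hi = p.effective_bounds()
    v = 10.0**u if p.log_scale else u
    return min(max(v, lo), hi)


def sweep(
    config: FitConfig,
    network: NetworkSpec,
    popn,
    data: Mapping[str, np.ndarray],
    options: SimOptions | None = None,
) -> list[dict[str, Any]]:
    """Evaluate the Cartesian sweep grid at reduced N_R.

    Returns grid points sorted best-score-first, each flagged with whether it
    produced a bimodal reporter distribution in any condition (the flag is
    for seeding only; it does not enter the score).
    """
    grids = []
    for p in config.free_parameters:
        grids.append(p.grid if p.grid else (get_parameters(network, [p])[0],))
    mesh = np.meshgrid(*grids, indexing="ij")
    points = np.stack([m.ravel() for m in mesh], axis=-1)
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence((config.seed, 0xF17))))
    results = []
    for vec in points:
        score, c_best = evaluate(
            vec, config, network, popn, data, rng,
            n_repeats=config.sweep_repeats, options=options,
        )
        # bimodality of the last repeat's first condition, cheap re-simulation
        set_parameters(network, config.free_parameters, vec)
        counts = simulate_counts(
            network, config.conditions[0], popn, seed=config.seed, options=options
        )
        results.append(
            {
                "values": {p.name: float(v) for p, v in zip(config.free_parameters, vec)},
                "vector": np.asarray(vec, dtype=float),
                "score": score,
                "c_fluo": c_best,
                "bimodal": is_bimodal(counts),
            }
        )
    results.sort(key=lambda r: -r["score"])
    return results


def fit(
    config: FitConfig,
    network: NetworkSpec,
    popn,
    data: Mapping[str, np.ndarray],
    options: SimOptions | None = None,
    start: Sequence[float] | None = None,
) -> FitResult:
    """Sweep-seeded Nelder-Mead maximization of the fluorescence likelihood.

    If ``start`` is omitted the sweep is run first and the best
    (bimodality-preferred) grid point seeds the simplex.  The stage budget is
    expressed in objective evaluations (``config.max_evaluations``).
    """
    free = config.free_parameters
    if not free:
        rng0 = np.random.Generator(np.random.PCG64(np.random.SeedSequence((config.seed, 0xF31))))
        score, c_best = evaluate([], config, network, popn, data, rng0, options=options)
        return FitResult(parameters={}, score=score, c_fluo=c_best,
                         score_trajectory=[score], n_evaluations=1, start_point={})
    if start is None:
        ranked = sweep(config, network, popn, data, options)
        preferred = [r for r in ranked if r["bimodal"]] or ranked
        start = preferred[0]["vector"]
    start = np.asarray(start, dtype=float)
    start_named = {p.name: float(v) for p, v in zip(free, start)}

    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence((config.seed, 0xF31))))
    trajectory: list[float] = []
    best: dict[str, Any] = {"score": -np.inf, "c": np.nan, "vec": start.copy()}
    n_eval = 0

    def objective(u: np.ndarray) -> float:
        nonlocal n_eval
        vec = np.array([_from_internal(p, ui) for p, ui in zip(free, u)])
        score, c_best = evaluate(vec, config, network, popn, data, rng, options=options)
        n_eval += 1
        trajectory.append(score)
        if score > best["score"]:
            best.update(score=score, c=c_best, vec=vec)
        return -score

    u0 = np.array([_to_internal(p, v) for p, v in zip(free, start)])
    minimize(
        objective,
        u0,
        method="Nelder-Mead",
        options={
            "maxfev": config.max_evaluations,
            "xatol": 1e-3,
            "fatol": 0.5,  # log-likelihood units; stochastic objective
        },
    )
    set_parameters(network, free, best["vec"])
    return FitResult(
        parameters={p.name: float(v) for p, v in zip(free, best["vec"])},
        score=float(best["score"]),
        c_fluo=float(best["c"]),
        score_trajectory=trajectory,
        n_evaluations=n_eval,
        start_point=start_named,
    )
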