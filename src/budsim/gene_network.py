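"""Two-state-promoter gene network model and the GAL-network activity function.

Every gene (a fluorescent reporter G0 plus network genes G1..GN) carries seven
stochastic reactions: promoter activation/inactivation, transcription from the
OFF (basal, leaky) and ON promoter states, mRNA decay, translation, and
protein decay.  The promoter activation rate is modulated by a network
*functional form* ``F`` in [0, 1] computed from regulator concentrations and
the inducer level: ``r_ON = r_act_max * F``.

Parameters are specified in their *observed* form — the population-level mRNA
synthesis rate ``rm_obs`` and basal fraction ``b_obs`` a molecular biologist
would measure — and converted to the mechanistic ON-state rates used by the
simulator via :func:`derive_rates`:

    f_active = r_act_max / (r_act_max + r_off)
    rm_obs   = rm_true * f_active + b_true * rm_true * (1 - f_active)
    b_obs * rm_obs = b_true * rm_true

Concentrations are expressed in count-at-reference-volume units: a cell of
volume ``V`` with ``P`` protein copies has concentration ``P * Vref / V``, so
at ``V = Vref`` concentration equals copy number.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np

__all__ = [
    "GeneSpec",
    "DerivedRates",
    "FunctionalFormParams",
    "GalFunctionalForm",
    "ConstantActivity",
    "NetworkSpec",
    "RateTable",
    "PROCESS_CATEGORIES",
    "derive_rates",
    "gal_functional_form",
    "promoter_activation_rate",
    "basal_steady_state",
]

#: Process categories sharing one extrinsic (per-cell) noise factor each.
PROCESS_CATEGORIES = (
    "promoter",        # activation and inactivation rates
    "transcription",   # basal and full transcription
    "mrna_decay",
    "translation",
    "protein_decay",
)


@dataclass(frozen=True)
class GeneSpec:
    """Observed-scale stochastic parameters of one gene (rates per minute)."""

    name: str
    r_act_max: float       # maximum promoter activation rate (1/min)
    f_active: float        # fully-induced active fraction, in (0, 1]
    rm_obs: float          # observed mRNA synthesis rate (mRNA/min/promoter)
    b_obs: float           # observed basal expression fraction, in [0, 1]
    r_p: float             # translation rate (protein/(mRNA*min))
    d_m: float             # mRNA degradation rate (1/min)
    d_p: float             # protein degradation rate (1/min)
    n_promoter_G1: int = 1  # promoter copies before DNA replication

    def __post_init__(self) -> None:
        if not 0.0 < self.f_active <= 1.0:
            raise ValueError(f"{self.name}: f_active must lie in (0, 1], got {self.f_active}")
        if not 0.0 <= self.b_obs <= 1.0:
            raise ValueError(f"{self.name}: b_obs must lie in [0, 1], got {self.b_obs}")
        for attr in ("r_act_max", "rm_obs", "r_p", "d_m", "d_p"):
            if getattr(self, attr) < 0:
                raise ValueError(f"{self.name}: {attr} must be >= 0, got {getattr(self, attr)}")
        if self.n_promoter_G1 < 1:
            raise ValueError(f"{self.name}: n_promoter_G1 must be >= 1")


@dataclass(frozen=True)
class DerivedRates:
    """Mechanistic rates implied by a :class:`GeneSpec`."""

    r_off: float    # promoter inactivation rate (1/min)
    rm_true: float  # ON-state transcription rate (mRNA/min/promoter)
    b_true: float   # OFF/ON transcription ratio, in [0, 1]


def derive_rates(spec: GeneSpec) -> DerivedRates:
    """Convert observed (rm_obs, b_obs) to mechanistic (r_off, rm_true, b_true).

    Inverts the forward relations given in the module docstring; the round
    trip reproduces the observed values to machine precision.
    """
    f = spec.f_active
    r_off = spec.r_act_max * (1.0 - f) / f
    rm_true = spec.rm_obs * (1.0 - spec.b_obs * (1.0 - f)) / f
    if rm_true > 0:
        b_true = spec.b_obs * spec.rm_obs / rm_true
    else:
        b_true = 0.0
    if b_true > 1.0 + 1e-12:
        raise ValueError(
            f"{spec.name}: derived OFF/ON ratio b_true = {b_true} > 1; "
            "observed parameters are inconsistent with a leaky two-state promoter"
        )
    return DerivedRates(r_off=r_off, rm_true=rm_true, b_true=min(b_true, 1.0))


@dataclass(frozen=True)
class FunctionalFormParams:
    """Scale parameters of the GAL-network activity function."""

    S3: float            # scale of Gal3p action
    S1: float            # scale of Gal1p action
    S80: float = 4500.0  # scale of Gal80p action (fixed by convention)
    alpha: float = 1.0   # inner exponent
    beta: float = 2.0    # outer Hill exponent
    g_model: str = "linear"  # inducer coupling: "linear" or "saturating"
    g_K: float = 0.05    # half-saturation (% w/v) for the saturating form

    def __post_init__(self) -> None:
        for attr in ("S3", "S1", "S80"):
            if getattr(self, attr) <= 0:
                raise ValueError(f"{attr} must be > 0, got {getattr(self, attr)}")
        if self.beta <= 0:
            raise ValueError(f"beta must be > 0, got {self.beta}")
        if self.g_model not in ("linear", "saturating"):
            raise ValueError(f"unknown g_model {self.g_model!r}")

    def g(self, galactose: float) -> float:
        """Inducer coupling g(galactose); galactose in % w/v."""
        if galactose < 0:
            raise ValueError(f"galactose must be >= 0, got {galactose}")
        if self.g_model == "linear":
            return galactose
        return galactose / (self.g_K + galactose)


def gal_functional_form(
    conc_gal3p: float,
    conc_gal1p: float,
    conc_gal80p: float,
    inducer: float,
    params: FunctionalFormParams,
) -> float:
    """GAL-network activity F in [0, 1].

    F = 1 / (1 + (S80*[Gal80p] / (1 + (S3*g*[Gal3p] + S1*g*[Gal1p])**alpha))**beta)

    Monotone increasing in the activators Gal3p/Gal1p, decreasing in the
    repressor Gal80p.  With no repressor F = 1.
    """
    if min(conc_gal3p, conc_gal1p, conc_gal80p) < 0:
        raise ValueError("concentrations must be >= 0")
    g = params.g(inducer)
    activator = params.S3 * g * conc_gal3p + params.S1 * g * conc_gal1p
    denom = 1.0 + activator**params.alpha
    ratio = params.S80 * conc_gal80p / denom
    if ratio == 0.0:
        return 1.0
    # guard against overflow for extreme repressor excess
    log_term = params.beta * math.log(ratio)
    if log_term > 700.0:
        return 0.0
    return 1.0 / (1.0 + math.exp(log_term))


class GalFunctionalForm:
    """GAL activity plug-in: binds :class:`FunctionalFormParams` to the gene
    names playing the Gal3p/Gal1p/Gal80p roles."""

    kind = "gal"

    def __init__(
        self,
        params: FunctionalFormParams,
        regulators: Mapping[str, str] | None = None,
    ) -> None:
        self.params = params
        self.regulators = dict(
            regulators or {"gal3": "GAL3", "gal1": "GAL1", "gal80": "GAL80"}
        )
        for role in ("gal3", "gal1", "gal80"):
            if role not in self.regulators:
                raise ValueError(f"missing regulator role {role!r}")

    def regulator_indices(self, gene_names: Sequence[str]) -> tuple[int, int, int]:
        idx = {name: i for i, name in enumerate(gene_names)}
        try:
            return (
                idx[self.regulators["gal3"]],
                idx[self.regulators["gal1"]],
                idx[self.regulators["gal80"]],
            )
        except KeyError as exc:
            raise ValueError(f"regulator gene {exc} not present in the network") from exc

    def activity(
        self, concentrations: Mapping[str, float] | np.ndarray, inducer: float,
        gene_names: Sequence[str] | None = None,
    ) -> float:
        if isinstance(concentrations, Mapping):
            c3 = concentrations[self.regulators["gal3"]]
            c1 = concentrations[self.regulators["gal1"]]
            c80 = concentrations[self.regulators["gal80"]]
        else:
            if gene_names is None:
                raise ValueError("gene_names required with array concentrations")
            i3, i1, i80 = self.regulator_indices(gene_names)
            c3, c1, c80 = concentrations[i3], concentrations[i1], concentrations[i80]
        return gal_functional_form(c3, c1, c80, inducer, self.params)


class ConstantActivity:
    """Degenerate functional form: F is a constant, independent of state.

    Useful for validating the stochastic engine against single-gene
    birth-death and telegraph closed forms.
    """

    kind = "constant"

    def __init__(self, value: float = 1.0) -> None:
        if not 0.0 <= value <= 1.0:
            raise ValueError(f"F must lie in [0, 1], got {value}")
        self.value = value

    def activity(self, concentrations, inducer, gene_names=None) -> float:
        return self.value


@dataclass(frozen=True)
class RateTable:
    """Per-gene rate arrays (mechanistic scale) cached for the simulator."""

    r_act: np.ndarray
    r_off: np.ndarray
    rm_true: np.ndarray
    b_true: np.ndarray
    r_p: np.ndarray
    d_m: np.ndarray
    d_p: np.ndarray
    n_promoter: np.ndarray


@dataclass
class NetworkSpec:
    """An N-component network: ordered genes (reporter first), the activity
    plug-in, the reference volume and the extrinsic-noise level."""

    genes: list[GeneSpec]
    functional_form: GalFunctionalForm | ConstantActivity
    Vref: float = 45.0               # reference volume (fL)
    noise_cv: float = 0.10           # CV of the per-cell per-process factors
    tied_parameters: list[tuple[str, str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError("network must contain at least the reporter gene")
        if self.Vref <= 0:
            raise ValueError(f"Vref must be > 0, got {self.Vref}")
        if self.noise_cv < 0:
            raise ValueError(f"noise_cv must be >= 0, got {self.noise_cv}")
        names = [g.name for g in self.genes]
        if len(set(names)) != len(names):
            raise ValueError("gene names must be unique")
        for ga, gb, fld in self.tied_parameters:
            for name in (ga, gb):
                if name not in names:
                    raise ValueError(f"tied_parameters references unknown gene {name!r}")
            if not hasattr(self.genes[0], fld):
                raise ValueError(f"tied_parameters references unknown field {fld!r}")
        self.apply_ties()

    @property
    def gene_names(self) -> list[str]:
        return [g.name for g in self.genes]

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    def gene(self, name: str) -> GeneSpec:
        for g in self.genes:
            if g.name == name:
                return g
        raise KeyError(name)

    def apply_ties(self) -> None:
        """Copy each tied field from the first gene of the pair to the second."""
        by_name = {g.name: i for i, g in enumerate(self.genes)}
        for ga, gb, fld in self.tied_parameters:
            src = self.genes[by_name[ga]]
            dst = self.genes[by_name[gb]]
            self.genes[by_name[gb]] = replace(dst, **{fld: getattr(src, fld)})

    def set_parameter(self, gene_name: str, fld: str, value: float) -> None:
        """Update one gene parameter (or ``functional_form`` scalar) and
        re-propagate ties."""
        if gene_name == "functional_form":
            self.functional_form = GalFunctionalForm(
                replace(self.functional_form.params, **{fld: value}),
                self.functional_form.regulators,
            )
            return
        by_name = {g.name: i for i, g in enumerate(self.genes)}
        i = by_name[gene_name]
        self.genes[i] = replace(self.genes[i], **{fld: value})
        self.apply_ties()

    def rate_table(self) -> RateTable:
        derived = [derive_rates(g) for g in self.genes]
        return RateTable(
            r_act=np.array([g.r_act_max for g in self.genes]),
            r_off=np.array([d.r_off for d in derived]),
            rm_true=np.array([d.rm_true for d in derived]),
            b_true=np.array([d.b_true for d in derived]),
            r_p=np.array([g.r_p for g in self.genes]),
            d_m=np.array([g.d_m for g in self.genes]),
            d_p=np.array([g.d_p for g in self.genes]),
            n_promoter=np.array([g.n_promoter_G1 for g in self.genes], dtype=np.int64),
        )

    def activity(self, protein_counts: np.ndarray, volume: float, inducer: float) -> float:
        """F evaluated at the given cell state (counts scaled to Vref units)."""
        conc = np.asarray(protein_counts, dtype=float) * (self.Vref / volume)
        return self.functional_form.activity(conc, inducer, gene_names=self.gene_names)


def promoter_activation_rate(gene: GeneSpec, F: float) -> float:
    """ON-switching rate r_ON = r_act_max * F."""
    if not 0.0 <= F <= 1.0:
        raise ValueError(f"F must lie in [0, 1], got {F}")
    return gene.r_act_max * F


def basal_steady_state(
    spec: NetworkSpec,
    rates: RateTable | None = None,
    inducer: float = 0.0,
    start: np.ndarray | None = None,
    tol: float = 1e-6,
    max_iter: int = 10_000,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Deterministic basal fixed point at ``V = Vref``.

    Iterates the mean-field map — protein concentrations -> F -> per-gene ON
    fraction ``phi = r_on/(r_on + r_off)`` -> mean mRNA
    ``rm_true*(phi + b_true*(1-phi))*n_promoter/d_m`` -> mean protein
    ``r_p*mRNA/d_p`` — to convergence (relative change < ``tol``).

    Returns (mean mRNA, mean protein, ON-state probability) arrays.
    """
    rt = rates if rates is not None else spec.rate_table()
    n = spec.n_genes
    protein = np.zeros(n) if start is None else np.asarray(start, dtype=float).copy()
    mrna = np.zeros(n)
    phi = np.zeros(n)
    for _ in range(max_iter):
        F = spec.activity(protein, spec.Vref, inducer)
        r_on = rt.r_act * F
        with np.errstate(invalid="ignore"):
            phi = np.where(r_on + rt.r_off > 0, r_on / (r_on + rt.r_off), 1.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            mrna = np.where(
                rt.d_m > 0,
                rt.rm_true * (phi + rt.b_true * (1.0 - phi)) * rt.n_promoter / rt.d_m,
                0.0,
            )
            new_protein = np.where(rt.d_p > 0, rt.r_p * mrna / rt.d_p, 0.0)
        denom = np.maximum(np.abs(protein), 1.0)
        if np.all(np.abs(new_protein - protein) / denom < tol):
            return mrna, new_protein, phi
        protein = new_protein
    raise RuntimeError(f"basal steady state did not converge in {max_iter} iterations")
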