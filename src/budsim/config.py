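"""Configuration schema, defaults, and YAML loading.

A run configuration has five sections — ``cell_cycle``, ``network``,
``protocol``, ``sim`` and ``fit`` — plus a master ``seed`` and an ``output``
section.  :func:`load_config` validates the file against the schema (unknown
keys are rejected with an error naming them), fills defaults, and exposes
constructed model objects.

Shipped defaults describe a haploid budding-yeast strain with a 120-min mean
doubling time and the four-gene GAL circuit (reporter, GAL1, GAL3, GAL80).
The cell-cycle numbers are calibrated so that both newborn daughters and
experienced mothers complete a cycle in ~120 min on average: daughters are
born at the bud volume (r2-r2m)*T3 = 22.5 fL and need the full start-size
rule to license *start*, mothers re-enter G1 above the start size and wait
only T1min.  Gene-expression defaults are literature-anchored order-of-
magnitude values (basal mRNA ~1 per cell, induced protein ~10^3) — the
fitted fluorescence conversion factor absorbs their overall scale.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

from .cell_cycle import CellCyclePopulationParams, Normal
from .gene_network import (
    FunctionalFormParams,
    GalFunctionalForm,
    GeneSpec,
    NetworkSpec,
)
from .population import ProtocolSpec
from .ssa import SimOptions

__all__ = [
    "RunConfig",
    "DEFAULT_CONFIG",
    "load_config",
    "dump_config",
    "config_from_dict",
    "default_cell_cycle",
    "default_gal_network",
]


DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 0,
    "cell_cycle": {
        "Vi": {"mean": 30.0, "sd": 3.0},
        "r1": {"mean": 0.25, "sd": 0.025},
        "r2": {"mean": 0.45, "sd": 0.045},
        "r2m": {"mean": 0.15, "sd": 0.015},
        "T1min": {"mean": 30.0, "sd": 3.0},
        "T2": {"mean": 15.0, "sd": 1.5},
        "T3": {"mean": 75.0, "sd": 7.5},
        "k": 40.0,
        "b": 20.0,
        "c_inherit": 0.25,
        "t1_combiner": "max",
    },
    "network": {
        "Vref": 45.0,
        "noise_cv": 0.10,
        "genes": [
            {
                "name": "YFP",
                "r_act_max": 0.1,
                "f_active": 0.5,
                "rm_obs": 1.0,
                "b_obs": 0.01,
                "r_p": 0.5,
                "d_m": 0.05,
                "d_p": 0.01,
                "n_promoter_G1": 1,
            },
            {
                "name": "GAL1",
                "r_act_max": 0.1,
                "f_active": 0.5,
                "rm_obs": 1.0,
                "b_obs": 0.01,
                "r_p": 0.5,
                "d_m": 0.05,
                "d_p": 0.01,
                "n_promoter_G1": 1,
            },
            {
                "name": "GAL3",
                "r_act_max": 0.1,
                "f_active": 0.5,
                "rm_obs": 1.0,
                "b_obs": 0.01,
                "r_p": 0.5,
                "d_m": 0.05,
                "d_p": 0.01,
                "n_promoter_G1": 1,
            },
            {
                "name": "GAL80",
                "r_act_max": 0.1,
                "f_active": 0.5,
                "rm_obs": 0.2,
                "b_obs": 0.5,
                "r_p": 0.5,
                "d_m": 0.05,
                "d_p": 0.01,
                "n_promoter_G1": 1,
            },
        ],
        "functional_form": {
            "S3": 50000.0,
            "S1": 5000.0,
            "S80": 4500.0,
            "alpha": 1.0,
            "beta": 3.0,
            "g_model": "linear",
            "g_K": 0.05,
            "regulators": {"gal3": "GAL3", "gal1": "GAL1", "gal80": "GAL80"},
        },
        "tied_parameters": [
            ["YFP", "GAL1", "r_act_max"],
            ["YFP", "GAL1", "f_active"],
        ],
    },
    "protocol": {
        "protocol": "custom",
        "n_initial": 1000,
        "pre_duration": 660.0,
        "inducer_pre": 0.0,
        "sample_size": None,
        "post_duration": 0.0,
        "inducer_post": 0.0,
        "snapshot_interval": None,
        "chemistry": True,
    },
    "sim": {
        "dV": 0.02,
        "scale_first_order": "scaled",
    },
    "fit": {
        "n_repeats": 4,
        "n_fluor_restarts": 8,
        "conditions": [],
        "free_parameters": [],
        "max_evaluations": 50,
    },
    "output": {
        "dir": "runs",
    },
}


def _merge_defaults(user: Mapping[str, Any], default: Mapping[str, Any], path: str = "") -> dict:
    """Fill missing keys from defaults; reject keys absent from the schema.

    Lists (genes, conditions, tied parameters) are taken verbatim from the
    user when present; list-item schemas are validated by the constructors.
    """
    out: dict[str, Any] = {}
    unknown = [f"{path}{k}" for k in user if k not in default]
    if unknown:
        raise ValueError(f"unknown configuration keys: {', '.join(sorted(unknown))}")
    for key, dval in default.items():
        if key not in user:
            out[key] = copy.deepcopy(dval)
        elif isinstance(dval, Mapping) and isinstance(user[key], Mapping):
            out[key] = _merge_defaults(user[key], dval, f"{path}{key}.")
        else:
            out[key] = copy.deepcopy(user[key])
    return out


def default_cell_cycle() -> CellCyclePopulationParams:
    return _cell_cycle_from(DEFAULT_CONFIG["cell_cycle"])


def default_gal_network() -> NetworkSpec:
    return _network_from(DEFAULT_CONFIG["network"])


def _cell_cycle_from(d: Mapping[str, Any]) -> CellCyclePopulationParams:
    def norm(key: str) -> Normal:
        v = d[key]
        return Normal(mean=float(v["mean"]), sd=float(v["sd"]))

    return CellCyclePopulationParams(
        Vi=norm("Vi"),
        r1=norm("r1"),
        r2=norm("r2"),
        r2m=norm("r2m"),
        T1min=norm("T1min"),
        T2=norm("T2"),
        T3=norm("T3"),
        k=float(d["k"]),
        b=float(d["b"]),
        c_inherit=float(d["c_inherit"]),
        t1_combiner=str(d["t1_combiner"]),
    )


def _network_from(d: Mapping[str, Any]) -> NetworkSpec:
    genes = [GeneSpec(**g) for g in d["genes"]]
    ff = dict(d["functional_form"])
    regulators = ff.pop("regulators")
    gene_names = {g.name for g in genes}
    for role, name in regulators.items():
        if name not in gene_names:
            raise ValueError(
                f"functional_form regulator {role!r} references unknown gene {name!r}"
            )
    ties = [tuple(t) for t in d["tied_parameters"]]
    for ga, gb, fld in ties:
        for name in (ga, gb):
            if name not in gene_names:
                raise ValueError(f"tied_parameters references unknown gene {name!r}")
    form = GalFunctionalForm(FunctionalFormParams(**ff), regulators)
    return NetworkSpec(
        genes=genes,
        functional_form=form,
        Vref=float(d["Vref"]),
        noise_cv=float(d["noise_cv"]),
        tied_parameters=ties,
    )


def _protocol_from(d: Mapping[str, Any]) -> ProtocolSpec:
    return ProtocolSpec(
        protocol=str(d["protocol"]),
        n_initial=int(d["n_initial"]),
        pre_duration=float(d["pre_duration"]),
        inducer_pre=float(d["inducer_pre"]),
        sample_size=None if d["sample_size"] is None else int(d["sample_size"]),
        post_duration=float(d["post_duration"]),
        inducer_post=float(d["inducer_post"]),
        snapshot_interval=(
            None if d["snapshot_interval"] is None else float(d["snapshot_interval"])
        ),
        chemistry=bool(d["chemistry"]),
    )


@dataclass
class RunConfig:
    """Validated configuration plus the constructed model objects."""

    raw: dict[str, Any]
    seed: int
    cell_cycle: CellCyclePopulationParams
    network: NetworkSpec
    protocol: ProtocolSpec
    sim: SimOptions
    fit: dict[str, Any]
    output_dir: Path


def config_from_dict(user: Mapping[str, Any]) -> RunConfig:
    raw = _merge_defaults(user or {}, DEFAULT_CONFIG)
    sim = SimOptions(
        dV=float(raw["sim"]["dV"]),
        scale_first_order=str(raw["sim"]["scale_first_order"]),
        t1_combiner=str(raw["cell_cycle"]["t1_combiner"]),
    )
    return RunConfig(
        raw=raw,
        seed=int(raw["seed"]),
        cell_cycle=_cell_cycle_from(raw["cell_cycle"]),
        network=_network_from(raw["network"]),
        protocol=_protocol_from(raw["protocol"]),
        sim=sim,
        fit=dict(raw["fit"]),
        output_dir=Path(raw["output"]["dir"]),
    )


def load_config(path: str | Path) -> RunConfig:
    """Load, validate and complete a YAML (or JSON) configuration file."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    if not isinstance(user, Mapping):
        raise ValueError(f"{path}: top level must be a mapping")
    return config_from_dict(user)


def dump_config(cfg: RunConfig, path: str | Path) -> None:
    """Write the normalized (defaults-filled) configuration back to YAML."""
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.raw, fh, sort_keys=False)
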