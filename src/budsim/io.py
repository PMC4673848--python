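"""CSV/JSON writers, readers and the synthetic-fixture generator.

All files are comma-separated UTF-8 with a mandatory header row; time is in
minutes, volume in fL, rates per minute.  The fixture generator emits
synthetic "experimental" fluorescence datasets in the same shape as exported
flow-cytometry CSVs (one fluorescence value per cell, one file per condition)
from known ground-truth parameters, so fitting and analysis code can be
exercised offline with a recoverable answer key.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .cell_cycle import CellCyclePopulationParams
from .fluorescence import FluorescenceModel, to_fluorescence
from .gene_network import NetworkSpec
from .population import LineageLog, PopulationSnapshot, ProtocolSpec, run_protocol
from .ssa import SimOptions

__all__ = [
    "FixtureSpec",
    "generate_fixtures",
    "load_manifest",
    "write_snapshot",
    "read_snapshot",
    "write_lineage",
    "write_metadata",
]


def write_snapshot(snapshot: PopulationSnapshot, path: str | Path) -> Path:
    """One CSV row per live cell, ordered by cell_id."""
    path = Path(path)
    df = snapshot.cells.sort_values("cell_id")
    df.insert(0, "time", snapshot.time)
    df.to_csv(path, index=False)
    return path


def read_snapshot(path: str | Path) -> PopulationSnapshot:
    df = pd.read_csv(path)
    time = float(df["time"].iloc[0]) if len(df) else 0.0
    return PopulationSnapshot(time=time, cells=df.drop(columns=["time"]))


def write_lineage(log: LineageLog, out_dir: str | Path) -> tuple[Path, Path]:
    """Write divisions.csv and traces.csv; traces may be header-only."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    div_path = out_dir / "divisions.csv"
    pd.DataFrame(
        log.divisions,
        columns=["time", "mother_id", "daughter_id", "v_mother", "v_daughter"],
    ).to_csv(div_path, index=False)
    rows = [
        (cid, t, v, rep)
        for cid in sorted(log.traces)
        for (t, v, rep) in log.traces[cid]
    ]
    tr_path = out_dir / "traces.csv"
    pd.DataFrame(rows, columns=["cell_id", "time", "volume", "reporter"]).to_csv(
        tr_path, index=False
    )
    return div_path, tr_path


def write_metadata(out_dir: str | Path, **payload) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / "metadata.json"
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=str)
    return path


@dataclass
class FixtureSpec:
    """Recipe for a synthetic fluorescence dataset with a known answer key."""

    conditions: list[tuple[float, float]]  # (galactose % w/v, duration h)
    cells_per_condition: int = 1000
    n_initial: int = 200
    c_fluo_true: float = 1.0
    mu_B: float = 61.0
    sd_B: float = 17.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cells_per_condition < 100:
            raise ValueError("cells_per_condition must be >= 100")
        if not self.conditions:
            raise ValueError("at least one condition required")


def generate_fixtures(
    spec: FixtureSpec,
    network: NetworkSpec,
    popn: CellCyclePopulationParams,
    out_dir: str | Path,
    options: SimOptions | None = None,
) -> dict:
    """Simulate at ground truth and write experiment-shaped CSV files.

    For each (galactose, duration) condition a population of ``n_initial``
    cells is induced for the stated duration, ``cells_per_condition`` cells
    are sampled from the final population, and their reporter counts are
    converted to fluorescence with the true conversion factor plus normal
    background.  Writes one CSV per condition, a ``manifest.csv`` mapping
    (galactose, hours) to file, and ``truth.json`` with the generating
    parameters.  Identical seeds give byte-identical files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    model = FluorescenceModel(c_fluo=spec.c_fluo_true, mu_B=spec.mu_B, sd_B=spec.sd_B)
    manifest_rows = []
    for i, (gal, hours) in enumerate(spec.conditions):
        proto = ProtocolSpec(
            protocol="custom",
            n_initial=spec.n_initial,
            pre_duration=hours * 60.0,
            inducer_pre=gal,
            sample_size=None,
            post_duration=0.0,
            inducer_post=gal,
        )
        res = run_protocol(proto, network, popn, seed=spec.seed + i, options=options)
        counts = res.final_snapshot.reporter_counts()
        rng = np.random.Generator(
            np.random.PCG64(np.random.SeedSequence((spec.seed, 0xF1C, i)))
        )
        if len(counts) > spec.cells_per_condition:
            idx = rng.choice(len(counts), spec.cells_per_condition, replace=False)
            counts = counts[np.sort(idx)]
        fluor = to_fluorescence(counts, model, rng)
        fname = f"fluorescence_gal{gal:g}_t{hours:g}h.csv"
        pd.DataFrame({"fluorescence": fluor}).to_csv(out_dir / fname, index=False)
        manifest_rows.append({"galactose": gal, "hours": hours, "path": fname})
    manifest = pd.DataFrame(manifest_rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    truth = {
        "c_fluo_true": spec.c_fluo_true,
        "mu_B": spec.mu_B,
        "sd_B": spec.sd_B,
        "seed": spec.seed,
        "n_initial": spec.n_initial,
        "cells_per_condition": spec.cells_per_condition,
        "conditions": spec.conditions,
        "genes": [vars(g) | {} for g in network.genes],
        "functional_form": vars(network.functional_form.params) | {},
        "synthetic": True,
    }
    with open(out_dir / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
    return {"dir": str(out_dir), "manifest": manifest, "truth": truth}


def load_manifest(fixture_dir: str | Path) -> dict[str, np.ndarray]:
    """Read a fixture/experiment directory into {condition key: values}.

    Keys are ``"gal<g>:<hours>h"`` strings matching the manifest rows.
    """
    fixture_dir = Path(fixture_dir)
    manifest = pd.read_csv(fixture_dir / "manifest.csv")
    out = {}
    for _, row in manifest.iterrows():
        key = f"gal{row['galactose']:g}:{row['hours']:g}h"
        df = pd.read_csv(fixture_dir / row["path"])
        out[key] = df["fluorescence"].to_numpy(dtype=float)
    return out
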