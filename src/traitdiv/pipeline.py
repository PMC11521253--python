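"""End-to-end orchestration: simulate/load → code → distance → ordinate →
FD metrics → null tests → FCA, with every intermediate written as flat CSV
plus a JSON run manifest.

Each stage is an ordinary function over the documented artifacts, so stages
can be run and inspected independently from Python; :func:`run_pipeline`
chains them.  For a fixed seed the CSV artifacts are byte-identical across
runs.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .coding import code_traits, functional_entities, subset_by_function
from .distance import mixed_distance
from .landings import (DECADES, aggregate_all, assemblage_table, check_decades,
                       minmax_standardize, read_landings, write_landings)
from .metrics import PooledSpace, compute_fd
from .nullmodels import METRICS, run_comparisons
from .ordination import fca, pcoa
from .schema import build_reference_schema, read_trait_table, write_schema, write_trait_table
from .simulate import ScenarioConfig, generate_landings, generate_species_pool

__all__ = ["RunConfig", "run_pipeline"]

ALL_FUNCTIONS = ("combined", "habitat_use", "locomotion", "feeding", "life_history")


@dataclass
class RunConfig:
    """Inputs and knobs for one pipeline run.

    Exactly one of (``trait_table`` + ``landings``) or ``scenario`` must be
    provided.  ``standardization_scope`` is ``"per-assemblage"`` or
    ``"global"`` (min-max range shared across assemblages).
    """

    out_dir: Path
    trait_table: Path | None = None
    landings: Path | None = None
    scenario: ScenarioConfig | None = None
    functions: Sequence[str] = ALL_FUNCTIONS
    metrics: Sequence[str] = METRICS
    n_iter: int = 999
    seed: int = 0
    decades: Mapping[str, tuple[int, int]] = field(default_factory=lambda: dict(DECADES))
    years: tuple[int, int] = (1980, 2020)
    standardization_scope: str = "per-assemblage"

    def __post_init__(self) -> None:
        has_real = self.trait_table is not None and self.landings is not None
        if has_real == (self.scenario is not None):
            raise ValueError("provide either trait_table+landings or a scenario, not both")
        if self.n_iter < 1:
            raise ValueError("n_iter must be >= 1")
        check_decades(self.decades, self.years)
        self.out_dir = Path(self.out_dir)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage in order and return the run manifest.

    Artifacts (all flat CSV under ``config.out_dir``): the trait table and
    landings (generated or copied-by-reference), the coded bin-fuzzy matrix,
    per-function distance matrices, PCoA eigenvalues and coordinates, the
    assemblage weight table, the FD metric table, the null-test table, and
    per-function FCA tables.  The manifest (``manifest.json``) records input
    hashes, seed, versions, per-stage timing and flags.
    """
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    schema = build_reference_schema()
    manifest: dict = {"seed": config.seed, "version": __version__,
                      "numpy": np.__version__, "pandas": pd.__version__,
                      "standardization_scope": config.standardization_scope,
                      "n_iter": config.n_iter, "stages": {}, "artifacts": [],
                      "flags": []}

    def artifact(path: Path) -> None:
        manifest["artifacts"].append(path.name)

    def stage(name: str, start: float) -> None:
        manifest["stages"][name] = round(time.perf_counter() - start, 4)

    # -- inputs -------------------------------------------------------------
    t0 = time.perf_counter()
    if config.scenario is not None:
        pool_records = generate_species_pool(config.scenario, schema)
        records = generate_landings(pool_records, config.scenario, schema)
        trait_path = out / "trait_table.csv"
        landings_path = out / "landings.csv"
        write_trait_table(pool_records, trait_path, schema)
        write_landings(records, landings_path)
    else:
        trait_path, landings_path = Path(config.trait_table), Path(config.landings)
        if not trait_path.exists():
            raise FileNotFoundError(
                f"trait table {trait_path} not found — the schema/coding stage needs a "
                "species × trait CSV (see traitdiv.schema.read_trait_table)")
        pool_records = read_trait_table(trait_path, schema)
        report = read_landings(landings_path, years=config.years)
        if report.errors:
            manifest["flags"].append(f"landings: {report.n_rejected} rows rejected")
        records = report.records
    write_schema(schema, out / "schema.txt")
    manifest["inputs"] = {"trait_table": _sha256(trait_path),
                          "landings": _sha256(landings_path)}
    artifact(trait_path); artifact(landings_path); artifact(out / "schema.txt")
    stage("inputs", t0)

    # -- coding -------------------------------------------------------------
    t0 = time.perf_counter()
    pool = code_traits(pool_records, schema)
    pool.to_csv(out / "coded_matrix.csv")
    artifact(out / "coded_matrix.csv")
    stage("coding", t0)

    # -- assemblage weights -------------------------------------------------
    t0 = time.perf_counter()
    groups = aggregate_all(records, config.decades)
    scope = config.standardization_scope
    bounds = None
    if scope == "global":
        allx = [v for g in groups.values() for v in g.values()]
        bounds = (min(allx), max(allx))
    assemblages = {key: minmax_standardize(totals, bounds=bounds)
                   for key, totals in sorted(groups.items())}
    fleet_groups: dict[str, dict[str, float]] = {}
    for r in records:
        g = fleet_groups.setdefault(r.fleet, {})
        g[r.species] = g.get(r.species, 0.0) + r.weight_kg
    fleet_totals = {fleet: minmax_standardize(totals, bounds=bounds)
                    for fleet, totals in sorted(fleet_groups.items())}
    assemblage_table(groups, scope).to_csv(out / "assemblages.csv", index=False)
    artifact(out / "assemblages.csv")
    stage("weights", t0)

    # -- distance + ordination + FD metrics ---------------------------------
    t0 = time.perf_counter()
    fd_rows = []
    spaces: dict[str, PooledSpace] = {}
    for function in config.functions:
        sub = subset_by_function(pool, function)
        dist = mixed_distance(sub)
        dist.to_csv(out / f"distance_{function}.csv")
        ordn = pcoa(dist)
        ordn.to_frame().to_csv(out / f"pcoa_coords_{function}.csv")
        pd.Series(ordn.eigenvalues, name="eigenvalue").to_csv(
            out / f"pcoa_eigenvalues_{function}.csv", index_label="axis")
        artifact(out / f"distance_{function}.csv")
        artifact(out / f"pcoa_coords_{function}.csv")
        artifact(out / f"pcoa_eigenvalues_{function}.csv")
        space = PooledSpace.build(pool, function)
        spaces[function] = space
        for fleet, aw in sorted(fleet_totals.items()):
            fd_rows.append(compute_fd(pool, aw, function, f"{fleet}:all",
                                      space=space).as_row())
        for (fleet, decade), aw in assemblages.items():
            fd_rows.append(compute_fd(pool, aw, function, f"{fleet}:{decade}",
                                      space=space).as_row())
    fd_table = pd.DataFrame(fd_rows)
    fd_table.to_csv(out / "fd_metrics.csv", index=False)
    artifact(out / "fd_metrics.csv")
    manifest["flags"].extend(sorted({f for f in fd_table["flags"] if f}))
    stage("fd_metrics", t0)

    # -- null models --------------------------------------------------------
    t0 = time.perf_counter()
    null_table, _ = run_comparisons(pool, assemblages, fleet_totals,
                                    functions=config.functions,
                                    metrics=config.metrics,
                                    n_iter=config.n_iter, seed=config.seed)
    null_table.to_csv(out / "null_tests.csv", index=False)
    artifact(out / "null_tests.csv")
    stage("null_models", t0)

    # -- FCA ----------------------------------------------------------------
    t0 = time.perf_counter()
    for function in config.functions:
        sub = subset_by_function(pool, function)
        result = fca(sub)
        prefix = f"fca_{function}"
        pd.DataFrame(result.species_coords, index=list(result.species),
                     columns=[f"axis{k+1}" for k in range(result.n_axes)]
                     ).to_csv(out / f"{prefix}_species.csv", index_label="species")
        mod_idx = pd.Index([f"{t}.{m}" for t, m in result.modalities], name="modality")
        pd.DataFrame(result.modality_coords, index=mod_idx,
                     columns=[f"axis{k+1}" for k in range(result.n_axes)]
                     ).to_csv(out / f"{prefix}_modalities.csv")
        pd.Series(result.eigenvalues, name="inertia").to_csv(
            out / f"{prefix}_eigenvalues.csv", index_label="axis")
        result.modality_correlations.to_csv(out / f"{prefix}_correlations.csv", index=False)
        for name in ("species", "modalities", "eigenvalues", "correlations"):
            artifact(out / f"{prefix}_{name}.csv")
    stage("fca", t0)

    manifest["sing_sp_pool"] = len(functional_entities(pool))
    manifest["nbsp_pool"] = pool.n_species
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def write_report(out_dir: Path) -> Path:
    """Aggregate a run's tables into one human-readable summary document."""
    out_dir = Path(out_dir)
    manifest = json.loads((out_dir / "manifest.json").read_text())
    fd = pd.read_csv(out_dir / "fd_metrics.csv")
    nulls = pd.read_csv(out_dir / "null_tests.csv")
    lines = ["# Functional diversity run report", "",
             f"seed: {manifest['seed']}  package: traitdiv {manifest['version']}",
             f"pool: {manifest['nbsp_pool']} species, "
             f"{manifest['sing_sp_pool']} functional entities", "",
             "## FD metrics", fd.to_string(index=False), ""]
    if "p_value" in nulls.columns:
        sig = nulls[nulls["p_value"] < 0.05]
        lines += ["## Null tests", f"{len(nulls)} tests; "
                  f"{len(sig)} with p < 0.05 (no multiplicity correction)",
                  sig.to_string(index=False) if len(sig) else ""]
    path = out_dir / "report.md"
    path.write_text("\n".join(lines) + "\n")
    return path
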