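"""End-to-end screening pipeline: blocks -> ligands -> cages -> ranking.

``screen_library`` chains every stage for each ligand of the
combinatorial library: 3D ligand embedding, assembly of the four cage
isomers, conformer search + relaxation with the configured backend,
structural metrics on each relaxed cage, energy separations and
threshold classification. Outputs are plain DataFrames so the CLI (and
tests) can write diff-stable CSV/JSON.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import pandas as pd

from .assembly import Isomer, assemble_cage, enumerate_isomer_specs
from .library import (
    BuildingBlock,
    LigandSpec,
    build_ligand_structure,
    enumerate_ligand_specs,
    ligand_smiles,
)
from .metrics import compute_metrics
from .ranking import (
    IsomerEnergies,
    RankingRecord,
    Thresholds,
    classify,
    energy_separations,
    rank_library,
)
from .relaxation import BackendConfig, conformer_search

logger = logging.getLogger("cagescreen")

SCHEMA_VERSION = 1


@dataclass
class RunConfig:
    """Everything a full screening run depends on."""

    backend: BackendConfig = field(default_factory=BackendConfig)
    thresholds: Thresholds = field(default_factory=Thresholds)
    seed: int = 42
    radius_scale: float = 1.0


def manifest(
    coordinating: list[BuildingBlock], cores: list[BuildingBlock]
) -> dict:
    """JSON-able ligand library manifest (ids, components, SMILES)."""
    blocks = {b.label: b for b in [*coordinating, *cores]}
    specs = enumerate_ligand_specs(coordinating, cores)
    return {
        "schema_version": SCHEMA_VERSION,
        "n_coordinating": len(coordinating),
        "n_cores": len(cores),
        "n_ligands": len(specs),
        "ligands": [
            {
                "id": s.id,
                "coord_a": s.coord_a,
                "core": s.core,
                "coord_b": s.coord_b,
                "smiles": ligand_smiles(s, blocks),
            }
            for s in specs
        ],
    }


def screen_ligand(
    spec: LigandSpec,
    blocks: dict[str, BuildingBlock],
    config: RunConfig,
) -> tuple[list[dict], RankingRecord]:
    """Run one ligand through the whole pipeline.

    Returns the four per-cage metric rows and the ligand's ranking
    record (classification based on the lowest-energy structure's
    geometry).
    """
    lig = build_ligand_structure(spec, blocks, seed=config.seed)
    rows = []
    energies: dict[str, float] = {}
    reports = {}
    method = config.backend.backend
    for cage_spec in enumerate_isomer_specs(spec):
        t0 = time.perf_counter()
        cage = assemble_cage(lig, cage_spec, radius_scale=config.radius_scale)
        relaxed, result = conformer_search(
            cage,
            n_conformers=config.backend.n_conformers,
            seed=config.backend.seed,
            backend=config.backend.backend,
            config=config.backend,
        )
        report = compute_metrics(relaxed)
        energies[cage_spec.isomer.value] = result.energy
        reports[cage_spec.isomer.value] = report
        method = result.method
        rows.append(
            {
                "ligand": spec.id,
                "isomer": cage_spec.isomer.value,
                "energy": result.energy,
                "method": result.method,
                **report.as_dict(),
            }
        )
        logger.info(
            "cage %s_%s: E=%.2f kJ/mol (%.2fs)",
            spec.id,
            cage_spec.isomer.value,
            result.energy,
            time.perf_counter() - t0,
        )
    delta_e, delta_e_cis, lowest = energy_separations(
        IsomerEnergies(spec.id, energies, method=method)
    )
    low_report = reports[lowest]
    record = classify(
        spec.id,
        delta_e,
        delta_e_cis,
        lowest,
        q_sqp_min=low_report.q_sqp_min,
        d_max=low_report.d_max,
        thresholds=config.thresholds,
        method=method,
    )
    return rows, record


def screen_library(
    coordinating: list[BuildingBlock],
    cores: list[BuildingBlock],
    config: RunConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Screen the full combinatorial library.

    Returns ``(cages, ranking)``: one metric row per cage (4 per
    ligand) and the ranked per-ligand report.
    """
    config = config or RunConfig()
    blocks = {b.label: b for b in [*coordinating, *cores]}
    specs = enumerate_ligand_specs(coordinating, cores)
    all_rows: list[dict] = []
    records: list[RankingRecord] = []
    for i, spec in enumerate(specs):
        t0 = time.perf_counter()
        rows, record = screen_ligand(spec, blocks, config)
        all_rows.extend(rows)
        records.append(record)
        logger.info(
            "ligand %s (%d/%d) done in %.1fs",
            spec.id, i + 1, len(specs), time.perf_counter() - t0,
        )
    cages = pd.DataFrame(all_rows)
    return cages, rank_library(records)


def separations_from_energy_table(df: pd.DataFrame) -> pd.DataFrame:
    """Per-ligand separations from a long-format energies table.

    Expects columns ``ligand``, ``isomer``, ``energy`` (kJ/mol) and
    optionally ``method``; used by ranking-only runs on externally
    computed energies.
    """
    out = []
    for lig, grp in df.groupby("ligand", sort=True):
        method = grp["method"].iloc[0] if "method" in grp else "external"
        e = IsomerEnergies(lig, dict(zip(grp["isomer"], grp["energy"])), method)
        delta_e, delta_e_cis, lowest = energy_separations(e)
        out.append(
            {
                "ligand": lig,
                "delta_e": delta_e,
                "delta_e_cis": delta_e_cis,
                "lowest_isomer": lowest,
                "method": method,
            }
        )
    return pd.DataFrame(out)


def rank_from_tables(
    separations: pd.DataFrame,
    metrics: pd.DataFrame,
    thresholds: Thresholds | None = None,
) -> pd.DataFrame:
    """Classification + ranking from separations and per-cage metrics.

    Geometry (q_sqp_min, d_max) is taken from each ligand's
    lowest-energy isomer row of ``metrics``.
    """
    records = []
    for row in separations.itertuples():
        sel = metrics[
            (metrics["ligand"] == row.ligand)
            & (metrics["isomer"] == row.lowest_isomer)
        ]
        if sel.empty:  # fall back to the cis row (metrics-only inputs)
            sel = metrics[
                (metrics["ligand"] == row.ligand)
                & (metrics["isomer"] == Isomer.CIS.value)
            ]
        if sel.empty:
            raise KeyError(f"no metrics row for ligand {row.ligand}")
        records.append(
            classify(
                row.ligand,
                row.delta_e,
                row.delta_e_cis,
                row.lowest_isomer,
                q_sqp_min=float(sel["q_sqp_min"].iloc[0]),
                d_max=float(sel["d_max"].iloc[0]),
                thresholds=thresholds,
                method=str(getattr(row, "method", "external")),
            )
        )
    return rank_library(records)
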