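"""End-to-end orchestration: shrinkage -> clustering -> profiling -> spatial stats.

``run_pipeline`` takes a cohort of cell tables (typically from the synth
module or from CSVs) and executes every stage in order, writing each
stage's outputs as CSV under ``config.out_dir`` with a provenance sidecar
(config hash + seed).  Stage failures abort with the stage name attached.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import clustering, neighborhood, overlap, profiling, shrinkage, zones
from .celltable import CellTable
from .config import RunConfig

log = logging.getLogger("spatialplex")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineResult:
    tables: list[CellTable]
    models: dict[str, shrinkage.ShrinkageModel]
    assignments: dict[str, clustering.ClusterAssignment]
    profiles: dict[str, dict[int, clustering.ClusterProfile]]
    summaries: dict[str, profiling.CellTypeSummary] = field(default_factory=dict)
    neighborhood_results: pd.DataFrame | None = None
    neighborhood_consensus: pd.DataFrame | None = None
    overlap_results: pd.DataFrame | None = None
    overlap_consensus: pd.DataFrame | None = None
    zonal: zones.ZonalResult | None = None
    compositions: tuple[pd.DataFrame, pd.DataFrame] | None = None


def _write_sidecar(out_dir: Path, config: RunConfig) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "run_meta.json").write_text(
        json.dumps({"config_hash": config.digest(), "seed": config.seed}, indent=1)
    )


def run_pipeline(
    config: RunConfig,
    tables: Sequence[CellTable],
    write: bool = True,
) -> PipelineResult:
    """Execute the full analysis on a cohort; deterministic given seeds."""
    out_dir = Path(config.out_dir)
    if write:
        _write_sidecar(out_dir, config)
        config.to_yaml(out_dir / "config.yaml")

    result = PipelineResult(list(tables), {}, {}, {})
    shrunk_all: dict[str, pd.DataFrame] = {}

    # -- shrinkage ---------------------------------------------------------
    try:
        for t in result.tables:
            model = shrinkage.fit_shrinkage(t.intensities, config.g_initial, config.seed)
            model.lam = config.shrink_lambda
            shrunk_all[t.sample_id] = shrinkage.apply_shrinkage(model, t.intensities)
            result.models[t.sample_id] = model
            log.info("shrinkage[%s]: %d cells, %d markers", t.sample_id, len(t), len(t.markers))
    except Exception as e:  # noqa: BLE001
        raise StageError("shrinkage", e) from e

    # -- clustering --------------------------------------------------------
    try:
        for t in result.tables:
            shr = shrunk_all[t.sample_id]
            if config.global_panel and config.subpanels:
                truth = t.data[config.type_col] if config.type_col in t.data else None

                def mapper(ga, truth=truth):
                    if truth is None:
                        raise ValueError("nested run needs a broad_map or ground truth")
                    return clustering.broad_map_from_truth(ga, truth)

                asg = clustering.nested_classify(
                    shr,
                    config.global_panel,
                    mapper,
                    config.subpanels,
                    config.min_cluster_size,
                    config.subclass_min_cluster_size,
                    config.seed,
                )
            else:
                asg = clustering.embed_and_cluster(shr, config.min_cluster_size, config.seed)
            if config.junk_clusters:
                asg = clustering.flag_artifacts(asg, config.junk_clusters)
            result.assignments[t.sample_id] = asg
            t.data["cluster"] = asg.df["global_label"].to_numpy()
            log.info(
                "clustering[%s]: %d clusters, %d noise cells",
                t.sample_id,
                len(asg.cluster_ids()),
                int((asg.labels == clustering.NOISE).sum()),
            )
    except Exception as e:  # noqa: BLE001
        raise StageError("clustering", e) from e

    # -- profiling ---------------------------------------------------------
    try:
        for t in result.tables:
            asg = result.assignments[t.sample_id]
            if not asg.cluster_ids():
                raise ValueError(f"{t.sample_id}: no analyzable clusters remain")
            result.profiles[t.sample_id] = clustering.characterize_all(
                shrunk_all[t.sample_id], asg, alpha=config.alpha_marker, table=t
            )
        # summaries use the first sample's ground-truth-majority type map
        first = result.tables[0].sample_id
        asg0 = result.assignments[first]
        t0 = result.tables[0]
        if config.type_col in t0.data:
            tmap = clustering.broad_map_from_truth(asg0, t0.data[config.type_col])
            pos = shrinkage.marker_positivity(result.models[first], t0.intensities)
            cell_types = pd.Series(
                [tmap.get(int(l), "") for l in asg0.df["global_label"]], index=t0.data.index
            )
            result.summaries = profiling.summarize_cell_types(
                list(result.profiles[first].values()), tmap, cell_types, pos
            )
    except Exception as e:  # noqa: BLE001
        raise StageError("profiling", e) from e

    # -- neighborhood ------------------------------------------------------
    try:
        res = neighborhood.pairwise_neighborhood(
            result.tables, radii_um=config.radii_um, type_col=config.type_col
        )
        result.neighborhood_results = res
        result.neighborhood_consensus = neighborhood.consensus_significance(
            res, config.alpha_family
        )
    except Exception as e:  # noqa: BLE001
        raise StageError("neighborhood", e) from e

    # -- overlap -----------------------------------------------------------
    try:
        ores = overlap.pairwise_overlap(
            result.tables, radii_um=config.radii_um, type_col=config.type_col
        )
        result.overlap_results = ores
        result.overlap_consensus = overlap.overlap_consensus(ores, config.alpha_family)
    except Exception as e:  # noqa: BLE001
        raise StageError("overlap", e) from e

    # -- zones -------------------------------------------------------------
    try:
        has_zones = any(
            "zone" in t.data and (t.data["zone"] != zones.INTERSTITIAL).any()
            for t in result.tables
        )
        if has_zones:
            result.zonal = zones.zone_enrichment(
                result.tables, config.alpha_family, type_col=config.type_col
            )
            result.compositions = zones.composition_matrices(
                result.tables, type_col=config.type_col
            )
    except Exception as e:  # noqa: BLE001
        raise StageError("zones", e) from e

    if write:
        _write_outputs(result, out_dir)
    return result


def _write_outputs(result: PipelineResult, out_dir: Path) -> None:
    for t in result.tables:
        asg = result.assignments[t.sample_id]
        asg.df.assign(cell_id=t.data["cell_id"].to_numpy()).to_csv(
            out_dir / f"assignment_{t.sample_id}.csv", index=False
        )
    if result.neighborhood_results is not None:
        result.neighborhood_results.to_csv(out_dir / "neighborhood.csv", index=False)
        result.neighborhood_consensus.to_csv(out_dir / "neighborhood_consensus.csv", index=False)
    if result.overlap_results is not None:
        result.overlap_results.to_csv(out_dir / "overlap.csv", index=False)
        result.overlap_consensus.to_csv(out_dir / "overlap_consensus.csv", index=False)
    if result.zonal is not None:
        result.zonal.per_sample.to_csv(out_dir / "zonal_per_sample.csv", index=False)
        result.zonal.aggregate.to_csv(out_dir / "zonal_aggregate.csv", index=False)
    if result.compositions is not None:
        result.compositions[0].to_csv(out_dir / "type_across_regions.csv")
        result.compositions[1].to_csv(out_dir / "region_composition.csv")
    if result.summaries:
        long = profiling.summaries_to_frame(result.summaries)
        long.to_csv(out_dir / "cell_type_summary.csv", index=False)
        for tname, grp in long.groupby("cell_type"):
            safe = "".join(c if c.isalnum() else "_" for c in str(tname))
            grp.to_csv(out_dir / f"celltype_{safe}.csv", index=False)
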