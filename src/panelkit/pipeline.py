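"""End-to-end orchestration: counts -> calls -> QC -> stats -> structure ->
differentiation -> core sets, with a validated config and a run manifest.

A run is driven by a single YAML/JSON config (reproducibility of multi-stage
analyses); every stage writes its outputs before the next starts, and the
manifest records package version, parameters, seed and input checksums.
The manifest deliberately carries no timestamps so identical (inputs,
config, seed) produce byte-identical output trees.  A rerun into the same
output directory is skipped wholesale when the existing manifest matches
the current config and input checksums.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError as PydValidationError

from . import __version__
from .core_selection import greedy_core_snps, saturation_curve, select_core_lines
from .differentiation import amova, pairwise_fst
from .diversity_stats import group_summary, panel_summary
from .genotype_calling import CallThresholds, call_matrix
from .io_formats import (
    GenotypeMatrix,
    export_results,
    read_catalog,
    read_counts_table,
    read_fingerprint_matrix,
    read_metadata,
    sha256_file,
    write_fingerprint_matrix,
    write_manifest,
    write_newick,
)
from .panel_qc import PanelCriteria, apply_panel_filter, locus_qc
from .relatedness import code_and_pca, nj_tree, normalized_distance, pairwise_diff

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "StageError", "validate_config", "run_pipeline"]


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


class Stages(BaseModel):
    model_config = ConfigDict(extra="forbid")
    call: bool = True
    qc: bool = True
    stats: bool = True
    tree: bool = True
    pca: bool = True
    fst: bool = True
    amova: bool = True
    coreset: bool = True
    corelines: bool = True


class RunConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    counts: Optional[str] = None        # read-count TSV
    matrix: Optional[str] = None        # fingerprint CSV (alternative input)
    catalog: Optional[str] = None       # panel catalog TSV
    variants: Optional[str] = None      # genome-wide variant positions TSV
    meta: Optional[str] = None          # sample metadata TSV
    out_dir: str = "panelkit_out"
    seed: int = 0
    log_level: str = "INFO"
    group_by: str = "subpopulation"
    stages: Stages = Field(default_factory=Stages)

    hom_major_freq: float = Field(0.7, gt=0.5, le=1.0)
    het_min_freq: float = Field(0.35, gt=0.0, le=0.5)
    min_depth: int = Field(20, ge=0)
    min_maf: float = Field(0.4, ge=0.0, le=1.0)
    max_missing: float = Field(0.2, ge=0.0, le=1.0)
    max_het: float = Field(0.2, ge=0.0, le=1.0)
    flank_bp: int = Field(100, ge=0)
    core_fraction: float = Field(0.10, gt=0.0, le=1.0)
    pca_components: int = Field(3, ge=1)

    def input_paths(self) -> dict[str, str]:
        return {
            k: v
            for k, v in (
                ("counts", self.counts), ("matrix", self.matrix),
                ("catalog", self.catalog), ("variants", self.variants),
                ("meta", self.meta),
            )
            if v is not None
        }


def validate_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML/JSON run config, collecting all errors."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    try:
        config = RunConfig(**raw)
    except PydValidationError as exc:
        msgs = "; ".join(
            f"{'.'.join(str(l) for l in e['loc'])}: {e['msg']}"
            for e in exc.errors()
        )
        raise ValueError(f"{path}: invalid config: {msgs}") from exc
    errors = []
    if config.counts is None and config.matrix is None:
        errors.append("one of 'counts' or 'matrix' is required")
    for name, p in config.input_paths().items():
        if not Path(p).exists():
            errors.append(f"{name}: file not found: {p}")
    if errors:
        raise ValueError(f"{path}: invalid config: " + "; ".join(errors))
    return config


def _config_fingerprint(config: RunConfig) -> dict:
    digest = {k: sha256_file(p) for k, p in config.input_paths().items()}
    return {
        "version": __version__,
        "config": json.loads(config.model_dump_json()),
        "input_checksums": digest,
        "seed": config.seed,
    }


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages in dependency order; returns the manifest.

    Outputs land in ``config.out_dir``; a failing stage aborts the stages
    downstream of it with a StageError naming the stage.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.log_level)
    fh = logging.FileHandler(out / "run.log", mode="w")
    logging.getLogger().addHandler(fh)
    try:
        return _run(config, out)
    finally:
        logging.getLogger().removeHandler(fh)
        fh.close()


def _run(config: RunConfig, out: Path) -> dict:
    manifest = _config_fingerprint(config)
    manifest_path = out / "manifest.json"
    if manifest_path.exists():
        try:
            previous = json.loads(manifest_path.read_text())
        except json.JSONDecodeError:
            previous = None
        if previous == manifest:
            logger.info("inputs and config unchanged; reusing outputs in %s",
                        out)
            return manifest
    stage = "input"
    try:
        meta = read_metadata(config.meta) if config.meta else None
        catalog = (
            read_catalog(config.catalog, config.variants)
            if config.catalog else None
        )
        if config.counts:
            counts = read_counts_table(config.counts)
            stage = "call"
            thresholds = CallThresholds(
                hom_major_freq=config.hom_major_freq,
                het_min_freq=config.het_min_freq,
                min_depth=config.min_depth,
            )
            matrix = call_matrix(counts, thresholds)
            write_fingerprint_matrix(matrix, out / "calls.csv")
        else:
            matrix = read_fingerprint_matrix(config.matrix)

        if config.stages.qc and catalog is not None:
            stage = "qc"
            criteria = PanelCriteria(
                min_maf=config.min_maf, max_missing=config.max_missing,
                max_het=config.max_het, flank_bp=config.flank_bp,
            )
            qc = locus_qc(matrix, catalog, criteria)
            pd.DataFrame(
                [
                    {
                        "locus_id": q.locus_id, "maf": q.maf,
                        "missing_rate": q.missing_rate, "het_rate": q.het_rate,
                        "n_alleles": q.n_alleles, "flank_clean": q.flank_clean,
                        "passed": q.passed,
                        "failure_reasons": ";".join(q.failure_reasons),
                    }
                    for q in qc
                ]
            ).set_index("locus_id").to_csv(out / "qc_report.csv")
            matrix = apply_panel_filter(matrix, qc)
            write_fingerprint_matrix(matrix, out / "panel.csv")

        results: dict[str, object] = {}
        if config.stages.stats:
            stage = "stats"
            summ = panel_summary(matrix)
            results["locus_stats"] = summ.per_locus
            results["panel_means"] = summ.means
            if meta is not None:
                gs = group_summary(matrix, meta, config.group_by)
                results["group_stats"] = pd.DataFrame(
                    {
                        lab: {
                            "n_samples": g.n_samples,
                            "n_polymorphic": g.n_polymorphic,
                            **{k: v for k, v in g.summary.means.items()},
                            "inbreeding_f": g.group_inbreeding_f,
                        }
                        for lab, g in gs.items()
                    }
                ).T

        diff = None
        if config.stages.tree or config.stages.corelines:
            stage = "distance"
            diff = pairwise_diff(matrix)
            results["n_diff"] = diff.to_frame("n_diff")
            results["n_comparable"] = diff.to_frame("n_comparable")

        if config.stages.tree:
            stage = "tree"
            tree = nj_tree(normalized_distance(diff), diff.sample_ids)
            write_newick(tree.newick, out / "nj_tree.nwk")

        if config.stages.pca:
            stage = "pca"
            pca = code_and_pca(matrix, config.pca_components)
            results["pca_coordinates"] = pd.DataFrame(
                pca.coordinates, index=pca.sample_ids,
                columns=[f"PC{i+1}" for i in range(pca.coordinates.shape[1])],
            )
            results["pca_explained_variance"] = {
                f"PC{i+1}": float(v)
                for i, v in enumerate(pca.explained_variance)
            }

        if config.stages.fst and meta is not None:
            stage = "fst"
            results["fst"] = pairwise_fst(matrix, meta, config.group_by)\
                .to_frame()

        if config.stages.amova and meta is not None:
            stage = "amova"
            results["amova"] = amova(matrix, meta).table

        if config.stages.coreset:
            stage = "coreset"
            core = greedy_core_snps(matrix)
            results["core_set"] = {
                "selected": core.selected,
                "newly_resolved": core.newly_resolved,
                "cumulative_fraction": core.cumulative_fraction,
                "n_pairs": core.n_pairs,
                "n_resolvable": core.n_resolvable,
                "unresolved_pairs": core.unresolved_pairs,
                "pair_min_diff_histogram": core.pair_min_diff_histogram,
            }
            if core.selected:
                results["saturation"] = saturation_curve(matrix, core.selected)

        if config.stages.corelines and meta is not None:
            stage = "corelines"
            lines = select_core_lines(diff, meta, config.core_fraction,
                                      config.group_by)
            results["core_lines"] = {
                "fraction": lines.fraction,
                "selected": lines.selected,
                "ranking": lines.ranking,
            }

        stage = "export"
        export_results(results, out)
        write_manifest(manifest, manifest_path)
        return manifest
    except Exception as exc:  # noqa: BLE001 - reported with stage context
        raise StageError(stage, exc) from exc
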