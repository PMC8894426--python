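"""End-to-end orchestration of the four analysis arms.

A run takes (or simulates) the three raw tables plus metadata and panel,
normalizes each matrix once, and then executes the four arms: single
metabolites in cells, single metabolites in media, cells-over-media
ratios of shared metabolites, and metabotype pair-wise panel ratios.
Each arm's significant features feed correlation/cluster analysis and
LOOCV classification.  Every emitted file is hashed into a manifest so
identical config + seed reproduce identical artifacts.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import classify, corrclust, diffabund, normalize, ratios, synthdata, tables_io
from .containers import NormalizedTable, SampleMetadata, ValidationError
from .tables_io import RunConfig

logger = logging.getLogger(__name__)

ARMS = ("CELLS", "MEDIA", "CELL_MEDIA_RATIO", "METABOTYPE_RATIO")


@dataclass
class RunArtifacts:
    out_dir: Path
    files: list[str] = field(default_factory=list)
    meta: SampleMetadata | None = None
    diff: dict[str, pd.DataFrame] = field(default_factory=dict)
    diff_omnibus: dict[str, pd.DataFrame] = field(default_factory=dict)
    grid: pd.DataFrame | None = None
    misclassified: list[str] = field(default_factory=list)
    matching: tuple[float, float] | None = None
    manifest_path: Path | None = None


def _stage_seed(base_seed: int, stage: int) -> int:
    """Deterministic per-stage substream of the run seed (< 2^31)."""
    return int(np.random.SeedSequence([base_seed, stage]).generate_state(1)[0] % 2**31)


def _load_or_simulate(config: RunConfig):
    if config.cells_path and config.media_path and config.metadata_path:
        meta, protein = tables_io.read_metadata(config.metadata_path)
        cells = tables_io.read_abundance_table(
            config.cells_path, "CELLS", meta.frame["batch"], protein
        )
        media = tables_io.read_abundance_table(
            config.media_path, "MEDIA", meta.frame["batch"]
        )
        blank = (
            tables_io.read_abundance_table(config.blank_path, "BLANK")
            if config.blank_path
            else None
        )
        if not config.panel_path:
            raise ValidationError("metabotype arm requires a panel file")
        panel = tables_io.read_panel(config.panel_path)
        return meta, cells, media, blank, panel, None
    if not config.simulate:
        raise ValidationError("no input tables given and simulation disabled")
    meta = synthdata.generate_cohort(
        n_per_group=config.n_per_group,
        n_female_per_group=config.n_female_per_group,
        n_batches=config.n_batches,
        seed=_stage_seed(config.seed, 0),
    )
    plan = synthdata.EffectPlan(
        n_affected_cells=config.n_affected_cells,
        n_affected_media=config.n_affected_media,
        effect=config.effect,
        contrast_group=config.contrast_group,
        n_ratio_pairs=config.n_ratio_pairs,
        ratio_effect=config.ratio_effect,
        ratio_matrix=config.metabotype_matrix,
    )
    tables = synthdata.generate_tables(
        meta,
        n_cell_mets=config.n_cell_mets,
        n_media_mets=config.n_media_mets,
        n_shared=config.n_shared,
        batch_sd=config.batch_sd,
        noise_sd=config.noise_sd,
        censor_fraction=config.censor_fraction,
        n_panel=config.n_panel,
        n_panel_cells_only=config.n_panel_cells_only,
        n_panel_media_only=config.n_panel_media_only,
        plan=plan,
        seed=_stage_seed(config.seed, 1),
    )
    panel = (
        tables_io.read_panel(config.panel_path) if config.panel_path else tables.panel
    )
    return meta, tables.cells, tables.media, tables.blank, panel, tables.truth


def _significant_features(diff: pd.DataFrame) -> list[str]:
    return list(diff.index[diff["significant"]])


def run_all(config: RunConfig, out_dir) -> RunArtifacts:
    """Execute simulate/load -> normalize -> four arms -> cluster -> classify."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    art = RunArtifacts(out_dir)

    def emit(name: str, writer, *args) -> None:
        writer(out_dir / name, *args)
        art.files.append(name)

    meta, cells, media, blank, panel, truth = _load_or_simulate(config)
    art.meta = meta
    emit("metadata.tsv", tables_io.write_metadata, meta, cells.protein_conc)
    emit("cells.tsv", tables_io.write_abundance_table, cells)
    emit("media.tsv", tables_io.write_abundance_table, media)
    if blank is not None:
        emit("blank.tsv", tables_io.write_abundance_table, blank)
    emit("panel.txt", tables_io.write_panel, panel)
    if truth is not None:
        emit("truth.tsv", tables_io.write_truth, truth)

    fisher_p, kruskal_p = synthdata.verify_matching(meta)
    art.matching = (fisher_p, kruskal_p)
    logger.info("matching: Fisher sex p=%.4g, Kruskal-Wallis age p=%.4g",
                fisher_p, kruskal_p)

    norm: dict[str, NormalizedTable] = {
        "CELLS": normalize.normalize_matrix(cells),
        "MEDIA": normalize.normalize_matrix(media),
    }
    if blank is not None:
        norm["BLANK"] = normalize.normalize_matrix(blank)
    for kind in ("CELLS", "MEDIA"):
        emit(f"normalized_{kind.lower()}.tsv", tables_io.write_frame,
             norm[kind].scaled_values)
        emit(f"imputed_{kind.lower()}.tsv", tables_io.write_frame,
             norm[kind].imputed_mask)

    # models fit the log-scale values; center-scaled values feed
    # clustering and classification
    cm_ratio = ratios.cell_media_ratios(norm["CELLS"], norm["MEDIA"])
    metabotype = ratios.pairwise_panel_ratios(
        norm[config.metabotype_matrix], panel
    )
    arm_tables = {
        "CELLS": norm["CELLS"],
        "MEDIA": norm["MEDIA"],
        "CELL_MEDIA_RATIO": cm_ratio,
        "METABOTYPE_RATIO": metabotype,
    }
    arm_scaled = {arm: t.scaled_values for arm, t in arm_tables.items()}

    contrast = ("ASD_DD", config.contrast_group)
    design2 = diffabund.build_design(meta, contrast)
    design3 = diffabund.build_design(meta, "three_group")
    for arm, table in arm_tables.items():
        fits2 = diffabund.fit_linear_models(table, design2)
        art.diff[arm] = diffabund.moderated_test(fits2, alpha=config.alpha_adjusted)
        fits3 = diffabund.fit_linear_models(table, design3)
        art.diff_omnibus[arm] = diffabund.moderated_f_test(
            fits3, alpha=config.alpha_adjusted
        )
        emit(f"diff_{arm.lower()}.tsv", tables_io.write_diff_results, art.diff[arm])
        emit(f"diff_{arm.lower()}_3group.tsv", tables_io.write_diff_results,
             art.diff_omnibus[arm])
        logger.info("%s: %d significant (2-group), %d (3-group omnibus)",
                    arm, art.diff[arm]["significant"].sum(),
                    art.diff_omnibus[arm]["significant"].sum())

    # correlation / clustering of significant metabotype ratios
    sig_mb = _significant_features(art.diff["METABOTYPE_RATIO"])
    two_group_ids = design2.sample_ids
    if len(sig_mb) >= 2:
        features = metabotype.scaled_values.loc[two_group_ids, sig_mb]
        report = corrclust.correlation_matrix(features)
        order = corrclust.order_features(report)
        emit("metabotype_correlation.tsv", tables_io.write_frame,
             report.r.loc[order, order])
        blocks = corrclust.detect_negative_blocks(report)
        block_frame = pd.DataFrame(
            [
                {
                    "rank": i + 1,
                    "mean_r": b.mean_r,
                    "n_significant": b.n_significant,
                    "features_a": ";".join(b.features_a),
                    "features_b": ";".join(b.features_b),
                }
                for i, b in enumerate(blocks)
            ],
            columns=["rank", "mean_r", "n_significant", "features_a", "features_b"],
        )
        emit("negative_blocks.tsv",
             lambda p, f: f.to_csv(p, sep="\t", float_format="%.6g", index=False),
             block_frame)
        clust = corrclust.hcluster_samples(
            features, meta.frame.loc[two_group_ids, "group"]
        )
        art.misclassified = corrclust.misclassified_samples(clust, k=2)
        emit("cluster_samples.tsv",
             lambda p, c: pd.DataFrame(
                 {"leaf_order": range(len(c.leaf_order)),
                  "group": c.labels.loc[c.leaf_order].to_numpy()},
                 index=pd.Index(c.leaf_order, name="sample_id"),
             ).to_csv(p, sep="\t"),
             clust)
        logger.info("misclassified at k=2: %s", art.misclassified)

    # classification grid: 4 arms x 3 variants x 2 groupings
    feature_sets: dict[str, dict[str, pd.DataFrame]] = {}
    for arm, scaled in arm_scaled.items():
        sig2 = [f for f in _significant_features(art.diff[arm]) if f in scaled.columns]
        sig3 = [f for f in _significant_features(art.diff_omnibus[arm]) if f in scaled.columns]
        feature_sets[arm] = {
            "two_group": scaled.loc[two_group_ids, sig2],
            "three_group": scaled.loc[design3.sample_ids, sig3],
        }
    art.grid, _reports = classify.performance_grid(
        feature_sets,
        meta,
        positive_class=config.positive_class,
        iter_grid=tuple(config.logitboost_iter_grid),
        corr_threshold=config.corr_removal_threshold,
        variance_threshold=config.pca_variance_threshold,
    )
    emit("performance_grid.tsv",
         lambda p, g: g.to_csv(p, sep="\t", float_format="%.6g", index=False),
         art.grid)

    art.manifest_path = tables_io.write_manifest(
        out_dir, config, art.files,
        extra={"fisher_sex_p": f"{fisher_p:.6g}",
               "kruskal_age_p": f"{kruskal_p:.6g}"},
    )
    return art
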