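"""End-to-end pipeline: chain the analysis stages over on-disk inputs.

Stages: robust normalization -> copy-number stratification -> per-gene Welch
metrics -> competitive set test + preranked GSEA, with optional DEG calling,
ChIP peak integration and immune-fraction testing when the corresponding
inputs are supplied. All outputs are TSV with a fixed float format, so two
runs with identical inputs, config and seed are byte-identical.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping

import pandas as pd

from . import deg as deg_mod
from . import differential, enrichment, fractions as fractions_mod, io, normalize, peaks as peaks_mod, stratify
from .config import PipelineConfig

logger = logging.getLogger(__name__)

REQUIRED_INPUTS = ("expression", "metadata", "copy_number", "gene_sets")
OPTIONAL_INPUTS = ("counts", "annotation", "fractions")


def run_pipeline(
    config: PipelineConfig,
    inputs: Mapping[str, str | Path],
    oncogene: str,
    outdir: str | Path,
    peak_files: list[str | Path] | None = None,
) -> dict[str, Path]:
    """Execute the pipeline; returns the mapping of stage name -> output path.

    ``inputs`` keys: expression, metadata, copy_number, gene_sets (required);
    counts, annotation, fractions (optional). ``peak_files`` holds one BED
    per ChIP replicate/sample; peak integration needs counts + annotation too.
    Every referenced input is checked for existence before any computation.
    """
    paths = {k: Path(v) for k, v in inputs.items()}
    unknown = set(paths) - set(REQUIRED_INPUTS) - set(OPTIONAL_INPUTS)
    if unknown:
        raise ValueError(f"unknown input keys: {sorted(unknown)}")
    missing_keys = [k for k in REQUIRED_INPUTS if k not in paths]
    if missing_keys:
        raise ValueError(f"missing required inputs: {missing_keys}")
    all_files = list(paths.values()) + [Path(p) for p in (peak_files or [])]
    absent = [str(p) for p in all_files if not p.exists()]
    if absent:
        raise FileNotFoundError(f"input file(s) not found: {absent}")

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}

    def emit(name: str, frame: pd.DataFrame, index: bool = False) -> None:
        path = outdir / f"{name}.tsv"
        io.write_table(frame, path, index=index)
        outputs[name] = path

    config.to_yaml(outdir / "run_config.yaml")
    outputs["config"] = outdir / "run_config.yaml"

    matrix = io.read_expression_matrix(paths["expression"], paths["metadata"])
    logger.info("expression: %d genes x %d samples", *matrix.values.shape)
    filtered = normalize.filter_low_expression(matrix, config.expr_filter_threshold)
    standardized = normalize.robust_standardize(filtered, scale_method=config.scale_method)
    emit("normalized", standardized.values, index=True)

    cn = io.read_copy_number(paths["copy_number"])
    strat = stratify.stratify_cohort(
        cn,
        oncogene,
        samples=[s for s in standardized.sample_ids if s in cn.index],
        amp_threshold=config.amp_threshold,
        neutral_band=config.neutral_band,
    )
    emit("groups", strat.as_frame())

    profile = differential.differential_profile(standardized, strat.amplified, strat.neutral)
    emit("differential", profile.table, index=True)

    collection = io.read_gmt(paths["gene_sets"])
    set_table, set_filtered = enrichment.enrich_all(
        profile, collection, config.welch_set_min, config.welch_set_max
    )
    if set_filtered:
        logger.info("set test size filter excluded: %s", sorted(set_filtered))
    emit("set_test", set_table)

    gsea_table = enrichment.preranked_gsea(
        profile,
        collection,
        n_perm=config.n_permutations,
        min_size=config.gsea_min,
        max_size=config.gsea_max,
        seed=config.rng_seed,
    )
    emit("gsea", gsea_table)

    deg_table = None
    if "counts" in paths:
        counts = io.read_count_matrix(paths["counts"])
        group_a = [s for s in strat.amplified if s in counts.columns]
        group_b = [s for s in strat.neutral if s in counts.columns]
        factors = deg_mod.median_ratio_size_factors(counts)
        deg_table = deg_mod.deg_test(
            counts, factors, group_a, group_b, config.deg_fdr, config.deg_fc
        )
        emit("deg", deg_table, index=True)

    if peak_files and "annotation" in paths:
        if deg_table is None:
            raise ValueError("peak integration requires the counts input for DEG calling")
        annotation = io.read_annotation(paths["annotation"])
        peak_sets = [io.read_bed(p) for p in peak_files]
        loci = peaks_mod.recurrent_peaks(peak_sets, min_support=2, min_overlap=config.min_overlap)
        emit("loci", loci)
        assignments = peaks_mod.assign_nearest_gene(
            loci, annotation, config.promoter_upstream, config.promoter_downstream
        )
        emit("targets", assignments)
        up, down, conflicts = deg_mod.union_degs([deg_table])
        target_genes = set(assignments["gene_id"])
        up_targets, down_targets = peaks_mod.intersect_targets_degs(target_genes, up, down)
        overlap_frame = pd.DataFrame(
            sorted(
                [(g, "up") for g in up_targets] + [(g, "down") for g in down_targets]
            ),
            columns=["gene_id", "direction"],
        )
        emit("target_deg_overlap", overlap_frame)
        universe = set(deg_table.index)
        over = peaks_mod.fisher_overrepresentation(
            down_targets & universe, universe, collection, config.fisher_fdr
        )
        emit("overrepresentation", over)

    if "fractions" in paths:
        fraction_matrix = io.read_fraction_matrix(paths["fractions"])
        amp = [s for s in strat.amplified if s in fraction_matrix.index]
        neu = [s for s in strat.neutral if s in fraction_matrix.index]
        frac_table = fractions_mod.differential_fractions(fraction_matrix, amp, neu)
        emit("fraction_diff", frac_table, index=True)

    logger.info("pipeline complete: %d output file(s) in %s", len(outputs), outdir)
    return outputs
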