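"""Simplified differentially-expressed-gene (DEG) calling on count data.

Median-ratio (size-factor) normalization followed by a per-gene Welch test on
log2-transformed normalized counts, BH adjustment, and the double threshold:
a gene is a DEG when padj < 0.05 and linear |fold change| > 1.5 (i.e.
|log2FC| > log2 1.5). This deliberately does not reproduce a negative-
binomial GLM with dispersion shrinkage; downstream logic depends only on the
DEG table, so output from a full NB pipeline can be substituted via TSV.

Fold change uses a pseudo-count of 0.5 on the normalized group means; the
test transform uses log2(normalized + 1). Both constants are recorded in the
output table attrs.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .differential import _welch_rows
from .enrichment import bh_fdr

logger = logging.getLogger(__name__)

FC_PSEUDOCOUNT = 0.5
LOG_PSEUDOCOUNT = 1.0


def median_ratio_size_factors(counts: pd.DataFrame) -> pd.Series:
    """Per-sample size factors by the median-of-ratios method.

    The reference is the per-gene geometric mean over samples, computed over
    genes with nonzero counts in every sample; each sample's factor is the
    median ratio of its counts to the reference over those genes.
    """
    values = counts.to_numpy(dtype=float)
    all_nonzero = (values > 0).all(axis=1)
    if not all_nonzero.any():
        raise ValueError("no gene has nonzero counts in every sample; size factors undefined")
    log_ref = np.log(values[all_nonzero]).mean(axis=1)
    ratios = values[all_nonzero] / np.exp(log_ref)[:, None]
    factors = np.median(ratios, axis=0)
    return pd.Series(factors, index=counts.columns, name="size_factor")


def deg_test(
    counts: pd.DataFrame,
    size_factors: pd.Series,
    group_a: list[str],
    group_b: list[str],
    fdr_threshold: float = 0.05,
    fc_threshold: float = 1.5,
) -> pd.DataFrame:
    """Two-group DEG table (group A over group B).

    Columns: log2fc, p, padj, is_deg, degenerate. ``is_deg`` is exactly
    (padj < fdr_threshold) and (|linear fold change| > fc_threshold).
    """
    overlap = sorted(set(group_a) & set(group_b))
    if overlap:
        raise ValueError(f"groups overlap: {overlap}")
    for group in (group_a, group_b):
        missing = [s for s in group if s not in counts.columns]
        if missing:
            raise ValueError(f"sample(s) not in count matrix: {missing}")
    normalized = counts / size_factors
    a = normalized[list(group_a)].to_numpy(dtype=float)
    b = normalized[list(group_b)].to_numpy(dtype=float)
    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    log2fc = np.log2((mean_a + FC_PSEUDOCOUNT) / (mean_b + FC_PSEUDOCOUNT))
    t, df, p, _, degenerate = _welch_rows(
        np.log2(a + LOG_PSEUDOCOUNT), np.log2(b + LOG_PSEUDOCOUNT)
    )
    p = np.where(degenerate, 1.0, p)
    padj = bh_fdr(p)
    is_deg = (padj < fdr_threshold) & (np.abs(log2fc) > np.log2(fc_threshold))
    table = pd.DataFrame(
        {
            "log2fc": log2fc,
            "t": np.where(degenerate, 0.0, t),
            "p": p,
            "padj": padj,
            "is_deg": is_deg,
            "degenerate": degenerate,
        },
        index=counts.index.rename("gene_id"),
    )
    table.attrs["fc_pseudocount"] = FC_PSEUDOCOUNT
    table.attrs["log_pseudocount"] = LOG_PSEUDOCOUNT
    logger.info(
        "DEG test: %d genes, %d vs %d samples, %d DEGs (padj<%g, |FC|>%g)",
        len(table),
        len(group_a),
        len(group_b),
        int(is_deg.sum()),
        fdr_threshold,
        fc_threshold,
    )
    return table


def union_degs(deg_tables: list[pd.DataFrame]) -> tuple[set[str], set[str], set[str]]:
    """Union of DEGs across experiments, split by direction.

    Returns (up, down, conflicts): a gene up-regulated in one table and
    down-regulated in another appears in both unions and in ``conflicts``.
    """
    if not deg_tables:
        raise ValueError("need at least one DEG table")
    up: set[str] = set()
    down: set[str] = set()
    for table in deg_tables:
        degs = table[table["is_deg"]]
        up |= set(degs.index[degs["log2fc"] > 0])
        down |= set(degs.index[degs["log2fc"] < 0])
    conflicts = up & down
    if conflicts:
        logger.warning("%d gene(s) up in one experiment and down in another", len(conflicts))
    return up, down, conflicts
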