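"""ChIP-seq downstream integration.

Operations on called peak intervals (BED convention, 0-based half-open):
replicate merging, recurrence filtering across samples, nearest-gene target
assignment with promoter classification, factor co-occupancy, intersection
of targets with DEG unions, and Fisher's-exact over-representation of a gene
list against a set collection.

Peak clustering uses transitive single-linkage by genomic overlap (>= 1 bp by
default, configurable): any two intervals overlapping by at least
``min_overlap`` bases fall in the same cluster, and the cluster is reported
as the union interval [min start, max end).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .containers import GeneAnnotation, GeneSetCollection, as_peak_frame
from .enrichment import bh_fdr

logger = logging.getLogger(__name__)


def _clusters(frames: list[pd.DataFrame], min_overlap: int) -> pd.DataFrame:
    """Single-linkage overlap clustering of peaks pooled across sources.

    Returns one row per cluster: chrom, start, end (union interval),
    n_support (count of distinct source frames contributing).
    """
    pooled = []
    for source, frame in enumerate(frames):
        f = as_peak_frame(frame)[["chrom", "start", "end"]].copy()
        f["source"] = source
        pooled.append(f)
    merged = pd.concat(pooled, ignore_index=True)
    merged = merged.sort_values(["chrom", "start", "end"], kind="mergesort")
    rows = []
    cur = None
    for chrom, start, end, source in merged.itertuples(index=False):
        # two half-open intervals overlap by >= k bp iff next.start <= cur.end - k
        if cur is not None and chrom == cur[0] and start <= cur[2] - min_overlap:
            cur[2] = max(cur[2], end)
            cur[3].add(source)
        else:
            if cur is not None:
                rows.append((cur[0], cur[1], cur[2], len(cur[3])))
            cur = [chrom, start, end, {source}]
    if cur is not None:
        rows.append((cur[0], cur[1], cur[2], len(cur[3])))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "n_support"])


def recurrent_peaks(
    samples: list[pd.DataFrame], min_support: int = 2, min_overlap: int = 1
) -> pd.DataFrame:
    """Union intervals of overlap clusters supported by >= min_support samples."""
    if not 1 <= min_support <= len(samples):
        raise ValueError(
            f"min_support must be in [1, {len(samples)}], got {min_support}"
        )
    clusters = _clusters(samples, min_overlap)
    kept = clusters[clusters["n_support"] >= min_support].drop(columns="n_support")
    logger.info(
        "recurrence filter: %d clusters from %d samples, %d with support >= %d",
        len(clusters),
        len(samples),
        len(kept),
        min_support,
    )
    return kept.reset_index(drop=True)


def merge_replicate_peaks(
    rep1: pd.DataFrame, rep2: pd.DataFrame, min_overlap: int = 1
) -> pd.DataFrame:
    """Fuse overlapping peaks from two replicates into union intervals.

    Only replicate-supported intervals (overlap in both) are emitted.
    """
    return recurrent_peaks([rep1, rep2], min_support=2, min_overlap=min_overlap)


def promoter_windows(
    annotation: GeneAnnotation, upstream: int = 2000, downstream: int = 500
) -> pd.DataFrame:
    """Strand-aware promoter interval per gene, half-open, clamped at 0.

    On the + strand the window covers [tss - upstream, tss + downstream]
    positions; on the - strand [tss - downstream, tss + upstream].
    """
    t = annotation.table
    plus = t["strand"] == "+"
    start = np.where(plus, t["tss"] - upstream, t["tss"] - downstream)
    end = np.where(plus, t["tss"] + downstream + 1, t["tss"] + upstream + 1)
    return pd.DataFrame(
        {
            "gene_id": t["gene_id"],
            "chrom": t["chrom"],
            "start": np.maximum(start, 0).astype(np.int64),
            "end": end.astype(np.int64),
        }
    )


def assign_nearest_gene(
    loci: pd.DataFrame,
    annotation: GeneAnnotation,
    promoter_upstream: int = 2000,
    promoter_downstream: int = 500,
) -> pd.DataFrame:
    """Assign each locus to its closest gene by peak-edge-to-TSS distance.

    Distance is 0 when the locus overlaps a gene's promoter window, in which
    case the locus is classed ``promoter`` and assigned among
    promoter-overlapping genes; otherwise the minimal bp gap between the
    locus and any TSS on the chromosome decides. Ties break to the
    lexicographically smaller gene id.
    """
    loci = as_peak_frame(loci)
    windows = promoter_windows(annotation, promoter_upstream, promoter_downstream)
    missing_chroms = sorted(set(loci["chrom"]) - set(annotation.table["chrom"]))
    if missing_chroms:
        raise ValueError(f"chromosome(s) absent from annotation: {missing_chroms}")
    rows = []
    for chrom, chrom_loci in loci.groupby("chrom", sort=False):
        genes = annotation.by_chrom(chrom).reset_index(drop=True)
        win = windows[windows["chrom"] == chrom].reset_index(drop=True)
        tss = genes["tss"].to_numpy()
        gene_ids = genes["gene_id"].to_numpy()
        order = np.argsort(gene_ids, kind="stable")  # lexicographic tie-break
        for start, end in chrom_loci[["start", "end"]].itertuples(index=False):
            # gap between half-open [start, end) and the TSS position
            gap = np.where(
                tss < start, start - tss, np.where(tss >= end, tss - (end - 1), 0)
            )
            in_promoter = (start < win["end"].to_numpy()) & (win["start"].to_numpy() < end)
            if in_promoter.any():
                cand = order[in_promoter[order]]
                best = cand[np.argmin(gap[cand])] if len(cand) > 1 else cand[0]
                rows.append((chrom, start, end, gene_ids[best], 0, "promoter"))
            else:
                best = order[np.argmin(gap[order])]
                rows.append((chrom, start, end, gene_ids[best], int(gap[best]), "non-promoter"))
    out = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "gene_id", "distance", "region_class"]
    )
    logger.info(
        "nearest-gene assignment: %d loci -> %d distinct target genes (%d promoter)",
        len(out),
        out["gene_id"].nunique(),
        int((out["region_class"] == "promoter").sum()),
    )
    return out


def co_occupancy(
    loci_a: pd.DataFrame, loci_b: pd.DataFrame, min_overlap: int = 1
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Intervals of A overlapping any interval of B, with symmetric counts.

    Returns (table of A loci annotated with the first overlapping B partner,
    counts dict with ``a_overlapping_b`` and ``b_overlapping_a``).
    """

    def _hits(query: pd.DataFrame, subject: pd.DataFrame) -> pd.DataFrame:
        query = as_peak_frame(query)
        subject = as_peak_frame(subject)
        rows = []
        for chrom, q in query.groupby("chrom", sort=False):
            s = subject[subject["chrom"] == chrom]
            if s.empty:
                continue
            s_start = s["start"].to_numpy()
            s_end = s["end"].to_numpy()
            for start, end in q[["start", "end"]].itertuples(index=False):
                overlap = np.minimum(s_end, end) - np.maximum(s_start, start)
                idx = np.flatnonzero(overlap >= min_overlap)
                if idx.size:
                    rows.append((chrom, start, end, int(s_start[idx[0]]), int(s_end[idx[0]])))
        return pd.DataFrame(
            rows, columns=["chrom", "start", "end", "partner_start", "partner_end"]
        )

    a_in_b = _hits(loci_a, loci_b)
    b_in_a = _hits(loci_b, loci_a)
    counts = {"a_overlapping_b": len(a_in_b), "b_overlapping_a": len(b_in_a)}
    logger.info("co-occupancy: %(a_overlapping_b)d of A overlap B, %(b_overlapping_a)d of B overlap A", counts)
    return a_in_b, counts


def intersect_targets_degs(
    targets: set[str], up_degs: set[str], down_degs: set[str]
) -> tuple[set[str], set[str]]:
    """Split the binding-target gene set by DEG direction."""
    targets = set(targets)
    return targets & set(up_degs), targets & set(down_degs)


def fisher_overrepresentation(
    query: set[str],
    universe: set[str],
    collection: GeneSetCollection,
    fdr_threshold: float = 0.1,
    alternative: str = "greater",
) -> pd.DataFrame:
    """One-sided Fisher's exact over-representation of a query gene list.

    For each set S (intersected with the universe) the 2x2 table partitions
    the universe by query membership and set membership; the one-sided p for
    over-representation is the hypergeometric upper tail of the observed
    overlap. BH FDR across sets; rows flagged significant at
    fdr < fdr_threshold. ``alternative="two-sided"`` switches to the
    two-sided Fisher p.
    """
    query = set(query)
    universe = set(universe)
    stray = query - universe
    if stray:
        raise ValueError(f"query gene(s) outside the universe: {sorted(stray)[:10]}")
    m_total = len(universe)
    rows = []
    for name in collection:
        members = set(collection[name]) & universe
        overlap = len(query & members)
        if alternative == "greater":
            p = float(stats.hypergeom.sf(overlap - 1, m_total, len(members), len(query)))
        elif alternative == "two-sided":
            table = [
                [overlap, len(query) - overlap],
                [len(members) - overlap, m_total - len(query) - len(members) + overlap],
            ]
            p = float(stats.fisher_exact(table, alternative="two-sided")[1])
        else:
            raise ValueError(f"unknown alternative {alternative!r}")
        expected = len(query) * len(members) / m_total if m_total else 0.0
        rows.append((name, len(members), overlap, expected, min(max(p, 5e-324), 1.0)))
    out = pd.DataFrame(rows, columns=["set_name", "n_set", "n_overlap", "expected", "p"])
    out["fdr"] = bh_fdr(out["p"].to_numpy())
    out["significant"] = out["fdr"] < fdr_threshold
    out = out.sort_values(["p", "set_name"], kind="mergesort").reset_index(drop=True)
    logger.info(
        "over-representation: %d sets tested, %d significant at fdr < %g",
        len(out),
        int(out["significant"].sum()),
        fdr_threshold,
    )
    return out
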