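"""Gene-set enrichment: competitive Welch set test and preranked GSEA.

Two complementary procedures over a per-gene metric vector:

* ``welch_set_test`` / ``enrich_all`` — competitive test: Welch's
  unequal-variance t between the metrics of genes inside a set and the
  metrics of all genes outside it. Sets are first intersected with the
  measured universe; sets with fewer than ``min_size`` (default 10) or more
  than ``max_size`` (default 500) measured members are excluded. The
  per-set score is -log10(p) with the direction given by sign(t); BH FDR is
  computed across the surviving sets.

* ``preranked_gsea`` — weighted Kolmogorov-Smirnov running-sum enrichment on
  the metric-ranked gene list (weight |metric|, exponent 1). The running sum
  gains |metric_i| / sum_set |metric| at members and loses 1/(N - n_in)
  elsewhere; ES is the extremum. The null is gene-label permutation: random
  same-size gene draws re-scored against the same ranking. NES divides ES by
  the mean |null ES| of matching sign, and the permutation p is
  (1 + #{same-sign null at least as extreme}) / (1 + #{same-sign null}).
  Size filter 15-3000 measured members by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .containers import GeneSetCollection
from .differential import METRIC_CAP, GeneMetricVector, _welch_rows

logger = logging.getLogger(__name__)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# competitive Welch set test


@dataclass
class SetEnrichmentResult:
    set_name: str
    n_in: int
    t: float
    df: float
    p: float
    neglog10p: float
    direction: int


def _as_metric_series(metrics) -> pd.Series:
    if isinstance(metrics, GeneMetricVector):
        return metrics.metric
    return metrics


def welch_set_test(
    metrics,
    members,
    min_size: int = 10,
    max_size: int = 500,
    set_name: str = "",
) -> SetEnrichmentResult | None:
    """Competitive set test; returns None when the set fails the size filter.

    Membership is intersected with the measured genes before the size filter
    is applied, so unmeasured members never count.
    """
    series = _as_metric_series(metrics)
    if series.empty:
        raise ValueError("metric vector is empty")
    if min_size < 2:
        raise ValueError("min_size must be >= 2")
    in_mask = series.index.isin(set(members))
    n_in = int(in_mask.sum())
    if n_in < min_size or n_in > max_size:
        return None
    if n_in == len(series):
        raise ValueError(f"gene set {set_name!r} covers every measured gene; no out-set")
    values = series.to_numpy(dtype=float)
    t, df, p, log10_p, degenerate = _welch_rows(values[in_mask][None, :], values[~in_mask][None, :])
    if degenerate[0]:
        raise ValueError(f"gene set {set_name!r}: in-set and out-set metrics both constant-equal")
    neglog10p = float(min(-log10_p[0], METRIC_CAP))
    return SetEnrichmentResult(
        set_name=set_name,
        n_in=n_in,
        t=float(t[0]),
        df=float(df[0]),
        p=float(p[0]),
        neglog10p=neglog10p,
        direction=int(np.sign(t[0])),
    )


def enrich_all(
    metrics,
    collection: GeneSetCollection,
    min_size: int = 10,
    max_size: int = 500,
) -> tuple[pd.DataFrame, list[str]]:
    """Competitive set test over a collection with BH FDR across survivors.

    Returns (results table sorted by -log10 p descending, names of
    size-filtered sets). Raises when no set survives the size filter.
    """
    results: list[SetEnrichmentResult] = []
    filtered: list[str] = []
    for name in collection:
        res = welch_set_test(metrics, collection[name], min_size, max_size, set_name=name)
        if res is None:
            filtered.append(name)
        else:
            results.append(res)
    if not results:
        raise ValueError("no gene set survived the size filter")
    table = pd.DataFrame([vars(r) for r in results])
    table["fdr"] = bh_fdr(table["p"].to_numpy())
    table = table.sort_values(
        ["neglog10p", "set_name"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    logger.info(
        "competitive set test: %d sets scored, %d size-filtered", len(table), len(filtered)
    )
    return table, filtered


# ---------------------------------------------------------------------------
# preranked GSEA


def _es_from_sorted_positions(pos: np.ndarray, weights: np.ndarray, n_genes: int) -> np.ndarray:
    """Signed enrichment scores for rows of sorted hit positions.

    ``pos``: (m, k) 0-based positions in rank order, sorted ascending per
    row; ``weights``: (m, k) the |metric| values at those positions. The
    running-sum extremum is attained immediately after a hit (positive side)
    or immediately before one (negative side), so only 2k candidates per row
    need evaluating.
    """
    m, k = pos.shape
    if k >= n_genes:
        raise ValueError("gene set covers every ranked gene; ES undefined")
    totals = weights.sum(axis=1, keepdims=True)
    uniform = np.tile(np.arange(1, k + 1, dtype=float) / k, (m, 1))
    with np.errstate(invalid="ignore", divide="ignore"):
        cum_hit = np.where(totals > 0, np.cumsum(weights, axis=1) / totals, uniform)
    miss = (pos - np.arange(k)) / float(n_genes - k)
    after_hit = cum_hit - miss
    before_hit = np.concatenate([np.zeros((m, 1)), cum_hit[:, :-1]], axis=1) - miss
    rows = np.arange(m)
    i_max = after_hit.argmax(axis=1)
    i_min = before_hit.argmin(axis=1)
    pos_extreme = np.maximum(after_hit[rows, i_max], 0.0)
    neg_extreme = np.minimum(before_hit[rows, i_min], 0.0)
    # ranking position where each extremum is attained (for magnitude ties,
    # the extremum reached first along the ranked list wins, matching a
    # literal left-to-right walk of the running sum)
    pos_at = pos[rows, i_max]
    neg_at = pos[rows, i_min] - 1
    take_pos = (pos_extreme > -neg_extreme) | (
        (pos_extreme == -neg_extreme) & (pos_at <= neg_at)
    )
    return np.where(take_pos, pos_extreme, neg_extreme)


def enrichment_score(ranked_abs_metric: np.ndarray, member_positions) -> float:
    """ES of one gene set given |metric| in rank order and member positions."""
    pos = np.sort(np.asarray(member_positions, dtype=np.int64))
    weights = np.asarray(ranked_abs_metric, dtype=float)[pos]
    if weights.sum() == 0:
        raise ValueError("sum of |metric| over the gene set is zero; ES undefined")
    return float(_es_from_sorted_positions(pos[None, :], weights[None, :], len(ranked_abs_metric))[0])


def _null_es(abs_metric: np.ndarray, set_size: int, n_perm: int, rng) -> np.ndarray:
    """Null ES distribution for random same-size gene draws (vectorized)."""
    n_genes = len(abs_metric)
    draws = rng.random((n_perm, n_genes))
    pos = np.argpartition(draws, set_size, axis=1)[:, :set_size]
    pos.sort(axis=1)
    return _es_from_sorted_positions(pos, abs_metric[pos], n_genes)


def rank_genes(metrics) -> pd.Series:
    """Metric series in ranking order: metric descending, ties by gene id."""
    series = _as_metric_series(metrics)
    if series.index.has_duplicates:
        raise ValueError("duplicate gene ids in metric vector")
    frame = series.rename("metric").rename_axis("gene_id").reset_index()
    frame = frame.sort_values(["metric", "gene_id"], ascending=[False, True], kind="mergesort")
    return frame.set_index("gene_id")["metric"]


def preranked_gsea(
    metrics,
    collection: GeneSetCollection,
    n_perm: int = 1000,
    min_size: int = 15,
    max_size: int = 3000,
    seed: int = 0,
) -> pd.DataFrame:
    """Preranked GSEA with gene-permutation null; deterministic under seed.

    Returns one row per surviving set: es, nes, p, fdr, n_in, flag. Sets
    whose same-sign null is empty get NaN NES/p and the flag
    ``no_same_sign_null``; they are excluded from the BH adjustment. The
    null ES distribution is drawn once per distinct set size (it depends on
    the set only through its size).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    ranked = rank_genes(metrics)
    abs_metric = np.abs(ranked.to_numpy(dtype=float))
    position_of = {g: i for i, g in enumerate(ranked.index)}
    rng = np.random.default_rng(seed)
    null_cache: dict[int, np.ndarray] = {}
    rows = []
    for name in collection:
        pos = sorted(position_of[g] for g in collection[name] if g in position_of)
        n_in = len(pos)
        if n_in < min_size or n_in > max_size:
            continue
        es = enrichment_score(abs_metric, pos)
        if n_in not in null_cache:
            null_cache[n_in] = _null_es(abs_metric, n_in, n_perm, rng)
        null = null_cache[n_in]
        same_sign = null[null > 0] if es >= 0 else null[null < 0]
        if same_sign.size == 0:
            rows.append((name, n_in, es, np.nan, np.nan, "no_same_sign_null"))
            continue
        nes = es / np.abs(same_sign).mean()
        p = (1.0 + np.sum(np.abs(same_sign) >= abs(es))) / (1.0 + same_sign.size)
        rows.append((name, n_in, es, nes, p, ""))
    if not rows:
        raise ValueError("no gene set survived the size filter")
    table = pd.DataFrame(rows, columns=["set_name", "n_in", "es", "nes", "p", "flag"])
    table["fdr"] = np.nan
    scored = table["p"].notna()
    if scored.any():
        table.loc[scored, "fdr"] = bh_fdr(table.loc[scored, "p"].to_numpy())
    table = table.sort_values(["p", "set_name"], kind="mergesort", na_position="last").reset_index(
        drop=True
    )
    logger.info(
        "preranked GSEA: %d sets scored over %d genes, %d permutations",
        len(table),
        len(ranked),
        n_perm,
    )
    return table
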