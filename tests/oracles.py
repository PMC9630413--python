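"""Independent brute-force reference implementations used as test oracles.

Everything here is deliberately naive (explicit loops, exact arithmetic where
feasible) and shares no code with the package implementation.
"""

from __future__ import annotations

import math
from fractions import Fraction

import numpy as np


def walsh_median_brute(values) -> float:
    """Median of all Walsh averages via explicit double loop."""
    x = list(map(float, values))
    averages = []
    for i in range(len(x)):
        for j in range(i, len(x)):
            averages.append((x[i] + x[j]) / 2.0)
    averages.sort()
    n = len(averages)
    mid = n // 2
    if n % 2:
        return averages[mid]
    return (averages[mid - 1] + averages[mid]) / 2.0


def welch_brute(a, b):
    """Textbook Welch t, Welch-Satterthwaite df and two-sided p."""
    from scipy import stats

    a = list(map(float, a))
    b = list(map(float, b))
    na, nb = len(a), len(b)
    ma = sum(a) / na
    mb = sum(b) / nb
    va = sum((x - ma) ** 2 for x in a) / (na - 1)
    vb = sum((x - mb) ** 2 for x in b) / (nb - 1)
    se2 = va / na + vb / nb
    t = (ma - mb) / math.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return t, df, p


def gsea_es_brute(metrics_ranked, member_mask) -> float:
    """Weighted KS running-sum ES by walking every rank position."""
    high, low = gsea_running_extrema_brute(metrics_ranked, member_mask)
    return high if high >= -low else low


def gsea_running_extrema_brute(metrics_ranked, member_mask):
    """(max, min) of the weighted KS running sum, by explicit walk."""
    weights = [abs(float(m)) for m in metrics_ranked]
    n = len(weights)
    n_in = sum(member_mask)
    total = sum(w for w, hit in zip(weights, member_mask) if hit)
    running = 0.0
    high = 0.0
    low = 0.0
    for w, hit in zip(weights, member_mask):
        if hit:
            running += w / total
        else:
            running -= 1.0 / (n - n_in)
        high = max(high, running)
        low = min(low, running)
    return high, low


def hypergeom_upper_tail_exact(overlap, universe, set_size, query_size) -> Fraction:
    """P(X >= overlap) for X hypergeometric, in exact rational arithmetic."""
    total = math.comb(universe, query_size)
    acc = Fraction(0)
    for k in range(overlap, min(set_size, query_size) + 1):
        acc += Fraction(
            math.comb(set_size, k) * math.comb(universe - set_size, query_size - k), total
        )
    return acc


def bh_brute(p_values):
    """Benjamini-Hochberg step-up by the definition: min over the tail of p*m/rank."""
    p = list(map(float, p_values))
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adjusted = [0.0] * m
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running_min = min(running_min, p[i] * m / rank_from_top)
        adjusted[i] = running_min
    return adjusted


def size_factors_brute(counts: np.ndarray) -> np.ndarray:
    """Median-of-ratios size factors straight from the definition."""
    n_genes, n_samples = counts.shape
    reference = []
    usable = []
    for g in range(n_genes):
        row = counts[g]
        if (row > 0).all():
            log_gm = sum(math.log(c) for c in row) / n_samples
            reference.append(math.exp(log_gm))
            usable.append(g)
    factors = []
    for j in range(n_samples):
        ratios = sorted(counts[g, j] / reference[i] for i, g in enumerate(usable))
        k = len(ratios)
        mid = k // 2
        med = ratios[mid] if k % 2 else (ratios[mid - 1] + ratios[mid]) / 2.0
        factors.append(med)
    return np.array(factors)
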