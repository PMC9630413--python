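"""Per-gene two-group Welch statistics and direction-aware gene metrics.

The gene-level score used for enrichment is the signed log p-value,

    metric = -log10(p) * sign(t),

where t and the two-sided p come from Welch's unequal-variance t-test between
amplified and neutral samples. The metric is computed from the log survival
function of the t distribution so it stays meaningful when p underflows, and
its magnitude is capped (default 300). The alternative ranking statistic for
correlation-driven analyses is the Pearson r of every gene against a chosen
target gene's expression.

One Welch implementation (`_welch_rows`) backs the scalar test, the per-gene
genome scan, the gene-set test and the immune-fraction test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

METRIC_CAP = 300.0  # |metric| cap guarding against p-value underflow
_LN10 = np.log(10.0)


@dataclass
class TestResult:
    """Welch test outcome: t, Welch-Satterthwaite df, two-sided p.

    ``log10_p`` is log10 of the two-sided p computed via the log survival
    function; it is the quantity the signed metric is built from and remains
    finite-precision far below the smallest representable p.
    """

    t: float
    df: float
    p: float
    log10_p: float


@dataclass
class GeneMetricVector:
    """Per-gene signed statistic feeding enrichment.

    ``kind`` is "signed_log_p" (Welch scans) or "pearson_r" (correlation
    ranking); ``table`` carries the per-gene backing statistics.
    """

    metric: pd.Series
    kind: str
    table: pd.DataFrame

    def __post_init__(self) -> None:
        if not np.isfinite(self.metric.to_numpy(dtype=float)).all():
            raise ValueError("gene metrics must be finite after capping")


def _welch_rows(a: np.ndarray, b: np.ndarray):
    """Row-wise Welch t-test between 2-d arrays ``a`` (rows x nA) and ``b``.

    Returns (t, df, p, log10_p, degenerate) arrays. Rows where both groups
    are constant with equal values are flagged degenerate and get t=0, p=1.
    Rows with zero pooled standard error but unequal means get t=+/-inf, p=0
    and log10_p=-inf (callers cap the metric).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = a.shape[1], b.shape[1]
    if na < 2 or nb < 2:
        raise ValueError("Welch's t-test requires >= 2 observations per group")
    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    var_a = a.var(axis=1, ddof=1)
    var_b = b.var(axis=1, ddof=1)
    se2 = var_a / na + var_b / nb
    diff = mean_a - mean_b
    degenerate = (se2 == 0) & (diff == 0)
    infinite = (se2 == 0) & (diff != 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / np.sqrt(se2)
        df = se2**2 / (
            (var_a / na) ** 2 / (na - 1) + (var_b / nb) ** 2 / (nb - 1)
        )
    t = np.where(degenerate, 0.0, t)
    t = np.where(infinite, np.where(diff > 0, np.inf, -np.inf), t)
    df = np.where(se2 == 0, float(na + nb - 2), df)
    abs_t = np.abs(t)
    with np.errstate(over="ignore"):
        log_sf = stats.t.logsf(np.where(np.isfinite(abs_t), abs_t, 0.0), df)
    log10_p = (log_sf + np.log(2.0)) / _LN10
    log10_p = np.where(infinite, -np.inf, log10_p)
    log10_p = np.where(degenerate, 0.0, np.minimum(log10_p, 0.0))
    p = np.power(10.0, np.maximum(log10_p, -320.0))
    p = np.where(degenerate, 1.0, np.minimum(p, 1.0))
    p = np.where(infinite, 0.0, p)
    return t, df, p, log10_p, degenerate


def welch_t(a, b) -> TestResult:
    """Welch's unequal-variance t-test between two samples (two-sided)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.ndim != 1 or b.ndim != 1:
        raise ValueError("welch_t expects 1-d vectors")
    t, df, p, log10_p, degenerate = _welch_rows(a[None, :], b[None, :])
    if degenerate[0]:
        raise ValueError("both groups constant with equal value: Welch t is 0/0")
    return TestResult(t=float(t[0]), df=float(df[0]), p=float(p[0]), log10_p=float(log10_p[0]))


def signed_log_p_metric(result: TestResult, cap: float = METRIC_CAP) -> float:
    """-log10(p) * sign(t), with sign(0) := 0 and magnitude capped."""
    sign = float(np.sign(result.t))
    magnitude = min(-result.log10_p, cap)
    return sign * magnitude


def differential_profile(
    matrix, group_a: list[str], group_b: list[str], cap: float = METRIC_CAP
) -> GeneMetricVector:
    """Genome-wide Welch scan: one signed log-p metric per gene (A minus B).

    Genes constant-and-equal in both groups do not abort the scan; they get
    metric 0 and a ``degenerate`` flag.
    """
    overlap = sorted(set(group_a) & set(group_b))
    if overlap:
        raise ValueError(f"groups overlap: {overlap}")
    for group in (group_a, group_b):
        missing = [s for s in group if s not in matrix.values.columns]
        if missing:
            raise ValueError(f"sample(s) not in matrix: {missing}")
    a = matrix.values[list(group_a)].to_numpy(dtype=float)
    b = matrix.values[list(group_b)].to_numpy(dtype=float)
    t, df, p, log10_p, degenerate = _welch_rows(a, b)
    metric = np.sign(t) * np.minimum(-log10_p, cap)
    metric = np.where(degenerate, 0.0, metric)
    n_deg = int(degenerate.sum())
    if n_deg:
        logger.warning("%d gene(s) constant in both groups; metric set to 0", n_deg)
    n_capped = int((np.abs(metric) >= cap).sum())
    table = pd.DataFrame(
        {
            "t": np.where(degenerate, 0.0, t),
            "df": df,
            "p": p,
            "metric": metric,
            "degenerate": degenerate,
            "capped": np.abs(metric) >= cap,
        },
        index=matrix.values.index.rename("gene_id"),
    )
    table.attrs["metric_cap"] = cap
    table.attrs["n_capped"] = n_capped
    logger.info(
        "differential profile: %d genes, %d vs %d samples, %d degenerate, %d capped",
        len(table),
        len(group_a),
        len(group_b),
        n_deg,
        n_capped,
    )
    return GeneMetricVector(metric=table["metric"], kind="signed_log_p", table=table)


def correlation_profile(matrix, target_gene: str) -> GeneMetricVector:
    """Pearson r of every other gene against the target gene's expression."""
    if target_gene not in matrix.values.index:
        raise ValueError(f"target gene {target_gene!r} not in matrix")
    values = matrix.values.to_numpy(dtype=float)
    if values.shape[1] < 3:
        raise ValueError("correlation profile requires >= 3 samples")
    target = matrix.values.loc[target_gene].to_numpy(dtype=float)
    target_c = target - target.mean()
    target_norm = np.sqrt((target_c**2).sum())
    if target_norm == 0:
        raise ValueError(f"target gene {target_gene!r} has zero variance")
    centered = values - values.mean(axis=1, keepdims=True)
    norms = np.sqrt((centered**2).sum(axis=1))
    zero_var = norms == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        r = centered @ target_c / (norms * target_norm)
    r = np.where(zero_var, 0.0, r)
    table = pd.DataFrame(
        {"r": r, "zero_variance": zero_var},
        index=matrix.values.index.rename("gene_id"),
    )
    table = table.drop(index=target_gene)
    return GeneMetricVector(metric=table["r"].rename("metric"), kind="pearson_r", table=table)
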