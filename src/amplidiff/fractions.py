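"""Differential immune-cell-type abundance between amplified and neutral samples.

Input is a sample x cell-type matrix of deconvolved immune fractions (each
row a composition summing to 1, e.g. 22 leukocyte types). Per cell type a
Welch t-test (amplified minus neutral) on the raw proportion scale yields the
same signed log-p metric used for genes, with BH FDR across the cell types.
An optional logit transform is available; compositional dependence between
columns is acknowledged but not corrected.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .differential import METRIC_CAP, _welch_rows
from .enrichment import bh_fdr

logger = logging.getLogger(__name__)

ROW_SUM_TOLERANCE = 1e-6


def validate_fractions(fractions: pd.DataFrame) -> None:
    values = fractions.to_numpy(dtype=float)
    if ((values < 0) | (values > 1)).any():
        raise ValueError("fractions must lie in [0, 1]")
    sums = values.sum(axis=1)
    bad = np.flatnonzero(np.abs(sums - 1.0) >= ROW_SUM_TOLERANCE)
    if bad.size:
        raise ValueError(
            f"fraction rows must sum to 1 within {ROW_SUM_TOLERANCE}; "
            f"offending sample(s): {list(fractions.index[bad][:10])}"
        )


def differential_fractions(
    fractions: pd.DataFrame,
    amplified: list[str],
    neutral: list[str],
    logit: bool = False,
    cap: float = METRIC_CAP,
) -> pd.DataFrame:
    """Per-cell-type Welch test table: t, p, metric, fdr (amplified - neutral).

    Cell types constant-and-equal in both groups are flagged and get metric
    0 with p = 1 rather than aborting the scan.
    """
    validate_fractions(fractions)
    overlap = sorted(set(amplified) & set(neutral))
    if overlap:
        raise ValueError(f"groups overlap: {overlap}")
    for group in (amplified, neutral):
        missing = [s for s in group if s not in fractions.index]
        if missing:
            raise ValueError(f"sample(s) not in fraction matrix: {missing}")
        if len(group) < 2:
            raise ValueError("each group needs >= 2 samples")
    values = fractions.to_numpy(dtype=float).T  # cell types x samples
    if logit:
        eps = 1e-6
        clipped = np.clip(values, eps, 1 - eps)
        values = np.log(clipped / (1 - clipped))
    col_index = {s: i for i, s in enumerate(fractions.index)}
    a = values[:, [col_index[s] for s in amplified]]
    b = values[:, [col_index[s] for s in neutral]]
    t, df, p, log10_p, degenerate = _welch_rows(a, b)
    metric = np.sign(t) * np.minimum(-log10_p, cap)
    metric = np.where(degenerate, 0.0, metric)
    p = np.where(degenerate, 1.0, p)
    table = pd.DataFrame(
        {
            "t": np.where(degenerate, 0.0, t),
            "df": df,
            "p": p,
            "metric": metric,
            "degenerate": degenerate,
        },
        index=fractions.columns.rename("cell_type"),
    )
    table["fdr"] = bh_fdr(table["p"].to_numpy())
    logger.info(
        "differential fractions: %d cell types, %d vs %d samples, %d degenerate",
        len(table),
        len(amplified),
        len(neutral),
        int(degenerate.sum()),
    )
    return table
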