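"""Copy-number stratification of samples for a chosen oncogene.

A sample is AMPLIFIED when its log2 segment-mean copy-number ratio for the
oncogene strictly exceeds the amplification threshold (default 0.3), NEUTRAL
when the ratio lies inside the closed symmetric band [-band, threshold]
(default [-0.3, 0.3]), and EXCLUDED otherwise (deep-loss tail). Excluded
samples are dropped from all downstream group comparisons, never merged into
the neutral group.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from enum import Enum

import pandas as pd

from .containers import GeneAnnotation

logger = logging.getLogger(__name__)


class CNStatus(Enum):
    AMPLIFIED = "amplified"
    NEUTRAL = "neutral"
    EXCLUDED = "excluded"


def classify_cn_status(
    log_ratio: float, amp_threshold: float = 0.3, neutral_band: float = 0.3
) -> CNStatus:
    """Classify one log2 copy-number ratio.

    The amplified boundary is strict (> threshold); the neutral band is
    closed on both sides.
    """
    if not math.isfinite(log_ratio):
        raise ValueError(f"non-finite copy-number log ratio: {log_ratio}")
    if log_ratio > amp_threshold:
        return CNStatus.AMPLIFIED
    if -neutral_band <= log_ratio <= amp_threshold:
        return CNStatus.NEUTRAL
    return CNStatus.EXCLUDED


@dataclass
class Stratification:
    amplified: list[str]
    neutral: list[str]
    excluded: list[str]

    def as_frame(self) -> pd.DataFrame:
        rows = [(s, CNStatus.AMPLIFIED.value) for s in self.amplified]
        rows += [(s, CNStatus.NEUTRAL.value) for s in self.neutral]
        rows += [(s, CNStatus.EXCLUDED.value) for s in self.excluded]
        return pd.DataFrame(rows, columns=["sample_id", "cn_status"])


def stratify_cohort(
    cn: pd.DataFrame,
    oncogene: str,
    samples: list[str] | None = None,
    amp_threshold: float = 0.3,
    neutral_band: float = 0.3,
    min_group_size: int = 2,
) -> Stratification:
    """Partition samples by copy-number status of ``oncogene``.

    ``cn`` is a sample x gene table of log2 ratios. Order within each output
    group follows the input sample order. Raises when the amplified or
    neutral group ends up smaller than ``min_group_size`` (two-group tests
    downstream are undefined below that).
    """
    if oncogene not in cn.columns:
        raise ValueError(f"oncogene {oncogene!r} absent from copy-number table")
    if samples is None:
        samples = list(cn.index)
    missing = [s for s in samples if s not in cn.index]
    if missing:
        raise ValueError(f"sample(s) missing from copy-number table: {missing}")
    groups: dict[CNStatus, list[str]] = {s: [] for s in CNStatus}
    for sample in samples:
        status = classify_cn_status(float(cn.at[sample, oncogene]), amp_threshold, neutral_band)
        groups[status].append(sample)
    result = Stratification(
        amplified=groups[CNStatus.AMPLIFIED],
        neutral=groups[CNStatus.NEUTRAL],
        excluded=groups[CNStatus.EXCLUDED],
    )
    logger.info(
        "stratification on %s: %d amplified, %d neutral, %d excluded",
        oncogene,
        len(result.amplified),
        len(result.neutral),
        len(result.excluded),
    )
    for label, group in (("amplified", result.amplified), ("neutral", result.neutral)):
        if len(group) < min_group_size:
            raise ValueError(
                f"{label} group has {len(group)} sample(s); "
                f"need >= {min_group_size} for downstream two-group tests"
            )
    return result


def segments_to_gene_values(
    segments: pd.DataFrame, annotation: GeneAnnotation, genes: list[str] | None = None
) -> pd.DataFrame:
    """Map per-sample copy-number segments onto genes (helper).

    ``segments`` columns: sample_id, chrom, start, end, log_ratio (half-open
    intervals). The segment overlapping a gene's TSS wins; if several do,
    the one with the longer overlap of the gene body is used. Genes whose TSS
    is covered by no segment in a sample get NaN.
    """
    required = {"sample_id", "chrom", "start", "end", "log_ratio"}
    missing = required - set(segments.columns)
    if missing:
        raise ValueError(f"segment table missing columns: {sorted(missing)}")
    ann = annotation.table.set_index("gene_id")
    if genes is None:
        genes = list(ann.index)
    out = pd.DataFrame(
        index=pd.Index(sorted(segments["sample_id"].unique()), name="sample_id"),
        columns=genes,
        dtype=float,
    )
    for sample_id, seg in segments.groupby("sample_id"):
        for gene in genes:
            g = ann.loc[gene]
            hits = seg[(seg["chrom"] == g["chrom"]) & (seg["start"] <= g["tss"]) & (g["tss"] < seg["end"])]
            if hits.empty:
                continue
            if len(hits) > 1:
                overlap = hits[["end"]].copy()
                overlap["len"] = hits[["end"]].clip(upper=g["end"])["end"] - hits[["start"]].clip(
                    lower=g["start"]
                )["start"]
                hits = hits.loc[[overlap["len"].idxmax()]]
            out.at[sample_id, gene] = float(hits["log_ratio"].iloc[0])
    return out
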