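"""In-memory containers shared across the pipeline.

Thin dataclasses around pandas objects: the point is invariant checking
(unique identifiers, metadata coverage, coordinate sanity), not abstraction.
Genomic intervals follow the BED convention throughout: 0-based, half-open
[start, end). A gene's TSS is a single 0-based position (start of the body on
the + strand, end-1 on the - strand).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

PEAK_COLUMNS = ["chrom", "start", "end"]


def _check_unique(ids, what: str) -> None:
    idx = pd.Index(ids)
    if idx.has_duplicates:
        dups = sorted(idx[idx.duplicated()].unique().tolist())
        raise ValueError(f"duplicate {what}: {dups}")


@dataclass
class ExpressionMatrix:
    """Gene x sample continuous expression values plus per-sample metadata.

    ``values`` is indexed by gene id with sample ids as columns;
    ``sample_meta`` is indexed by sample id and must carry a ``cancer_type``
    column covering every sample in the matrix.
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.values.index, "gene id(s)")
        _check_unique(self.values.columns, "sample id(s)")
        if "cancer_type" not in self.sample_meta.columns:
            raise ValueError("sample metadata must have a 'cancer_type' column")
        missing = [s for s in self.values.columns if s not in self.sample_meta.index]
        if missing:
            raise ValueError(f"samples missing from metadata: {missing}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def cancer_types(self) -> pd.Series:
        """cancer_type label per sample, aligned to the matrix columns."""
        return self.sample_meta.loc[self.values.columns, "cancer_type"]

    def subset_genes(self, genes) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[list(genes)], self.sample_meta)


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT semantics): unique names, non-empty member lists.

    Members are stored deduplicated in first-seen order.
    """

    sets: dict[str, tuple[str, ...]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if len(members) == 0:
                raise ValueError(f"gene set {name!r} is empty")
            deduped = tuple(dict.fromkeys(members))
            self.sets[name] = deduped
        self.descriptions = {n: self.descriptions.get(n, "") for n in self.sets}

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def __getitem__(self, name: str) -> tuple[str, ...]:
        return self.sets[name]

    def names(self) -> list[str]:
        return list(self.sets)

    def total_members(self) -> int:
        return sum(len(m) for m in self.sets.values())


@dataclass
class GeneAnnotation:
    """Gene coordinates: id, chrom, strand, body [start, end), derived TSS."""

    table: pd.DataFrame
    chrom_lengths: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        required = {"gene_id", "chrom", "strand", "start", "end", "tss"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"annotation missing columns: {sorted(missing)}")
        _check_unique(self.table["gene_id"], "gene id(s)")
        bad_strand = set(self.table["strand"]) - {"+", "-"}
        if bad_strand:
            raise ValueError(f"invalid strand values: {sorted(bad_strand)}")
        t = self.table
        if ((t["tss"] < t["start"]) | (t["tss"] >= t["end"])).any():
            raise ValueError("every TSS must lie within its gene body")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.table["gene_id"])

    def by_chrom(self, chrom: str) -> pd.DataFrame:
        return self.table[self.table["chrom"] == chrom]


def as_peak_frame(df: pd.DataFrame) -> pd.DataFrame:
    """Validate and coordinate-sort a peak table (chrom, start, end[, ...])."""
    missing = [c for c in PEAK_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"peak table missing columns: {missing}")
    if len(df) and (df["start"] >= df["end"]).any():
        bad = df.index[df["start"] >= df["end"]][0]
        raise ValueError(f"peak at row {bad} has start >= end")
    out = df.copy()
    out["start"] = out["start"].astype(np.int64)
    out["end"] = out["end"].astype(np.int64)
    return out.sort_values(PEAK_COLUMNS, kind="mergesort").reset_index(drop=True)
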