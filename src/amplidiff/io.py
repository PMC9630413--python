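"""Readers and writers for every on-disk format the pipeline touches.

All tabular formats are plain TSV. Gene sets use the GMT dialect
(name TAB description TAB member...), peaks use BED3+ (0-based half-open),
gene annotation is a TSV with optional ``#chrom_length`` header lines
declaring chromosome sizes. Readers reject malformed records with
line-number-bearing errors; writers round-trip losslessly with their readers.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .containers import ExpressionMatrix, GeneAnnotation, GeneSetCollection, as_peak_frame

FLOAT_FORMAT = "%.10g"  # fixed float rendering keeps pipeline outputs byte-stable


class ParseError(ValueError):
    """Malformed record in an input file; message carries the line number."""


# ---------------------------------------------------------------------------
# matrices


def _read_indexed_tsv(path: str | Path, what: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dups = sorted(df.index[df.index.duplicated()].unique().tolist())
        raise ParseError(f"{path}: duplicate {what} id(s): {dups}")
    if df.columns.has_duplicates:
        dups = sorted(df.columns[df.columns.duplicated()].unique().tolist())
        raise ParseError(f"{path}: duplicate column id(s): {dups}")
    return df


def read_expression_matrix(path: str | Path, metadata_path: str | Path) -> ExpressionMatrix:
    values = _read_indexed_tsv(path, "gene")
    meta = _read_indexed_tsv(metadata_path, "sample")
    return ExpressionMatrix(values, meta)


def write_expression_matrix(
    matrix: ExpressionMatrix, path: str | Path, metadata_path: str | Path | None = None
) -> None:
    matrix.values.rename_axis("gene_id").to_csv(path, sep="\t", float_format=FLOAT_FORMAT)
    if metadata_path is not None:
        matrix.sample_meta.rename_axis("sample_id").to_csv(metadata_path, sep="\t")


def read_count_matrix(path: str | Path) -> pd.DataFrame:
    counts = _read_indexed_tsv(path, "gene")
    if not (counts.dtypes.map(pd.api.types.is_integer_dtype)).all():
        raise ParseError(f"{path}: count matrix must be integer-valued")
    if (counts < 0).any().any():
        raise ParseError(f"{path}: counts must be nonnegative")
    return counts


def read_copy_number(path: str | Path) -> pd.DataFrame:
    """Sample x gene table of log2 segment-mean copy-number ratios."""
    cn = _read_indexed_tsv(path, "sample")
    if not cn.map(lambda v: pd.notna(v)).all().all():
        raise ParseError(f"{path}: copy-number table contains missing values")
    return cn


def read_fraction_matrix(path: str | Path) -> pd.DataFrame:
    """Sample x cell-type immune fraction matrix; rows must sum to ~1."""
    fractions = _read_indexed_tsv(path, "sample")
    from .fractions import validate_fractions

    validate_fractions(fractions)
    return fractions


def write_table(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", float_format=FLOAT_FORMAT, index=index)


# ---------------------------------------------------------------------------
# GMT gene sets


def read_gmt(path: str | Path) -> GeneSetCollection:
    sets: dict[str, tuple[str, ...]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}:{lineno}: GMT line has {len(parts)} fields, need >= 3")
            name, desc, *members = parts
            members = [m for m in members if m]
            if not members:
                raise ParseError(f"{path}:{lineno}: gene set {name!r} has no members")
            if name in sets:
                raise ParseError(f"{path}:{lineno}: duplicate gene set name {name!r}")
            sets[name] = tuple(dict.fromkeys(members))
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in collection:
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *collection[name]]) + "\n")


# ---------------------------------------------------------------------------
# BED peaks


def read_bed(path: str | Path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}:{lineno}: BED line has {len(parts)} fields, need >= 3")
            chrom = parts[0]
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinate") from exc
            if start >= end:
                raise ParseError(f"{path}:{lineno}: start {start} >= end {end}")
            if start < 0:
                raise ParseError(f"{path}:{lineno}: negative start {start}")
            rows.append((chrom, start, end))
    return as_peak_frame(pd.DataFrame(rows, columns=["chrom", "start", "end"]))


def write_bed(peaks: pd.DataFrame, path: str | Path) -> None:
    as_peak_frame(peaks)[["chrom", "start", "end"]].to_csv(
        path, sep="\t", header=False, index=False
    )


# ---------------------------------------------------------------------------
# gene annotation


def read_annotation(path: str | Path) -> GeneAnnotation:
    chrom_lengths: dict[str, int] = {}
    header_lines = 0
    with open(path) as fh:
        for line in fh:
            if line.startswith("#chrom_length"):
                _, chrom, length = line.rstrip("\n").split("\t")
                chrom_lengths[chrom] = int(length)
                header_lines += 1
            else:
                break
    table = pd.read_csv(path, sep="\t", skiprows=header_lines)
    return GeneAnnotation(table, chrom_lengths)


def write_annotation(ann: GeneAnnotation, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, length in sorted(ann.chrom_lengths.items()):
            fh.write(f"#chrom_length\t{chrom}\t{length}\n")
        ann.table.to_csv(fh, sep="\t", index=False)
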