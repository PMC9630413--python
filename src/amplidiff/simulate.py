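"""Synthetic cohort generator.

Emulates the statistical structure the pipeline's analyses presuppose, so
every downstream stage can be exercised and scored against known truth
without external data:

* an expression matrix on a continuous (log-like) scale with per-cancer-type
  location/scale shifts, a low-expression decoy gene fraction placed below
  the filter threshold, and an amplified subpopulation in which a designated
  oncogene-target gene set is shifted up and a designated interferon-response
  ("IFN") set is shifted down by stated standardized effects;
* a per-sample copy-number table whose oncogene column separates amplified
  (log2 ratio in (0.4, 1.2)), neutral ((-0.25, 0.25)) and excluded deep-loss
  ((-1.0, -0.35)) samples by construction;
* a negative-binomial count matrix whose group fold changes are 2**effect
  for the designated sets;
* replicate ChIP peak sets with one promoter peak per target gene (small
  coordinate jitter) plus non-recurring background peaks laid on
  replicate-specific grid phases, so cross-replicate background overlap is
  impossible by spacing;
* Dirichlet immune-fraction matrices with a multiplicative alpha effect on
  one cell type in the amplified group.

Each artifact draws from its own RNG stream (seed + fixed offset), so
regenerating one artifact never perturbs another. Everything is fully
deterministic under the design seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, GeneAnnotation, GeneSetCollection, as_peak_frame

# RNG stream offsets per artifact
_STREAM_LABELS = 0
_STREAM_ANNOTATION = 1
_STREAM_EXPRESSION = 2
_STREAM_COPY_NUMBER = 3
_STREAM_COUNTS = 4
_STREAM_PEAKS = 5
_STREAM_FRACTIONS = 6
_STREAM_SETS = 7

AMPLIFIED_CN_RANGE = (0.4, 1.2)
NEUTRAL_CN_RANGE = (-0.25, 0.25)
EXCLUDED_CN_RANGE = (-1.0, -0.35)

DEFAULT_CELL_TYPES = tuple(f"immune_cell_{i:02d}" for i in range(1, 23))


@dataclass
class SimulationDesign:
    """Knobs of the synthetic cohort; defaults are the reference conditions."""

    n_genes: int = 5000
    n_samples: int = 80
    cancer_types: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"ductal": (0.0, 1.0), "lobular": (6.0, 1.25)}
    )
    amplified_fraction: float = 0.5
    excluded_fraction: float = 0.05
    oncogene: str = "MYC"
    target_set_size: int = 50
    ifn_set_size: int = 50
    target_set_effect: float = 1.0  # standardized mean shift in amplified samples
    ifn_set_effect: float = -0.8
    n_decoy_sets: int = 48
    decoy_set_sizes: tuple[int, ...] = (25, 50, 100)
    decoy_gene_fraction: float = 0.05  # low-expression genes exercising the filter
    noise_sd: float = 10.0
    baseline_mean: float = 60.0
    baseline_sd: float = 15.0
    baseline_floor: float = 30.0
    low_baseline_range: tuple[float, float] = (2.0, 12.0)
    nb_dispersion: float = 0.05
    count_depth_factor: float = 4.0
    cell_types: tuple[str, ...] = DEFAULT_CELL_TYPES
    dirichlet_alpha: tuple[float, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.amplified_fraction < 1:
            raise ValueError("amplified_fraction must be in (0, 1)")
        if not 0 <= self.excluded_fraction < 1 - self.amplified_fraction:
            raise ValueError("excluded_fraction leaves no room for neutral samples")
        if self.n_genes < 10:
            raise ValueError("n_genes must be >= 10")
        for name in ("n_samples", "target_set_size", "ifn_set_size"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        reserved = 1 + self.target_set_size + self.ifn_set_size
        if reserved >= self.n_genes:
            raise ValueError("designated sets do not fit into n_genes")
        if self.dirichlet_alpha is not None and len(self.dirichlet_alpha) != len(self.cell_types):
            raise ValueError("dirichlet_alpha length must match cell_types")

    def alpha(self) -> np.ndarray:
        if self.dirichlet_alpha is not None:
            return np.asarray(self.dirichlet_alpha, dtype=float)
        return 8.0 * 0.85 ** np.arange(len(self.cell_types))


@dataclass
class CohortTruth:
    """Ground truth sufficient to score every downstream recovery test."""

    groups: pd.Series  # sample -> amplified | neutral | excluded
    cancer_type: pd.Series
    target_set: tuple[str, ...]
    ifn_set: tuple[str, ...]
    low_expression_genes: tuple[str, ...]
    oncogene: str

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"group": self.groups, "cancer_type": self.cancer_type}
        ).rename_axis("sample_id")


@dataclass
class SyntheticCohort:
    expression: ExpressionMatrix
    copy_number: pd.DataFrame
    counts: pd.DataFrame
    gene_sets: GeneSetCollection
    truth: CohortTruth


def gene_ids(design: SimulationDesign) -> list[str]:
    return [design.oncogene] + [f"G{i:05d}" for i in range(1, design.n_genes)]


def sample_ids(design: SimulationDesign) -> list[str]:
    return [f"S{i:04d}" for i in range(1, design.n_samples + 1)]


def sample_groups(design: SimulationDesign) -> pd.DataFrame:
    """Per-sample cancer type and amplification group (shared RNG stream).

    Both the expression/count cohort and the fraction matrix derive their
    group labels from this function, so they always agree.
    """
    rng = np.random.default_rng(design.seed + _STREAM_LABELS)
    samples = sample_ids(design)
    types = rng.choice(list(design.cancer_types), size=len(samples))
    u = rng.random(len(samples))
    group = np.where(
        u < design.amplified_fraction,
        "amplified",
        np.where(u < design.amplified_fraction + design.excluded_fraction, "excluded", "neutral"),
    )
    return pd.DataFrame(
        {"cancer_type": types, "group": group}, index=pd.Index(samples, name="sample_id")
    )


def _designated_genes(design: SimulationDesign):
    """Deterministic choice of target set, IFN set and low-expression decoys."""
    rng = np.random.default_rng(design.seed + _STREAM_SETS)
    pool = np.array(gene_ids(design)[1:])  # oncogene never a set member
    perm = rng.permutation(len(pool))
    target = tuple(pool[perm[: design.target_set_size]])
    ifn = tuple(pool[perm[design.target_set_size : design.target_set_size + design.ifn_set_size]])
    rest = pool[perm[design.target_set_size + design.ifn_set_size :]]
    n_low = int(round(design.decoy_gene_fraction * design.n_genes))
    n_low = min(n_low, max(len(rest) - 10, 0))
    low = tuple(rest[:n_low])
    free = rest[n_low:]
    return target, ifn, low, free, rng


def generate_gene_sets(design: SimulationDesign) -> GeneSetCollection:
    """Truth sets plus random decoy sets drawn from unperturbed genes."""
    target, ifn, _, free, rng = _designated_genes(design)
    sets: dict[str, tuple[str, ...]] = {"MYC_TARGETS": target, "IFN_SIGNALING": ifn}
    descriptions = {
        "MYC_TARGETS": "up-regulated in amplified samples (truth)",
        "IFN_SIGNALING": "down-regulated in amplified samples (truth)",
    }
    sizes = design.decoy_set_sizes
    for i in range(design.n_decoy_sets):
        size = min(sizes[i % len(sizes)], len(free))
        members = tuple(rng.choice(free, size=size, replace=False))
        name = f"RANDOM_SET_{i + 1:03d}"
        sets[name] = members
        descriptions[name] = "random decoy set"
    return GeneSetCollection(sets, descriptions)


def generate_annotation(design: SimulationDesign) -> GeneAnnotation:
    """Non-overlapping gene bodies on two synthetic chromosomes.

    Genes occupy 4 kb bodies in 16 kb slots (ample spacing keeps promoter
    windows disjoint and nearest-gene assignment unambiguous); strand is
    random; TSS is body start (+) or end-1 (-).
    """
    rng = np.random.default_rng(design.seed + _STREAM_ANNOTATION)
    ids = gene_ids(design)
    slot, body = 16_000, 4_000
    n_chr1 = (len(ids) + 1) // 2
    rows = []
    chrom_lengths = {}
    for chrom, chunk in (("chr1", ids[:n_chr1]), ("chr2", ids[n_chr1:])):
        for i, gene in enumerate(chunk):
            offset = int(rng.integers(0, slot - body - 2_500))
            start = i * slot + 2_500 + offset  # margin keeps promoter windows >= 0
            end = start + body
            strand = "+" if rng.random() < 0.5 else "-"
            tss = start if strand == "+" else end - 1
            rows.append((gene, chrom, strand, start, end, tss))
        chrom_lengths[chrom] = len(chunk) * slot + 20_000
    table = pd.DataFrame(rows, columns=["gene_id", "chrom", "strand", "start", "end", "tss"])
    return GeneAnnotation(table, chrom_lengths)


def generate_cohort(design: SimulationDesign) -> SyntheticCohort:
    """Expression, copy-number, counts, gene sets and the truth record."""
    labels = sample_groups(design)
    samples = list(labels.index)
    genes = gene_ids(design)
    target, ifn, low, _, _ = _designated_genes(design)

    rng_expr = np.random.default_rng(design.seed + _STREAM_EXPRESSION)
    baseline = np.maximum(
        rng_expr.normal(design.baseline_mean, design.baseline_sd, size=len(genes)),
        design.baseline_floor,
    )
    gene_pos = {g: i for i, g in enumerate(genes)}
    low_idx = np.array([gene_pos[g] for g in low], dtype=int)
    if low_idx.size:
        baseline[low_idx] = rng_expr.uniform(*design.low_baseline_range, size=low_idx.size)

    loc = np.array([design.cancer_types[t][0] for t in labels["cancer_type"]])
    scale = np.array([design.cancer_types[t][1] for t in labels["cancer_type"]])
    amplified = (labels["group"] == "amplified").to_numpy()

    shift = np.zeros((len(genes), len(samples)))
    target_idx = np.array([gene_pos[g] for g in target], dtype=int)
    ifn_idx = np.array([gene_pos[g] for g in ifn], dtype=int)
    shift[np.ix_(target_idx, np.flatnonzero(amplified))] = design.target_set_effect * design.noise_sd
    shift[np.ix_(ifn_idx, np.flatnonzero(amplified))] = design.ifn_set_effect * design.noise_sd
    shift[gene_pos[design.oncogene], amplified] = design.target_set_effect * design.noise_sd

    noise = rng_expr.normal(0.0, 1.0, size=shift.shape) * (design.noise_sd * scale)[None, :]
    values = baseline[:, None] + loc[None, :] + shift + noise
    expression = ExpressionMatrix(
        pd.DataFrame(values, index=pd.Index(genes, name="gene_id"), columns=samples),
        labels[["cancer_type"]].copy(),
    )

    rng_cn = np.random.default_rng(design.seed + _STREAM_COPY_NUMBER)
    n = len(samples)
    onc = np.empty(n)
    for mask, rng_range in (
        (labels["group"] == "amplified", AMPLIFIED_CN_RANGE),
        (labels["group"] == "neutral", NEUTRAL_CN_RANGE),
        (labels["group"] == "excluded", EXCLUDED_CN_RANGE),
    ):
        idx = np.flatnonzero(mask.to_numpy())
        onc[idx] = rng_cn.uniform(*rng_range, size=idx.size)
    bystanders = [g for g in genes[1:4]]
    cn = pd.DataFrame({design.oncogene: onc}, index=pd.Index(samples, name="sample_id"))
    for g in bystanders:
        cn[g] = rng_cn.uniform(*NEUTRAL_CN_RANGE, size=n)

    rng_counts = np.random.default_rng(design.seed + _STREAM_COUNTS)
    mu = design.count_depth_factor * baseline[:, None] * np.ones((1, n))
    fold = np.ones_like(mu)
    fold[np.ix_(target_idx, np.flatnonzero(amplified))] = 2.0**design.target_set_effect
    fold[np.ix_(ifn_idx, np.flatnonzero(amplified))] = 2.0**design.ifn_set_effect
    mu = mu * fold
    shape = 1.0 / design.nb_dispersion
    counts_arr = rng_counts.negative_binomial(shape, shape / (shape + mu))
    counts = pd.DataFrame(
        counts_arr.astype(np.int64), index=pd.Index(genes, name="gene_id"), columns=samples
    )

    truth = CohortTruth(
        groups=labels["group"].copy(),
        cancer_type=labels["cancer_type"].copy(),
        target_set=target,
        ifn_set=ifn,
        low_expression_genes=low,
        oncogene=design.oncogene,
    )
    return SyntheticCohort(expression, cn, counts, generate_gene_sets(design), truth)


def generate_peaks(
    targets,
    annotation: GeneAnnotation,
    n_samples: int,
    fpr: float,
    seed: int,
    peak_width: int = 300,
    jitter: int = 150,
) -> list[pd.DataFrame]:
    """Replicate peak sets: one promoter peak per target plus background.

    Each replicate carries one peak centered on every target TSS with
    coordinate jitter (always inside the promoter window), plus
    round(fpr * n_genes) background peaks at random non-promoter grid
    positions. Background grids use a replicate-specific phase offset, so
    background peaks from different replicates can never overlap and are
    removed by any recurrence filter with support >= 2.
    """
    targets = list(targets)
    ann = annotation.table.set_index("gene_id")
    missing = [g for g in targets if g not in ann.index]
    if missing:
        raise ValueError(f"target gene(s) absent from annotation: {missing[:10]}")
    n_background = int(round(fpr * len(annotation.table)))
    spacing = max(2_000, (peak_width + 50) * max(n_samples, 1))
    from .peaks import promoter_windows

    windows = promoter_windows(annotation)
    replicates = []
    for rep in range(n_samples):
        rng = np.random.default_rng([seed, _STREAM_PEAKS, rep])
        rows = []
        for gene in targets:
            tss = int(ann.at[gene, "tss"])
            center = tss + int(rng.integers(-jitter, jitter + 1))
            start = max(center - peak_width // 2, 0)
            rows.append((str(ann.at[gene, "chrom"]), start, start + peak_width))
        if n_background:
            phase = rep * (peak_width + 50)
            candidates = []
            for chrom, length in sorted(annotation.chrom_lengths.items()):
                win = windows[windows["chrom"] == chrom]
                starts = np.arange(phase, length - peak_width, spacing, dtype=np.int64)
                ends = starts + peak_width
                keep = np.ones(len(starts), dtype=bool)
                for w_start, w_end in win[["start", "end"]].itertuples(index=False):
                    keep &= ~((starts < w_end) & (w_start < ends))
                candidates.extend((chrom, int(s)) for s in starts[keep])
            chosen = rng.choice(len(candidates), size=min(n_background, len(candidates)), replace=False)
            for i in sorted(chosen):
                chrom, start = candidates[i]
                rows.append((chrom, start, start + peak_width))
        replicates.append(
            as_peak_frame(pd.DataFrame(rows, columns=["chrom", "start", "end"]))
        )
    return replicates


def generate_fractions(
    design: SimulationDesign, shifted_cell_type: str, effect: float
) -> pd.DataFrame:
    """Dirichlet immune-fraction matrix with a group effect on one cell type.

    The amplified group's Dirichlet concentration for ``shifted_cell_type``
    is scaled by exp(effect); rows sum to 1 exactly up to float rounding.
    """
    if shifted_cell_type not in design.cell_types:
        raise ValueError(f"{shifted_cell_type!r} not among declared cell types")
    labels = sample_groups(design)
    rng = np.random.default_rng(design.seed + _STREAM_FRACTIONS)
    alpha = design.alpha()
    alpha_amp = alpha.copy()
    alpha_amp[list(design.cell_types).index(shifted_cell_type)] *= np.exp(effect)
    amplified = (labels["group"] == "amplified").to_numpy()
    out = np.empty((len(labels), len(design.cell_types)))
    # draw in sample order so the matrix is invariant to group sizes
    for i, is_amp in enumerate(amplified):
        out[i] = rng.dirichlet(alpha_amp if is_amp else alpha)
    return pd.DataFrame(
        out, index=labels.index.copy(), columns=list(design.cell_types)
    )
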