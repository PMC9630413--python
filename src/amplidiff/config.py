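"""Pipeline configuration.

All analysis constants live here with the defaults the pipeline was designed
around: the copy-number amplification threshold (log2 ratio 0.3) with a
symmetric neutral band, the low-expression filter at 20 expression units on
the robust (Hodges-Lehmann) average, gene-set size windows for the two
enrichment procedures (10-500 for the competitive Welch set test, 15-3000 for
preranked GSEA), the DEG thresholds (BH FDR < 0.05 and linear |fold change| >
1.5), the over-representation FDR cutoff (0.1), and the strand-aware promoter
window around the TSS.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    amp_threshold: float = 0.3
    neutral_band: float = 0.3
    expr_filter_threshold: float = 20.0
    welch_set_min: int = 10
    welch_set_max: int = 500
    gsea_min: int = 15
    gsea_max: int = 3000
    deg_fdr: float = 0.05
    deg_fc: float = 1.5
    fisher_fdr: float = 0.1
    promoter_upstream: int = 2000
    promoter_downstream: int = 500
    n_permutations: int = 1000
    rng_seed: int = 0
    scale_method: str = "hall"  # robust scale: "hall" (difference-based) or "mad"
    min_overlap: int = 1  # bp of overlap required to fuse/cluster peaks

    def __post_init__(self) -> None:
        positive = (
            "amp_threshold",
            "neutral_band",
            "expr_filter_threshold",
            "welch_set_min",
            "welch_set_max",
            "gsea_min",
            "gsea_max",
            "deg_fdr",
            "deg_fc",
            "fisher_fdr",
            "promoter_upstream",
            "promoter_downstream",
            "n_permutations",
            "min_overlap",
        )
        for name in positive:
            if not getattr(self, name) > 0:
                raise ValueError(f"config field {name!r} must be strictly positive")
        if self.neutral_band > self.amp_threshold:
            raise ValueError("neutral_band must not exceed amp_threshold")
        if not self.welch_set_min < self.welch_set_max:
            raise ValueError("welch_set_min must be < welch_set_max")
        if not self.gsea_min < self.gsea_max:
            raise ValueError("gsea_min must be < gsea_max")
        if self.scale_method not in ("hall", "mad"):
            raise ValueError("scale_method must be 'hall' or 'mad'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        """Load a flat key: value YAML document; unknown keys are rejected."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"{path}: config must be a flat key-value mapping")
        known = {f.name for f in fields(cls)}
        unknown = sorted(set(raw) - known)
        if unknown:
            raise ValueError(f"{path}: unknown config keys {unknown}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)
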