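import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # makes `import oracles` robust

from amplidiff import ExpressionMatrix, SimulationDesign, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(20250925)


def make_expression(values, sample_types=None, genes=None, samples=None) -> ExpressionMatrix:
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    sample_types = sample_types or ["typeA"] * len(samples)
    meta = pd.DataFrame({"cancer_type": sample_types}, index=pd.Index(samples, name="sample_id"))
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples), meta)


@pytest.fixture
def small_cohort():
    """Small seeded cohort with real effects, shared across module tests."""
    design = SimulationDesign(
        n_genes=600,
        n_samples=60,
        target_set_size=30,
        ifn_set_size=30,
        n_decoy_sets=10,
        excluded_fraction=0.05,
        seed=11,
    )
    return design, generate_cohort(design)
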