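import numpy as np
import pandas as pd
import pytest

from hypercoex import ExpressionMatrix, SyntheticConfig, generate_longitudinal


def make_expression(values, gene_ids=None, ages=None, condition="SC"):
    """Build a small ExpressionMatrix from a 2-D array."""
    values = np.asarray(values, dtype=float)
    n_genes, n_samples = values.shape
    gene_ids = gene_ids or [f"g{i}" for i in range(n_genes)]
    ages = ages if ages is not None else [5] * n_samples
    samples = [f"s{i}" for i in range(n_samples)]
    meta = pd.DataFrame(
        {
            "age_dpf": ages,
            "condition": [condition] * n_samples,
            "replicate": list(range(1, n_samples + 1)),
        },
        index=samples,
    )
    return ExpressionMatrix(pd.DataFrame(values, index=gene_ids, columns=samples), meta)


@pytest.fixture(scope="session")
def synth_default():
    """The default study design: 2000 genes, ages 5-30 dpf, 3 reps, seed 0."""
    return generate_longitudinal(SyntheticConfig(seed=0))


@pytest.fixture(scope="session")
def synth_small():
    """A scaled-down design for fast module tests."""
    cfg = SyntheticConfig(
        n_genes=400, genes_per_cluster=10, n_background_linked=25, seed=3
    )
    return generate_longitudinal(cfg)


@pytest.fixture
def tiny_expr():
    """4 genes x 6 samples over 3 ages, hand-set values."""
    rng = np.random.default_rng(42)
    vals = rng.normal(8, 1, (4, 6))
    return make_expression(vals, ages=[5, 5, 10, 10, 15, 15])
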