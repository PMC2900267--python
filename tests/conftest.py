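import numpy as np
import pytest

from chronomics import ExpressionMatrix, normalize_gene_wise, simulate_expression
from chronomics.simulate import ProfileSpec, default_profile_specs


@pytest.fixture
def toy_em() -> ExpressionMatrix:
    """3 genes x 4 arrays, two groups of two."""
    values = np.array([[1.0, 2.0, 3.0, 4.0],
                       [5.0, 5.0, 5.0, 5.0],
                       [2.0, 1.0, 4.0, 3.0]])
    return ExpressionMatrix(
        ["g1", "g2", "g3"], ["a1", "a2", "b1", "b2"], values,
        {"a1": "day0", "a2": "day0", "b1": "day2", "b2": "day2"})


@pytest.fixture
def five_group_em() -> ExpressionMatrix:
    """Deterministic 8-gene matrix over the 4/6/5/8/8 five-group design."""
    rng = np.random.default_rng(42)
    specs = [ProfileSpec(1, (1, 0.5, 0, -0.5, -1), 4, amplitude=2.0, noise_sd=0.4)]
    em, _ = simulate_expression(specs, 4, seed=rng.integers(2**31))
    return em


@pytest.fixture
def planted_norm():
    """Normalized matrix with 4 well-separated planted clusters of 15 genes."""
    specs = default_profile_specs(15, amplitude=2.0, noise_sd=0.4, n_clusters=4)
    em, truth = simulate_expression(specs, 0, seed=7)
    return normalize_gene_wise(em), truth
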