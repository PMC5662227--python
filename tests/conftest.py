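import pytest

from stemoran import ModelParameters


@pytest.fixture
def crypt_plasticity_params() -> ModelParameters:
    """P53 colorectal-crypt scenario: slightly deleterious mutant (r = 0.96)
    with reduced differentiation (u2 = 0.25) and inflammation-induced
    dedifferentiation (eta2 = 0.12)."""
    return ModelParameters(
        n_stem=10, n_diff=10, r1=1.0, r2=0.96, rt1=1.0, rt2=0.96,
        u1=0.5, u2=0.25, eta1=0.0, eta2=0.12,
    )


@pytest.fixture
def hierarchical_params() -> ModelParameters:
    """Zero-plasticity hierarchy with a mildly advantaged mutant."""
    return ModelParameters(
        n_stem=10, n_diff=10, r2=1.1, rt2=1.1, u1=0.5, u2=0.5,
    )


@pytest.fixture
def tiny_symmetric_params() -> ModelParameters:
    """Fully symmetric two-cell system solvable by hand."""
    return ModelParameters(
        n_stem=1, n_diff=1, u1=0.5, u2=0.5, eta1=0.5, eta2=0.5,
    )
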