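import numpy as np
import pytest

from fourierreg import FourierSpec, assemble_design, fit_ols, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def full_rank_model():
    """A single-predictor (full-rank) design with a noisy response, fitted."""
    spec = FourierSpec(T=(3,))
    delta = np.array([0.7, 0.4, 1.2, -0.8, 0.5])
    ds = generate_dataset(30, spec, delta, sigma2=0.5, seed=11)
    design = assemble_design(ds.predictors, spec)
    return fit_ols(design, ds.y), ds


@pytest.fixture
def rank_deficient_model():
    """A two-predictor design (collinear half-columns), fitted."""
    spec = FourierSpec(T=(2, 2))
    delta = np.array([0.35, 0.3, 1.2, -0.7, 0.35, -0.2, 0.9, 0.4])
    ds = generate_dataset(40, spec, delta, sigma2=0.8, seed=5)
    design = assemble_design(ds.predictors, spec)
    return fit_ols(design, ds.y), ds
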