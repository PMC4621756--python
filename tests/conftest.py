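import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from glycodrug._seeds import derive_seed
from glycodrug.normalization import filter_low_counts, log_transform
from glycodrug.synthetic import generate_drug_response, generate_spectral_counts

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def count_matrix_22x185():
    """Default-size spectral-count panel (22 cell lines, 185 proteins)."""
    return generate_spectral_counts(22, 185, 7, seed=11)


@pytest.fixture(scope="session")
def expression_22(count_matrix_22x185):
    """Analysis-ready log-expression matrix after the count filter."""
    return log_transform(filter_low_counts(count_matrix_22x185, 100))


@pytest.fixture(scope="session")
def sparse_response(expression_22):
    """One drug response with 3 true predictors at a 0.85 signal fraction."""
    y, truth = generate_drug_response(
        expression_22, k_true=3, noise_sd=0.42, seed=derive_seed(11, "drug"), target_r2=0.85
    )
    return y, truth


@pytest.fixture(scope="session")
def gaussian_regression():
    """Small dense regression problem with known sparse coefficients."""
    rng = np.random.default_rng(7)
    X = rng.normal(size=(30, 12))
    beta = np.zeros(12)
    beta[[1, 4, 9]] = [1.5, -2.0, 1.0]
    y = 3.0 + X @ beta + rng.normal(0, 0.5, 30)
    Xdf = pd.DataFrame(X, columns=[f"f{j:02d}" for j in range(12)])
    return Xdf, pd.Series(y), beta
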