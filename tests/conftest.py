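import numpy as np
import pandas as pd
import pytest

from neurokd.containers import ExpressionMatrix
from neurokd.synthetic import CohortConfig, simulate_bulk_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One medium synthetic cohort shared by recovery tests."""
    cfg = CohortConfig(n_subjects=400, n_cases=200, n_genes=200, n_variants=120, seed=42)
    bulk, genotypes, covariates, truth = simulate_bulk_cohort(cfg)
    return cfg, bulk, genotypes, covariates, truth


@pytest.fixture(scope="session")
def neuron_residual(default_cohort):
    from neurokd.deconvolution import compute_celltype_residual

    cfg, bulk, genotypes, covariates, truth = default_cohort
    names = [n for n, _, _ in cfg.covariate_spec]
    return compute_celltype_residual(bulk, names, truth.marker_genes, "neuron")


@pytest.fixture
def counts_matrix():
    rng = np.random.default_rng(7)
    values = pd.DataFrame(
        rng.poisson(40, size=(30, 12)).astype(float),
        index=[f"g{i}" for i in range(30)],
        columns=[f"s{j}" for j in range(12)],
    )
    return ExpressionMatrix(values, unit="counts")
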