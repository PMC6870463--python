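import warnings

import numpy as np
import pandas as pd
import pytest

from sibxpress import ExpressionMatrix, SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One full simulated study at the default design (15 families)."""
    return simulate_cohort(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def zero_noise_cohort():
    return simulate_cohort(SimulationConfig(seed=1, noise_sd_log2=0.0))


@pytest.fixture
def tiny_config():
    """A minimal, fast design for structural tests."""
    return SimulationConfig(
        seed=11, n_founders_per_breed=4, n_f1_pairs=2, n_f2_per_family=3,
        n_autosomal_genes=20, n_z_genes=4, n_w_genes=2,
        trans_module_size=3, mesenchyme_module_size=2,
        n_lps_induced=3, n_lps_repressed=2,
    )


def make_expression(values: np.ndarray, treatments=None, sexes=None,
                    families=None, chroms=None, individuals=None) -> ExpressionMatrix:
    """Hand-built ExpressionMatrix with minimal metadata."""
    n_genes, n_samples = values.shape
    samples = [f"s{i}" for i in range(n_samples)]
    genes = [f"g{i}" for i in range(n_genes)]
    smeta = pd.DataFrame(
        {
            "individual": individuals or [f"bird{i}" for i in range(n_samples)],
            "sex": sexes or ["M"] * n_samples,
            "family": families or ["FAM_A"] * n_samples,
            "generation": 2,
            "treatment": treatments or ["control"] * n_samples,
        },
        index=pd.Index(samples, name="sample"),
    )
    gmeta = pd.DataFrame(
        {"chromosome": chroms or ["chr1"] * n_genes},
        index=pd.Index(genes, name="gene"),
    )
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples),
                            smeta, gmeta)


@pytest.fixture
def expr_factory():
    return make_expression
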