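import numpy as np
import pandas as pd
import pytest

from latentmr.simulate import SimulationConfig, simulate_cohort, simulate_two_cohorts


@pytest.fixture(scope="session")
def strong_config():
    """Small cohort with strong instruments so single fits are informative."""
    return SimulationConfig(n_individuals=8000, theta2_true=0.05,
                            n_mediator_snps=20, seed=11)


@pytest.fixture(scope="session")
def strong_cohort(strong_config):
    return simulate_cohort(strong_config)


@pytest.fixture(scope="session")
def cohort_pair(strong_config):
    return simulate_two_cohorts(strong_config)


def make_instruments(alpha, b, se_alpha=0.01, se_b=0.05, eaf=0.3,
                     snp_ids=None) -> pd.DataFrame:
    """Hand-built harmonised instrument table."""
    alpha = np.asarray(alpha, float)
    b = np.asarray(b, float)
    m = alpha.size
    se_alpha = np.broadcast_to(np.asarray(se_alpha, float), (m,))
    se_b = np.broadcast_to(np.asarray(se_b, float), (m,))
    eaf = np.broadcast_to(np.asarray(eaf, float), (m,))
    return pd.DataFrame(
        {
            "snp": snp_ids or [f"rs{i}" for i in range(m)],
            "effect_allele": "A",
            "other_allele": "C",
            "eaf": eaf,
            "alpha_hat": alpha,
            "se_alpha": se_alpha,
            "pval_exposure": 1e-9,
            "b": b,
            "se_b": se_b,
            "pval_outcome": 0.5,
            "sigma2_Z": 2 * eaf * (1 - eaf),
            "n_exposure": 50000,
            "n_outcome": 50000,
        }
    )
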