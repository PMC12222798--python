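import numpy as np
import pandas as pd
import pytest

from tmecrosstalk.communication import default_erbb_pairs
from tmecrosstalk.mutualism import invitro_params
from tmecrosstalk.synthetic import CohortConfig, generate_count_cohort


@pytest.fixture(scope="session")
def erbb_pairs() -> pd.DataFrame:
    return default_erbb_pairs()


@pytest.fixture(scope="session")
def invitro():
    return invitro_params()


@pytest.fixture(scope="session")
def small_cohort(erbb_pairs):
    """Small count cohort with a 3-fold post-treatment NRG1 shift in fibroblasts."""
    cfg = CohortConfig(n_patients=4, n_cells_per_sample=150, n_genes=80,
                       n_pathways=5, seed=7)
    return generate_count_cohort(
        cfg, lr_pairs=erbb_pairs,
        shift_spec=[{"cell_type": "fibroblast", "gene": "NRG1", "fold": 3.0}],
    )


def dense_hier_loglik(y, patient, t, beta0, beta_t, omega, sigma_e2):
    """Independent dense multivariate-normal evaluation of the hierarchical model."""
    from scipy.stats import multivariate_normal

    y = np.asarray(y, float)
    patient = np.asarray(patient)
    t = np.asarray(t, float)
    ll = 0.0
    for p in np.unique(patient):
        m = patient == p
        Z = np.column_stack([np.ones(m.sum()), t[m]])
        V = sigma_e2 * np.eye(int(m.sum())) + Z @ omega @ Z.T
        ll += multivariate_normal.logpdf(y[m], beta0 + beta_t * t[m], V, allow_singular=True)
    return float(ll)
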