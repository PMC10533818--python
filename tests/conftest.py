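import numpy as np
import pandas as pd
import pytest

from widqt.synthetic_data import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Desk-scale cohort with a strong planted case effect for quick checks."""
    cfg = CohortConfig(n_train=200, n_internal=100, n_validation=100,
                       n_snps=20, n_mqtl_cpgs=40, n_background_cpgs=160,
                       case_effect=0.3, n_case_cpgs=12, seed=7)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_split(small_cohort):
    ph = small_cohort.phenotypes
    return {
        "train": ph.index[ph["set"] == "discovery-train"],
        "internal": ph.index[ph["set"] == "discovery-internal-validation"],
        "validation": ph.index[ph["set"] == "validation"],
        "discovery": ph.index[ph["set"] != "validation"],
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
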