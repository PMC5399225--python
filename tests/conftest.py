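import numpy as np
import pytest

import batkit as bk


@pytest.fixture(scope="session")
def small_cohort():
    """A small two-set cohort with a strong planted effect, shared across tests."""
    cfg = bk.CohortConfig(n_participants=8, n_sets=2, seed=7, effect_size=0.6)
    sessions, traits, gt = bk.generate_cohort(cfg)
    return cfg, sessions, traits, gt


@pytest.fixture(scope="session")
def small_table(small_cohort):
    _, sessions, _, _ = small_cohort
    return bk.extract_cohort_features(sessions)


@pytest.fixture(scope="session")
def recovery_runs():
    """Twenty independent n=200 cohorts at planted effect 0.5, run end to end.

    For each seed returns (r_trait_vs_mean_hf_power, r_index_vs_trait),
    both computed through the real extraction + composite pipeline on the
    attachment-deactivating themes.
    """
    from batkit.validation import index_recovery_experiment
    return index_recovery_experiment(seeds=range(20), n=200, effect_size=0.5)
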