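import numpy as np
import pytest

import cytoaging as ca


@pytest.fixture(scope="session")
def small_cohort():
    """Modest study-like cohort shared by read-only tests."""
    cfg = ca.CohortConfig(
        n_per_group={"CTR": 120, "REL": 100, "RSK": 10, "T1D": 90},
        n_features_per_cluster=(6, 3, 6, 3),
        seed=7,
    )
    return ca.generate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
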