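import numpy as np
import pytest

from scnpipe.synthgen import AtlasSpec, CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def small_atlas():
    return AtlasSpec.create(d=12, voxel_range=(20, 40), seed=7)


@pytest.fixture(scope="session")
def small_cohort(small_atlas):
    cfg = CohortConfig(n_controls=20, n_patients=15, mean_effect=1.0,
                       affected_parcels=[0, 1, 2], seed=11)
    return generate_cohort(small_atlas, cfg)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260922)
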