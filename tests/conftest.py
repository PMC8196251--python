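import numpy as np
import pandas as pd
import pytest

from svdstrat.synthetic import CohortSpec, ImageEffectSpec, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def small_cohort() -> pd.DataFrame:
    return generate_cohort(CohortSpec(seed=11).with_sizes(15))


@pytest.fixture(scope="session")
def small_effect_spec() -> ImageEffectSpec:
    return ImageEffectSpec(
        grid_shape=(16, 16, 16),
        blobs=(((5, 6, 8), 3.0, 1), ((10, 10, 6), 3.0, 4)),
        effect_sizes={"type3": (-2.0, 0.0)},
        noise_sd=1.0,
    )
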