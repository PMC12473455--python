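import numpy as np
import pytest

from leadii.denoise import NLMParams
from leadii.features import assemble_feature_table
from leadii.io import get_scheme
from leadii.simulate import NoiseSpec, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """16 synthetic records over the four rhythm groups, light noise."""
    noise = NoiseSpec(wander_amplitude=0.05, powerline_amplitude=0.02,
                      broadband_sd=0.02)
    return generate_cohort(4, ("AFIB", "SB", "SR", "ST"), seed=7, noise=noise)


@pytest.fixture(scope="session")
def small_table(small_cohort):
    """Feature table of the small cohort, denoised with a narrowed NLM search
    to keep the suite quick."""
    records, diags = small_cohort
    return assemble_feature_table(
        records, diags, get_scheme("four"),
        nlm_params=NLMParams(search_half_width=150),
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
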