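import numpy as np
import pytest

import tofcrop as tc
from tofcrop.pipeline import run_campaign_analysis


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def campaign_bundle():
    """Default synthetic campaign plus the full workflow analysis.

    Session-scoped: the render + analysis is the expensive part of the
    suite and every end-to-end test shares it.
    """
    field = tc.generate_field(seed=0)
    campaign = tc.default_campaign(field, seed=0)
    analysis = run_campaign_analysis(campaign)
    return field, campaign, analysis
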