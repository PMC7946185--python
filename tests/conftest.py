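import numpy as np
import pytest

from glvmap.dynamics import fast_settings
from glvmap.params import CommunityParameters
from glvmap.sampler import SamplerSettings, sample_climax_community
from glvmap.synth import fixture_community


@pytest.fixture(scope="session")
def fast():
    """Loosened integration tolerances shared by the heavier tests."""
    return fast_settings()


@pytest.fixture(scope="session")
def archetypes():
    return {
        name: fixture_community(name)
        for name in (
            "independent",
            "obligate_pair",
            "commensal_chain",
            "competitive_exclusion",
            "mutualist_triangle",
            "humpty_dumpty",
        )
    }


def random_community(seed: int, S: int = 3, sigma: float = 0.05, P_m: float = 0.5,
                     settings=None) -> CommunityParameters:
    """A sampled viable community at the interaction scale where dynamics are
    nontrivial (s = 0.1, r spanning negative values)."""
    ss = SamplerSettings(
        S=S, sigma=sigma, P_m=P_m, seed=seed, s_value=0.1, r_range=(-1.0, 1.0),
        **({"integration": settings} if settings else {}),
    )
    params, _ = sample_climax_community(ss)
    return params


@pytest.fixture(scope="session")
def random_3species(fast):
    return [random_community(100 + 17 * k, settings=fast) for k in range(6)]
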