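import numpy as np
import pytest

from aacscore import phantom
from aacscore.kauppila import SegmentKey


@pytest.fixture(scope="session")
def default_spec():
    return phantom.PhantomSpec()


@pytest.fixture(scope="session")
def sample_with_calc():
    """One phantom with known fractions: 0.5 anterior L1, 0.9 posterior L3."""
    spec = phantom.PhantomSpec(
        calcified_fractions={
            SegmentKey("L1", "anterior"): 0.5,
            SegmentKey("L3", "posterior"): 0.9,
        }
    )
    return phantom.make_phantom(spec, seed=5)


@pytest.fixture(scope="session")
def small_cohort():
    return phantom.sample_cohort(phantom.CohortSpec(n_cases=20, seed=42))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
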