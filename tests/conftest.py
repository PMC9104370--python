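import numpy as np
import pytest

from metasub import demo_spec, generate_cohort


@pytest.fixture(scope="session")
def demo_cohort():
    """One small synthetic cohort with planted two-subtype structure in
    PATHWAY_A and one planted effect per variable class."""
    spec = demo_spec(seed=7)
    return spec, generate_cohort(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
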