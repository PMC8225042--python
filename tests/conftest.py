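import numpy as np
import pytest

from msentropy import SignalSpec, generate


@pytest.fixture(scope="session")
def gaussian_20k():
    """One long unit Gaussian series shared by the statistical tests."""
    return generate(SignalSpec(kind="gaussian", n=20_000, seed=101))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260919)
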