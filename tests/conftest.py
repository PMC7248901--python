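import numpy as np
import pytest

from csrecon import Signal1D, build_basis


@pytest.fixture(scope="session")
def dft128():
    return build_basis("dft", 128)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def ecg_like():
    """A crude periodic beat train used by IO/analyzer plumbing tests."""
    n = 256
    t = np.arange(n)
    beat = np.exp(-((t % 64 - 32) ** 2) / 18.0)
    return Signal1D(beat + 0.1 * np.sin(2 * np.pi * t / 128.0))
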