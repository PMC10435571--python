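import numpy as np
import pytest

from bgregulome import SimulationManifest, build_pwm, default_pfm
from bgregulome.simulate import write_bundle


@pytest.fixture(scope="session")
def pfm():
    return default_pfm()


@pytest.fixture(scope="session")
def pwm(pfm):
    return build_pwm(pfm)


@pytest.fixture(scope="session")
def manifest():
    return SimulationManifest(seed=11)


@pytest.fixture(scope="session")
def bundle(manifest, tmp_path_factory):
    """The default synthetic input bundle, written once per session."""
    outdir = tmp_path_factory.mktemp("bundle")
    return write_bundle(manifest, outdir)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_pfm(rng, length):
    """A random count matrix with every column positive."""
    counts = rng.integers(1, 50, size=(length, 4)).astype(float)
    from bgregulome import PositionFrequencyMatrix

    return PositionFrequencyMatrix(identifier="RND", counts=counts)
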