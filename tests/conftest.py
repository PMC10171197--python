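import dataclasses

import numpy as np
import pytest

import ctvi


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def small_spec(**overrides):
    """A fast 48^3 phantom spec used across tests."""
    base = ctvi.PhantomSpec(
        shape=(48, 48, 48),
        lung_semiaxes_mm=(16.0, 24.0, 34.0),
        lung_gap_mm=8.0,
    )
    return dataclasses.replace(base, **overrides)


@pytest.fixture(scope="session")
def small_case():
    """One small phantom case shared by read-only tests."""
    return ctvi.make_phantom(small_spec())


@pytest.fixture
def block_volume():
    """Two homogeneous HU blocks (-900 | -500) split along x, mask = all."""
    data = np.full((12, 8, 8), -900.0)
    data[6:] = -500.0
    vol = ctvi.Volume(data, spacing=(2.0, 2.0, 2.0))
    mask = ctvi.BinaryMask(np.ones(data.shape), spacing=(2.0, 2.0, 2.0))
    return vol, mask
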