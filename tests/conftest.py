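import numpy as np
import pytest

from collmigr import VelocityField


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def field_from(u, v, valid=None, **kw) -> VelocityField:
    """Shorthand for building a field from component arrays."""
    return VelocityField.from_velocities(u, v, valid=valid, **kw)


def random_field(rng, ny=16, nx=16, **kw) -> VelocityField:
    return field_from(rng.normal(size=(ny, nx)), rng.normal(size=(ny, nx)), **kw)


@pytest.fixture
def uniform_field():
    def make(u0, v0, ny=8, nx=8, **kw):
        return field_from(np.full((ny, nx), float(u0)),
                          np.full((ny, nx), float(v0)), **kw)
    return make
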