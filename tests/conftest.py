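import numpy as np
import pytest

from conedose import (
    BeamModelSpec,
    ConeId,
    SlabPhantom,
    make_beam_model,
)
from conedose.synthetic import default_true_curves


@pytest.fixture(scope="session")
def beam_6xfff():
    return make_beam_model(BeamModelSpec(energy_label="6xFFF"))


@pytest.fixture(scope="session")
def beam_10xfff():
    return make_beam_model(BeamModelSpec(energy_label="10xFFF"))


@pytest.fixture(scope="session")
def true_curves():
    return default_true_curves()


@pytest.fixture()
def water_slab():
    """Validation slab stack: 4 x 50 mm water-equivalent, isocenter at 100 mm."""
    return SlabPhantom(slabs=[(50.0, 1.0)] * 4, surface_z_mm=100.0)


@pytest.fixture()
def cone75():
    return ConeId(7.5)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260922)
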