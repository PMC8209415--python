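import numpy as np
import pytest

from mrgridqa.detect import detect_slice
from mrgridqa.distortion import radial_model
from mrgridqa.phantom import build_lattice, build_phantom
from mrgridqa.protocols import protocol_preset
from mrgridqa.simulate import render_mr, render_reference


@pytest.fixture(scope="session")
def spec():
    return build_phantom()


@pytest.fixture(scope="session")
def lattice(spec):
    return build_lattice(spec)


@pytest.fixture(scope="session")
def proto750():
    return protocol_preset("ge_750")


@pytest.fixture(scope="session")
def ref750(spec, proto750):
    """Single noiseless reference slice at the 512-matrix preset."""
    return render_reference(spec, proto750, n_slices=1)


@pytest.fixture(scope="session")
def ref750_detected(ref750, spec, proto750, lattice):
    return detect_slice(ref750, 0, spec, proto750, lattice)


@pytest.fixture(scope="session")
def model3():
    """3 mm peak GNL field (largest magnitude among the scanner presets)."""
    return radial_model(3.0)


@pytest.fixture(scope="session")
def mr750_3mm(spec, proto750, model3):
    return render_mr(spec, proto750, model3, n_slices=1)


@pytest.fixture(scope="session")
def mr750_3mm_detected(mr750_3mm, spec, proto750, lattice):
    return detect_slice(mr750_3mm, 0, spec, proto750, lattice)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
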