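import numpy as np
import pytest

from cardiofuse import (
    PhantomSpec,
    make_angiography_phantom,
    make_cine_phantom,
    make_perfusion_phantom,
)
from cardiofuse.pipeline import phantom_roi


@pytest.fixture(scope="session")
def small_spec():
    """Compact phantom for fast registration tests."""
    return PhantomSpec(
        cine_size=(48, 48, 8),
        cine_spacing=(3.0, 3.0, 13.0),
        angio_size=(64, 64, 52),
        angio_spacing=(2.0, 2.0, 2.0),
        perf_size=(48, 48),
        perf_spacing=(3.0, 3.0),
        n_phases=8,
        n_frames=20,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_cine(small_spec):
    cine, truth = make_cine_phantom(small_spec)
    return cine, truth


@pytest.fixture(scope="session")
def small_angio(small_spec):
    return make_angiography_phantom(small_spec)


@pytest.fixture(scope="session")
def small_perfusion(small_spec):
    return make_perfusion_phantom(small_spec)


@pytest.fixture(scope="session")
def small_roi(small_spec, small_cine):
    cine, _ = small_cine
    return phantom_roi(small_spec, cine.grid.size[:2], cine.grid.spacing[:2])


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
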