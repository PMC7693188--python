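import numpy as np
import pytest

from parcelpvc import (
    PhantomSpec,
    default_activity_map,
    make_parcellation_phantom,
    simulate_pet,
)

SMALL_SPEC = PhantomSpec(
    grid_shape=(32, 32, 32),
    spacing_mm=(2.5, 2.5, 2.5),
    n_cortical_parcels=4,
    ribbon_thickness_mm=5.0,
    seed=0,
)


@pytest.fixture(scope="session")
def small_phantom():
    """32^3 four-sector phantom shared by the fast tests."""
    return make_parcellation_phantom(SMALL_SPEC)


@pytest.fixture(scope="session")
def medium_phantom():
    """48^3 six-sector phantom for PVC and registration tests."""
    return make_parcellation_phantom(
        PhantomSpec(n_cortical_parcels=6, seed=0)
    )


@pytest.fixture(scope="session")
def medium_pet(medium_phantom):
    """Noiseless PET blurred at 8 mm FWHM from the default activity map."""
    labels, parcels = medium_phantom
    truth = default_activity_map(parcels, seed=1)
    pet = simulate_pet(labels, truth, fwhm_mm=8.0, noise_sd=0.0)
    return pet, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
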