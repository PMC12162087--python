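import numpy as np
import pytest

from fstloc import prf, stimuli, synth


@pytest.fixture(scope="session")
def bar_apertures() -> stimuli.ApertureMovie:
    """Translating-bar protocol at a raster that keeps fits fast: 12.2 deg
    field, 61x61 raster, 8 positions x 4 directions x 3 TRs = 96 TRs."""
    return stimuli.gen_prf_apertures(
        "bar", radius=12.2, grid_size=61, n_steps=8, step_trs=3
    )


@pytest.fixture(scope="session")
def prf_fitter(bar_apertures) -> prf.PRFFitter:
    return prf.PRFFitter(bar_apertures)


@pytest.fixture(scope="session")
def hemisphere() -> synth.SyntheticHemisphere:
    return synth.make_hemisphere(seed=0)


@pytest.fixture(scope="session")
def hrf_kernel() -> np.ndarray:
    from fstloc import glm

    return glm.hrf(1.0)
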