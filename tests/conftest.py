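import numpy as np
import pytest

from nervemetry.phantom import PhantomSpec, dilate_roi, make_nerve_phantom


@pytest.fixture(scope="session")
def noise_free_phantom():
    """Default-geometry phantom with no noise: the exact signal-model world."""
    spec = PhantomSpec(snr=np.inf, mtr_nerve=33.0, seed=0)
    pair, truth = make_nerve_phantom(spec)
    return spec, pair, truth


@pytest.fixture(scope="session")
def noisy_tilted_phantom():
    """SNR-50 phantom tilted 20 degrees, with a generous rater-style ROI."""
    spec = PhantomSpec(snr=50.0, mtr_nerve=33.0, tilt_deg=20.0, seed=11)
    pair, truth = make_nerve_phantom(spec)
    return spec, pair, truth, dilate_roi(truth.roi)
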