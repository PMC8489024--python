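import numpy as np
import pytest

from pupilkit.model import Prediction
from pupilkit.synth import EyeAppearance, render_frame


class DarkPupilOracle:
    """Stand-in segmenter scoring pixels by darkness.

    On noise-free dark-pupil fixtures the pupil is the darkest region, so
    thresholding ``1 - image`` recovers it; this lets pipeline logic be
    tested quickly and independently of a trained network.
    """

    def __init__(self, cutoff: float = 0.2):
        self.cutoff = cutoff

    def predict(self, image: np.ndarray) -> Prediction:
        pmap = (np.asarray(image) < self.cutoff).astype(float)
        empty = pmap.sum() == 0
        return Prediction(pupil_map=pmap, eye_prob=1.0, blink_prob=1.0 if empty else 0.0)


@pytest.fixture
def oracle_model():
    return DarkPupilOracle()


@pytest.fixture
def clean_appearance():
    """Noise-free, unoccluded dark-pupil eye."""
    return EyeAppearance(
        pupil_center=(64.0, 60.0),
        pupil_semi_axes=(14.0, 10.0),
        pupil_angle=0.4,
        noise_sigma=0.0,
        specular_spot_count=0,
    )


@pytest.fixture
def clean_frame(clean_appearance):
    return render_frame(clean_appearance, seed=0)
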