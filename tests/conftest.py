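import warnings

import numpy as np
import pytest

from octaquant.simulate import AngiogramSpec, generate_angiogram

# morphology deprecation chatter from skimage 0.26 is irrelevant to the checks
warnings.filterwarnings("ignore", category=FutureWarning)


SMALL_FIELD_UM = 1700


def small_spec(**kw) -> AngiogramSpec:
    """A compact synthetic-eye spec for fast unit tests.

    The field still holds the full foveal disc and most of the parafoveal
    annulus; tree counts scale with the field area so densities stay in
    the physiological range.
    """
    defaults = dict(
        field_um=SMALL_FIELD_UM,
        faz_axes_um=(360.0, 300.0),
        n_trees={"SVC": 28, "DVC": 42},
    )
    defaults.update(kw)
    return AngiogramSpec(**defaults)


@pytest.fixture(scope="session")
def small_eye():
    """One small synthetic eye (both plexuses) with truth, shared per session."""
    return generate_angiogram(small_spec(), seed=11)


@pytest.fixture(scope="session")
def small_eye_processed(small_eye):
    from octaquant import process_eye

    images, truth = small_eye
    return process_eye(images["SVC"], images["DVC"]), truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
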