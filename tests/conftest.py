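import numpy as np
import pytest

from dotapet.phantom import PhantomSpec, Study, SliceStack, OrganMask, LesionLabelMap


@pytest.fixture
def small_spec():
    """Compact phantom used across tests: 48×48 grid, short studies."""
    return PhantomSpec(grid_shape=(48, 48), n_slices_range=(10, 14), seed=0)


@pytest.fixture
def noiseless_spec():
    return PhantomSpec(grid_shape=(64, 64), n_slices_range=(24, 28),
                       noise_sigma=0.0, seed=0)


@pytest.fixture
def hard_spec():
    """No blur, no noise: lesion pixels are exact steps."""
    return PhantomSpec(grid_shape=(64, 64), n_slices_range=(24, 28),
                       noise_sigma=0.0, blur_fwhm_mm=0.0, seed=0)


def make_study(labels, activity=None, study_id="00001", abnormal=None,
               pixel_mm=4.0):
    """Tiny in-memory study from a label array (tests' hand-built cases)."""
    labels = np.asarray(labels)
    if activity is None:
        activity = 100.0 + 100.0 * (labels > 0)
    liver = np.ones_like(labels, dtype=bool)
    if abnormal is None:
        abnormal = bool((labels > 0).any())
    return Study(study_id, SliceStack(np.asarray(activity, float), pixel_mm),
                 OrganMask(liver), LesionLabelMap(labels), abnormal)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
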