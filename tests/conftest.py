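import numpy as np
import pytest

from neurorads.image_core import LabelMask, VolumetricImage
from neurorads.synthetic import (
    PhantomSpec,
    TumorFocus,
    TumorSpec,
    make_head_phantom,
    make_synthetic_cohort,
    make_toy_atlas,
    make_tumor,
)


@pytest.fixture(scope="session")
def phantom():
    """Noise-free 48^3 head phantom at 1 mm with its exact brain mask."""
    return make_head_phantom(PhantomSpec(shape=(48, 48, 48), seed=11, noise_sd=0.0))


@pytest.fixture(scope="session")
def noisy_phantom():
    return make_head_phantom(PhantomSpec(shape=(48, 48, 48), seed=11, noise_sd=0.01))


@pytest.fixture(scope="session")
def tumor_case(phantom):
    """Unifocal ellipsoid tumor on the phantom: (mask, enhanced image, analytic ml)."""
    image, brain = phantom
    spec = TumorSpec(foci=(TumorFocus((20.0, 25.0, 23.0), (7.0, 6.0, 5.0)),))
    mask, enhanced, vols = make_tumor(spec, image, brain)
    return mask, enhanced, vols


@pytest.fixture(scope="session")
def toy_atlas(phantom):
    image, brain = phantom
    return make_toy_atlas(image, n_regions=4, brain=brain)


@pytest.fixture(scope="session")
def cohort(tmp_path_factory):
    """3-patient synthetic cohort written once per session."""
    out = tmp_path_factory.mktemp("cohort")
    manifest = make_synthetic_cohort(3, seed=202, out_dir=out, shape=(40, 40, 40))
    return out, manifest


def grid(shape=(16, 16, 16), spacing=(1.0, 1.0, 1.0)):
    return VolumetricImage(np.zeros(shape), spacing)


def binary_mask(labels, spacing=(1.0, 1.0, 1.0), kind="tumor"):
    labels = np.asarray(labels, dtype=np.int32)
    g = VolumetricImage(np.zeros(labels.shape), spacing)
    return LabelMask(labels, g, kind)
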