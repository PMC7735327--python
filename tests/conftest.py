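import numpy as np
import pytest

from faceatlas import PhantomParams, generate_phantom_subject, generate_population
from faceatlas.core import SegmentationMask


@pytest.fixture(scope="session")
def phantom_32():
    """One 32^3 subject (image, mask) at 1 mm isotropic."""
    return generate_phantom_subject(PhantomParams(grid_shape=(32, 32, 32), seed=42))


@pytest.fixture(scope="session")
def phantom_48():
    return generate_phantom_subject(PhantomParams(grid_shape=(48, 48, 48), seed=42))


@pytest.fixture(scope="session")
def small_bank():
    """Five 32^3 subjects with moderate shape variation."""
    return generate_population(
        5, PhantomParams(grid_shape=(32, 32, 32), subject_deformation_scale=2.0, seed=7)
    )


def random_mask(rng, shape=(16, 16, 16), p=0.3, spacing=(1.0, 1.0, 1.0)):
    """A random (usually disconnected) binary mask; guaranteed non-empty."""
    lab = (rng.random(shape) < p).astype(np.uint8)
    if lab.sum() == 0:
        lab[tuple(d // 2 for d in shape)] = 1
    return SegmentationMask(lab, spacing)


def random_blob_mask(rng, shape=(16, 16, 16), spacing=(1.0, 1.0, 1.0)):
    """A random connected blob: thresholded smoothed noise around the centre."""
    from scipy import ndimage

    field = ndimage.gaussian_filter(rng.standard_normal(shape), 2.0)
    idx = np.indices(shape)
    c = (np.array(shape) - 1) / 2
    bowl = sum(((idx[a] - c[a]) / (0.45 * shape[a])) ** 2 for a in range(3))
    lab = ((field - field.mean()) / (field.std() + 1e-12) + 1.0 - 2.0 * bowl > 0).astype(
        np.uint8
    )
    if lab.sum() == 0:
        lab[tuple(d // 2 for d in shape)] = 1
    return SegmentationMask(lab, spacing)
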