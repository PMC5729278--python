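import warnings

import numpy as np
import pytest

from foamquant.imaging_io import merge_channels
from foamquant.segmentation import SegmentationParams, filter_cells, segment_channel
from foamquant.synthetic import SyntheticSpec, generate_image

warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def default_params():
    return SegmentationParams()


@pytest.fixture(scope="session")
def mixed_fixture():
    """One synthetic image with mononucleate, binucleate and border cells."""
    spec = SyntheticSpec(n_cells=60, n_binucleate=3, n_border_touching=3, seed=7)
    img, truth = generate_image(spec)
    return spec, img, truth


@pytest.fixture(scope="session")
def segmented_mixed(mixed_fixture, default_params):
    """The mixed fixture pushed through the full segmentation chain."""
    _, img, truth = mixed_fixture
    merged = merge_channels(img)
    nuclei = segment_channel(img.blue, default_params.h_blue, default_params, "nuclei")
    candidates = segment_channel(
        merged, default_params.h_merged, default_params, "candidates"
    )
    counts: dict = {}
    cells = filter_cells(candidates, nuclei, default_params, counts)
    return img, truth, nuclei, candidates, cells, counts


def disk_image(radius=20, intensity=0.8, background=0.05, size=100, noise_sd=0.02, seed=0):
    """Bright disk on a dim background with mild Gaussian noise."""
    rng = np.random.default_rng(seed)
    img = np.full((size, size), background)
    yy, xx = np.mgrid[:size, :size]
    img[(yy - size // 2) ** 2 + (xx - size // 2) ** 2 <= radius**2] = intensity
    return np.clip(img + rng.normal(0, noise_sd, img.shape), 0, 1)
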