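import warnings

import numpy as np
import pytest

from angioquant.binarize import fuzzy_threshold
from angioquant.graph import build_graph, classify_elements, diameter_map, prune_twigs, skeletonize
from angioquant.imagery import Calibration, RasterImage
from angioquant.phantom import PhantomSpec, generate_phantom, square_calibration

warnings.filterwarnings("ignore", category=RuntimeWarning, module="angioquant.binarize")


@pytest.fixture
def cal64():
    return square_calibration(64, pitch_um=3.0)


def make_image(pixels, pitch_um=3.0):
    pixels = np.asarray(pixels, dtype=float)
    ny, nx = pixels.shape
    cal = Calibration(
        width_mm=pitch_um * nx / 1000.0,
        height_mm=pitch_um * ny / 1000.0,
        px_x=nx,
        px_y=ny,
    )
    return RasterImage(pixels=pixels, calibration=cal)


@pytest.fixture(scope="session")
def clean_phantom():
    """One noise-free default phantom shared by read-only tests."""
    spec = PhantomSpec(seed=11, speckle_variance=0.0, gaussian_sigma=0.0)
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def clean_pipeline_products(clean_phantom):
    """Segmentation, skeleton, diameters and unpruned graph of the clean phantom."""
    img, truth = clean_phantom
    bin_map = fuzzy_threshold(img)
    skel = skeletonize(bin_map)
    dmap = diameter_map(bin_map, skel)
    graph = classify_elements(build_graph(skel, dmap))
    return img, truth, bin_map, skel, dmap, graph
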