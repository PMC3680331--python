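import numpy as np
import pytest
from scipy import ndimage
from skimage import draw

from cardiofract import EdgeImage, ImageSlice


@pytest.fixture
def rng():
    return np.random.default_rng(20240817)


def euclidean_circle_edge(radius: int, frame: int | None = None) -> EdgeImage:
    """1-px boundary of the Euclidean disc of given radius."""
    n = frame or (2 * radius + 28)
    c = n // 2
    yy, xx = np.mgrid[0:n, 0:n]
    disc = (yy - c) ** 2 + (xx - c) ** 2 <= radius**2
    edge = disc & ~ndimage.binary_erosion(disc)
    return EdgeImage(edge.astype(np.uint8))


def midpoint_circle_edge(radius: int, frame: int | None = None) -> EdgeImage:
    """Midpoint-algorithm circle raster (skimage.draw.circle_perimeter)."""
    n = frame or (2 * radius + 28)
    c = n // 2
    img = np.zeros((n, n), dtype=np.uint8)
    rr, cc = draw.circle_perimeter(c, c, radius)
    img[rr, cc] = 1
    return EdgeImage(img)


def square_outline_edge(side: int = 10, frame: int = 20) -> EdgeImage:
    img = np.zeros((frame, frame), dtype=np.uint8)
    o = (frame - side) // 2
    img[o : o + side, o] = 1
    img[o : o + side, o + side - 1] = 1
    img[o, o : o + side] = 1
    img[o + side - 1, o : o + side] = 1
    return EdgeImage(img)


def bimodal_slice(rng, lo=50.0, hi=200.0, sd=10.0, shape=(64, 64)) -> ImageSlice:
    """Half-and-half Gaussian mixture image, integer intensities."""
    n = shape[0] * shape[1]
    vals = np.concatenate(
        [rng.normal(lo, sd, n // 2), rng.normal(hi, sd, n - n // 2)]
    )
    rng.shuffle(vals)
    vals = np.clip(np.round(vals), 0, 255).astype(int)
    return ImageSlice(vals.reshape(shape))
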