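"""Thresholding, binarization and Sobel border extraction."""

import numpy as np
import pytest
from scipy import ndimage
from skimage import filters, measure

from cardiofract import (
    BinaryMask,
    ImageSlice,
    RoiSpec,
    SegmentationError,
    binarize,
    extract_endocardial_border,
    isodata_threshold,
    make_smooth_annulus,
    make_trabeculated_slice,
    sobel_border,
)
from cardiofract.phantoms import PhantomSpec

from conftest import bimodal_slice


def intermeans_oracle(values: np.ndarray) -> float:
    """Independent brute-force intermeans iteration on the integer histogram."""
    hist = np.bincount(values.astype(int).ravel())
    levels = np.arange(hist.size)
    t = float((levels * hist).sum() / hist.sum())
    for _ in range(1000):
        lo = levels <= t
        m_lo = (levels[lo] * hist[lo]).sum() / hist[lo].sum()
        m_hi = (levels[~lo] * hist[~lo]).sum() / hist[~lo].sum()
        t_new = 0.5 * (m_lo + m_hi)
        if abs(t_new - t) < 0.5:
            return t_new
        t = t_new
    raise AssertionError("oracle did not converge")


class TestIsodataThreshold:
    def test_symmetric_bimodal_midpoint(self):
        img = ImageSlice(np.array([[0, 10], [10, 0]] * 2, dtype=int))
        assert isodata_threshold(img) == pytest.approx(5.0)

    def test_constant_roi_is_degenerate(self):
        img = ImageSlice(np.full((8, 8), 7, dtype=int))
        with pytest.raises(SegmentationError, match="degenerate"):
            isodata_threshold(img)

    def test_gaussian_mixture_matches_histogram_oracle(self, rng):
        img = bimodal_slice(rng)
        t = isodata_threshold(img)
        expected = intermeans_oracle(img.pixels)
        assert 50 < t < 200
        assert t == pytest.approx(expected, abs=1.0)

    def test_cross_check_against_skimage(self, rng):
        img = bimodal_slice(rng)
        t = isodata_threshold(img)
        t_ref = filters.threshold_isodata(img.pixels)
        # same algorithm family; agree within one intensity level
        assert t == pytest.approx(t_ref, abs=1.5)

    def test_roi_restricts_histogram(self, rng):
        px = np.zeros((32, 32), dtype=int)
        px[:16] = 100  # top half bright; bottom half 0
        px[20:, 20:] = 7
        img = ImageSlice(px)
        roi = RoiSpec(0, x0=0, y0=0, x1=32, y1=16)
        with pytest.raises(SegmentationError):
            isodata_threshold(img, roi)  # ROI constant at 100


class TestBinarize:
    def test_threshold_split(self):
        img = ImageSlice(np.array([[0, 10], [10, 0]], dtype=int))
        mask = binarize(img, 5.0)
        assert mask.pixels.tolist() == [[0, 1], [1, 0]]

    def test_matches_per_pixel_oracle(self, rng):
        px = rng.integers(0, 256, (40, 40))
        img = ImageSlice(px)
        t = 127.0
        mask = binarize(img, t)
        assert np.array_equal(mask.pixels, (px > t).astype(np.uint8))

    def test_outside_roi_is_background(self, rng):
        px = rng.integers(1, 256, (30, 30))
        img = ImageSlice(px)
        roi = RoiSpec(0, x0=5, y0=5, x1=25, y1=25)
        mask = binarize(img, 127.5, roi)
        assert mask.pixels[:5].sum() == 0 and mask.pixels[:, :5].sum() == 0
        assert mask.pixels[5:25, 5:25].sum() == (px[5:25, 5:25] > 127.5).sum()

    def test_threshold_outside_range_rejected(self):
        img = ImageSlice(np.array([[0, 10]], dtype=int))
        with pytest.raises(ValueError):
            binarize(img, 11.0)


class TestSobelBorder:
    def test_filled_square_outline_band(self):
        px = np.zeros((20, 20), dtype=np.uint8)
        px[5:15, 5:15] = 1
        edge = sobel_border(BinaryMask(px))
        # band = outline of the square plus the adjacent background ring
        inner = np.zeros_like(px)
        inner[6:14, 6:14] = 1
        assert edge.pixels[7:13, 7:13].sum() == 0  # deep interior clean
        assert edge.pixels[5:15, 5].all() and edge.pixels[5, 5:15].all()
        assert edge.n_edge_pixels > 0

    def test_single_pixel_impulse(self):
        px = np.zeros((9, 9), dtype=np.uint8)
        px[4, 4] = 1
        edge = sobel_border(BinaryMask(px))
        ys, xs = np.nonzero(edge.pixels)
        assert np.all(np.abs(ys - 4) <= 1) and np.all(np.abs(xs - 4) <= 1)

    def test_empty_mask_rejected(self):
        with pytest.raises(SegmentationError, match="no border"):
            sobel_border(BinaryMask(np.zeros((5, 5), dtype=np.uint8)))

    def test_disc_edge_count_vs_contour_oracle(self):
        n, r = 64, 20
        yy, xx = np.mgrid[0:n, 0:n]
        disc = ((yy - 32) ** 2 + (xx - 32) ** 2 <= r * r).astype(np.uint8)
        edge = sobel_border(BinaryMask(disc))
        # marching-squares oracle: one contour vertex per boundary cell
        # crossing; the Sobel band is two pixels wide, so expect ~2x as
        # many pixels as crossings
        contour = measure.find_contours(disc.astype(float), 0.5)[0]
        n_crossings = len(contour) - 1
        assert edge.n_edge_pixels == pytest.approx(2 * n_crossings, rel=0.15)

    def test_band_width_at_most_two_on_convex_mask(self):
        n = 64
        yy, xx = np.mgrid[0:n, 0:n]
        disc = ((yy - 32) ** 2 + (xx - 32) ** 2 <= 20**2).astype(np.uint8)
        edge = sobel_border(BinaryMask(disc))
        eight = np.ones((3, 3), bool)
        band = ndimage.binary_dilation(disc, eight) & ~ndimage.binary_erosion(
            disc, eight
        )
        assert np.all(band[edge.pixels == 1])


class TestFullChain:
    def test_annulus_yields_closed_ring(self):
        sl = make_smooth_annulus(PhantomSpec(seed=4))
        edge = extract_endocardial_border(sl.image)
        # a closed border encloses the lumen: filling it recovers the disc
        filled = ndimage.binary_fill_holes(edge.pixels)
        assert filled.sum() > sl.true_lumen_mask.pixels.sum() * 0.95

    def test_papillary_blobs_contribute_edges(self):
        spec = PhantomSpec(seed=9, n_papillary=2, roughness_amplitude=0.0,
                           border_model="sinusoidal_trabeculae")
        sl = make_trabeculated_slice(spec)
        edge = extract_endocardial_border(sl.image)
        _, n_components = ndimage.label(edge.pixels, structure=np.ones((3, 3)))
        assert n_components >= 3  # ring + two blob outlines

    def test_deterministic(self):
        sl = make_smooth_annulus(PhantomSpec(seed=2))
        e1 = extract_endocardial_border(sl.image)
        e2 = extract_endocardial_border(sl.image)
        assert np.array_equal(e1.pixels, e2.pixels)

    def test_stage_image_dump(self, tmp_path, rng):
        from cardiofract.segmentation import save_stage_images

        img = bimodal_slice(rng)
        paths = save_stage_images(img, tmp_path)
        assert all(p.exists() for p in paths) and len(paths) == 3

    def test_polarity_invariance(self, rng):
        img = bimodal_slice(rng)
        t = isodata_threshold(img)
        edge_bright = sobel_border(binarize(img, t))
        inverted = ImageSlice(255 - img.pixels)
        t_inv = isodata_threshold(inverted)
        edge_dark = sobel_border(binarize(inverted, t_inv, bright_foreground=False))
        assert t_inv == pytest.approx(255 - t, abs=1.0)
        assert np.array_equal(edge_bright.pixels, edge_dark.pixels)
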