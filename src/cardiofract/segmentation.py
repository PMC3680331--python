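"""Endocardial border extraction from a short-axis grayscale slice.

The border is obtained in three deterministic steps, mirroring the classic
bright-blood cine workflow: (1) automatic intensity thresholding of the
region of interest with the iterative-intermeans (IsoData) rule, (2)
binarization with the blood pool (bright phase, balanced-SSFP convention)
as foreground, and (3) edge detection on the binary mask with the 3x3
Sobel operator — any pixel of nonzero gradient magnitude is a border
pixel.  Papillary muscles and subvalvular structures that survive
binarization contribute their own outlines to the edge image; they are
part of the endocardial complexity being measured and are deliberately
not removed.
"""

from __future__ import annotations

import dataclasses
from typing import Optional

import numpy as np
from scipy import ndimage

__all__ = [
    "ImageSlice",
    "BinaryMask",
    "EdgeImage",
    "RoiSpec",
    "SegmentationError",
    "isodata_threshold",
    "binarize",
    "sobel_border",
    "extract_endocardial_border",
]

#: quantization used for non-integer intensity data
N_HISTOGRAM_BINS = 256
#: convergence tolerance of the intermeans iteration, in intensity units
#: (integer data) or histogram-bin widths (float data)
ISODATA_TOL = 0.5
ISODATA_MAX_ITER = 500


class SegmentationError(ValueError):
    """Raised for degenerate inputs (constant ROI, empty mask, ...)."""


@dataclasses.dataclass(frozen=True)
class RoiSpec:
    """Rectangular region of interest, 0-based, half-open ``[x0, x1) x [y0, y1)``.

    ``x`` indexes columns, ``y`` rows.  ROI delineation is the only manual
    step of the analysis; when no ROI is given the full frame is used.
    """

    slice_index: int
    x0: int
    y0: int
    x1: int
    y1: int

    def __post_init__(self) -> None:
        if not (self.x1 > self.x0 and self.y1 > self.y0):
            raise ValueError(f"empty ROI rectangle: {self}")

    def validate_against(self, shape: tuple[int, int]) -> None:
        h, w = shape
        if self.x0 < 0 or self.y0 < 0 or self.x1 > w or self.y1 > h:
            raise ValueError(f"ROI {self} outside image bounds {shape}")

    @classmethod
    def full_frame(cls, shape: tuple[int, int], slice_index: int = 0) -> "RoiSpec":
        h, w = shape
        return cls(slice_index=slice_index, x0=0, y0=0, x1=w, y1=h)

    def slices(self) -> tuple[slice, slice]:
        return slice(self.y0, self.y1), slice(self.x0, self.x1)


@dataclasses.dataclass(frozen=True)
class ImageSlice:
    """One 2-D grayscale end-diastolic frame with in-plane geometry."""

    pixels: np.ndarray
    slice_index: int = 0
    pixel_spacing_mm: float = 1.0

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError("ImageSlice.pixels must be 2-D")
        if np.any(px < 0):
            raise ValueError("intensities must be non-negative")
        if self.pixel_spacing_mm <= 0:
            raise ValueError("pixel_spacing_mm must be positive")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclasses.dataclass(frozen=True)
class BinaryMask:
    """Binary raster; 1 = blood pool (bright phase)."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or not np.isin(px, (0, 1)).all():
            raise ValueError("BinaryMask must be a 2-D {0,1} grid")
        object.__setattr__(self, "pixels", px.astype(np.uint8))


@dataclasses.dataclass(frozen=True)
class EdgeImage:
    """Binary raster of the extracted endocardial border."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or not np.isin(px, (0, 1)).all():
            raise ValueError("EdgeImage must be a 2-D {0,1} grid")
        object.__setattr__(self, "pixels", px.astype(np.uint8))

    @property
    def n_edge_pixels(self) -> int:
        return int(self.pixels.sum())


def _roi_or_full(image: ImageSlice, roi: Optional[RoiSpec]) -> RoiSpec:
    if roi is None:
        return RoiSpec.full_frame(image.shape, image.slice_index)
    roi.validate_against(image.shape)
    return roi


def isodata_threshold(image: ImageSlice, roi: Optional[RoiSpec] = None) -> float:
    """Iterative-intermeans (IsoData) threshold of the ROI intensities.

    Iterates ``t_{k+1} = (mean(I <= t_k) + mean(I > t_k)) / 2`` until the
    update is below :data:`ISODATA_TOL`.  Integer images iterate on the raw
    intensities; floating-point images are quantized to
    :data:`N_HISTOGRAM_BINS` bins first and the converged bin threshold is
    mapped back to intensity units.

    Raises
    ------
    SegmentationError
        If the ROI is constant ("degenerate histogram") or the iteration
        does not converge within :data:`ISODATA_MAX_ITER` steps.
    """
    roi = _roi_or_full(image, roi)
    values = np.asarray(image.pixels)[roi.slices()].ravel().astype(np.float64)
    vmin, vmax = float(values.min()), float(values.max())
    if vmin == vmax:
        raise SegmentationError(
            f"degenerate histogram: ROI is constant at intensity {vmin}"
        )

    integral = np.issubdtype(np.asarray(image.pixels).dtype, np.integer)
    if integral:
        work = values
        scale, offset = 1.0, 0.0
    else:
        # quantize to bin indices; threshold returned in original units
        scale = (vmax - vmin) / (N_HISTOGRAM_BINS - 1)
        offset = vmin
        work = np.round((values - vmin) / scale)

    t = work.mean()
    for _ in range(ISODATA_MAX_ITER):
        low = work[work <= t]
        high = work[work > t]
        if low.size == 0 or high.size == 0:
            # mean-started iteration always brackets data; guard anyway
            t = work.mean()
            low = work[work <= t]
            high = work[work > t]
        t_next = 0.5 * (low.mean() + high.mean())
        if abs(t_next - t) < ISODATA_TOL:
            return float(t_next * scale + offset)
        t = t_next
    raise SegmentationError(
        f"IsoData iteration failed to converge within {ISODATA_MAX_ITER} "
        f"steps (last t={t * scale + offset:.4f})"
    )


def binarize(
    image: ImageSlice,
    threshold: float,
    roi: Optional[RoiSpec] = None,
    bright_foreground: bool = True,
) -> BinaryMask:
    """Binarize: foreground iff intensity strictly above ``threshold``.

    Pixels outside the ROI are background.  ``bright_foreground=False``
    flips the polarity convention (foreground below threshold), for
    inverted-contrast data.
    """
    roi = _roi_or_full(image, roi)
    px = np.asarray(image.pixels, dtype=np.float64)
    if not (px.min() <= threshold <= px.max()):
        raise ValueError(
            f"threshold {threshold} outside intensity range "
            f"[{px.min()}, {px.max()}]"
        )
    fg = px > threshold if bright_foreground else px < threshold
    mask = np.zeros(px.shape, dtype=np.uint8)
    ys, xs = roi.slices()
    mask[ys, xs] = fg[ys, xs]
    return BinaryMask(mask)


def sobel_border(mask: BinaryMask) -> EdgeImage:
    """Edges of a binary mask: 3x3 Sobel gradient magnitude > 0.

    On a {0,1} image any nonzero gradient marks the maximal-gradient locus,
    so no magnitude cut-off is needed; the resulting border band is at most
    two pixels wide across a step edge.
    """
    px = np.asarray(mask.pixels, dtype=np.float64)
    if px.sum() == 0:
        raise SegmentationError("no border: mask has no foreground pixels")
    gx = ndimage.sobel(px, axis=1, mode="nearest")
    gy = ndimage.sobel(px, axis=0, mode="nearest")
    magnitude = np.hypot(gx, gy)
    return EdgeImage((magnitude > 1e-12).astype(np.uint8))


def fill_holes(mask: BinaryMask) -> BinaryMask:
    """Optional morphological cleanup (off by default in the pipeline)."""
    return BinaryMask(ndimage.binary_fill_holes(mask.pixels).astype(np.uint8))


def save_stage_images(
    image: ImageSlice, out_dir, roi: Optional[RoiSpec] = None, prefix: str = "slice"
) -> list:
    """Debug dump: PNGs of the input, binarized mask and edge image."""
    from pathlib import Path

    import imageio.v3 as iio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t = isodata_threshold(image, roi)
    mask = binarize(image, t, roi)
    edge = sobel_border(mask)
    px = np.asarray(image.pixels, dtype=np.float64)
    scaled = (255 * (px - px.min()) / (np.ptp(px) or 1)).astype(np.uint8)
    paths = []
    for name, arr in (
        ("input", scaled),
        ("mask", mask.pixels * 255),
        ("edges", edge.pixels * 255),
    ):
        p = out / f"{prefix}_{image.slice_index:02d}_{name}.png"
        iio.imwrite(p, arr.astype(np.uint8))
        paths.append(p)
    return paths


def extract_endocardial_border(
    image: ImageSlice,
    roi: Optional[RoiSpec] = None,
    morphological_cleanup: bool = False,
) -> EdgeImage:
    """Full segmentation chain: threshold -> binarize -> Sobel edges.

    Deterministic for fixed input.  ``morphological_cleanup`` fills holes
    in the blood-pool mask before edge detection; it is off by default
    because it removes papillary/trabecular outlines and therefore changes
    the measured fractal dimension.
    """
    t = isodata_threshold(image, roi)
    mask = binarize(image, t, roi)
    if morphological_cleanup:
        mask = fill_holes(mask)
    return sobel_border(mask)
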