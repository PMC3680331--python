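"""Box-counting fractal dimension of a binary edge image.

A grid of boxes of side ``s`` is laid over the border and the number of
boxes containing at least one edge pixel is counted; as the grid calibre
grows the count decays as a power of the scale, and the fractal dimension
(FD) is minus the slope of the ordinary least-squares line through
``ln(count)`` versus ``ln(scale)``, with scale = box size / image size.

Grid calibres run over consecutive integer box sizes from 2 px up to 45%
of the border diameter (the longer side of the border's tight bounding
box).  The same calibre series is applied in four grid orientations —
the grid anchored in turn at each corner of the border bounding box —
and each orientation is fitted separately; the slice FD is the mean of
the four per-orientation FDs.

For a smooth planar curve FD -> 1 at fine scales; a border that wrinkles
at every scale fills more of the plane and its FD rises toward 2.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import stats

from .segmentation import EdgeImage

__all__ = [
    "BoxCountSeries",
    "SliceFDResult",
    "ORIGINS",
    "border_diameter",
    "box_size_series",
    "count_boxes",
    "fit_fd",
    "slice_fd",
]

MIN_BOX_SIZE = 2
MAX_SCALE_FRACTION = 0.45  # of the border diameter
#: grid anchor corners, as (flip_rows, flip_cols) of the bounding box
ORIGINS = ("tl", "tr", "bl", "br")
#: sanity band for the FD of a connected, non-degenerate planar border;
#: values outside raise a quality flag on the result, never a clamp
FD_SANITY_BAND = (0.9, 2.1)


class InsufficientScaleRangeError(ValueError):
    """Border too small to support at least two box sizes."""


@dataclasses.dataclass(frozen=True)
class BoxCountSeries:
    """Per-orientation box counts for one edge image.

    ``counts[origin]`` maps 1:1 onto ``box_sizes_px``; counts are
    non-increasing in box size and every count is at least 1.
    """

    box_sizes_px: np.ndarray
    scales: np.ndarray
    counts: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        sizes = np.asarray(self.box_sizes_px, dtype=int)
        if sizes.size < 2 or np.any(np.diff(sizes) <= 0):
            raise ValueError("box sizes must be >= 2 strictly increasing values")
        if sizes[0] != MIN_BOX_SIZE:
            raise ValueError(f"minimum box size must be {MIN_BOX_SIZE}")
        for origin, c in self.counts.items():
            c = np.asarray(c)
            if c.shape != sizes.shape:
                raise ValueError(f"counts[{origin}] shape mismatch")
            if np.any(c < 1):
                raise ValueError(f"counts[{origin}] must all be >= 1")


@dataclasses.dataclass(frozen=True)
class SliceFDResult:
    """Fractal dimension of one slice: four orientations and their mean."""

    fd_per_orientation: tuple[float, float, float, float]
    fd: float
    fit_r2_per_orientation: tuple[float, float, float, float]
    n_box_sizes: int
    flags: tuple[str, ...] = ()


def _nonzero_bbox(edge: EdgeImage) -> tuple[np.ndarray, np.ndarray, int, int]:
    rows, cols = np.nonzero(edge.pixels)
    if rows.size == 0:
        raise ValueError("empty edge image")
    rows = rows - rows.min()
    cols = cols - cols.min()
    return rows, cols, int(rows.max()) + 1, int(cols.max()) + 1


def border_diameter(edge: EdgeImage) -> int:
    """Diameter of the border: longer side of its tight bounding box, px."""
    _, _, h, w = _nonzero_bbox(edge)
    return max(h, w)


def box_size_series(diameter: int) -> np.ndarray:
    """Consecutive integer box sizes from 2 to ``floor(0.45 * diameter)``."""
    s_max = int(np.floor(MAX_SCALE_FRACTION * diameter))
    if s_max < MIN_BOX_SIZE + 1:
        raise InsufficientScaleRangeError(
            f"insufficient scale range: diameter {diameter} px allows "
            f"max box size {s_max} (< 2 usable sizes)"
        )
    return np.arange(MIN_BOX_SIZE, s_max + 1, dtype=int)


def count_boxes(edge: EdgeImage, box_size: int, origin: str = "tl") -> int:
    """Number of grid boxes of side ``box_size`` containing an edge pixel.

    The grid tiles the border bounding region anchored at one of its four
    corners (``origin`` in {"tl", "tr", "bl", "br"}).
    """
    if box_size < MIN_BOX_SIZE:
        raise ValueError(f"box_size must be >= {MIN_BOX_SIZE}")
    if origin not in ORIGINS:
        raise ValueError(f"origin must be one of {ORIGINS}")
    rows, cols, h, w = _nonzero_bbox(edge)
    if origin in ("bl", "br"):
        rows = (h - 1) - rows
    if origin in ("tr", "br"):
        cols = (w - 1) - cols
    cell_ids = (rows // box_size) * ((w // box_size) + 1) + (cols // box_size)
    return int(np.unique(cell_ids).size)


def fit_fd(
    box_sizes: np.ndarray, counts: np.ndarray, image_size: int
) -> tuple[float, float]:
    """OLS fit of ln(count) on ln(scale); returns (FD, r^2).

    FD is minus the slope.  ``image_size`` only shifts the intercept of
    the ln-ln line, never the slope, so the FD is insensitive to its
    precise definition.
    """
    box_sizes = np.asarray(box_sizes, dtype=float)
    counts = np.asarray(counts, dtype=float)
    if np.unique(box_sizes).size < 2:
        raise ValueError("need at least 2 distinct box sizes to fit")
    scales = box_sizes / float(image_size)
    fit = stats.linregress(np.log(scales), np.log(counts))
    return -float(fit.slope), float(fit.rvalue) ** 2


def box_count_series(edge: EdgeImage, image_size: int) -> BoxCountSeries:
    """All per-orientation counts over the full calibre series."""
    sizes = box_size_series(border_diameter(edge))
    counts = {
        origin: np.array([count_boxes(edge, int(s), origin) for s in sizes])
        for origin in ORIGINS
    }
    return BoxCountSeries(
        box_sizes_px=sizes, scales=sizes / float(image_size), counts=counts
    )


def slice_fd(edge: EdgeImage, image_size: int | None = None) -> SliceFDResult:
    """Slice FD: fit each grid orientation, average the four FDs.

    ``image_size`` defaults to the longer side of the edge frame (the
    analyzed ROI); it affects only the regression intercept.
    """
    if image_size is None:
        image_size = max(edge.pixels.shape)
    series = box_count_series(edge, image_size)
    fds, r2s = [], []
    for origin in ORIGINS:
        fd, r2 = fit_fd(series.box_sizes_px, series.counts[origin], image_size)
        fds.append(fd)
        r2s.append(r2)
    mean_fd = float(np.mean(fds))
    flags: list[str] = []
    if not (FD_SANITY_BAND[0] < mean_fd < FD_SANITY_BAND[1]):
        flags.append("fd-outside-sanity-band")
    return SliceFDResult(
        fd_per_orientation=tuple(fds),
        fd=mean_fd,
        fit_r2_per_orientation=tuple(r2s),
        n_box_sizes=int(series.box_sizes_px.size),
        flags=tuple(flags),
    )
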