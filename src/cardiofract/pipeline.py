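"""End-to-end per-subject analysis: stack in, FD profile + perimetry out.

The most apical slice — a few millilitres of blood, highly prone to
partial-volume averaging — is excluded by default and can be kept with a
flag.  Slices whose segmentation or fractal fit fails (degenerate
histogram, border too small for the calibre series) are reported as
missing and excluded from the averages with a warning; they are never
imputed.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from typing import Mapping, Optional, Sequence

from .boxcount import InsufficientScaleRangeError, SliceFDResult, slice_fd
from .profile import (
    PerimetryResult,
    VentricleFDProfile,
    build_profile,
    partition_thirds,
    perimetry,
)
from .segmentation import (
    EdgeImage,
    ImageSlice,
    RoiSpec,
    SegmentationError,
    extract_endocardial_border,
)

__all__ = ["SubjectAnalysis", "analyze_slices"]

log = logging.getLogger("cardiofract")


@dataclasses.dataclass(frozen=True)
class SubjectAnalysis:
    profile: VentricleFDProfile
    perimetry: PerimetryResult
    edges: tuple[EdgeImage, ...]
    analyzed_indices: tuple[int, ...]
    failed_indices: tuple[int, ...]


def analyze_slices(
    slices: Sequence[ImageSlice],
    bsa_m2: float,
    rois: Optional[Mapping[int, RoiSpec]] = None,
    exclude_apical: bool = True,
    thirds_over: str = "analyzed",
    morphological_cleanup: bool = False,
) -> SubjectAnalysis:
    """Run segmentation, box counting, aggregation and perimetry.

    ``slices`` must be ordered base->apex.  ``thirds_over`` chooses whether
    the basal/mid/apical split is computed over the analyzed slices
    ("analyzed", default) or over all acquired slice positions
    ("acquired"), in which case excluded/failed positions still occupy
    their place in the partition.
    """
    if thirds_over not in ("analyzed", "acquired"):
        raise ValueError("thirds_over must be 'analyzed' or 'acquired'")
    n_total = len(slices)
    if n_total == 0:
        raise ValueError("empty stack")
    use = list(range(n_total))
    if exclude_apical and n_total > 1:
        use = use[:-1]

    results: list[tuple[int, SliceFDResult, EdgeImage]] = []
    failed: list[int] = []
    for i in use:
        roi = rois.get(i) if rois else None
        try:
            edge = extract_endocardial_border(
                slices[i], roi, morphological_cleanup=morphological_cleanup
            )
            fd = slice_fd(edge)
        except (SegmentationError, InsufficientScaleRangeError, ValueError) as exc:
            warnings.warn(f"slice {i} excluded from analysis: {exc}")
            failed.append(i)
            continue
        results.append((i, fd, edge))
    if len(results) < 3:
        raise ValueError(
            f"only {len(results)} analyzable slices; need >= 3 for a profile"
        )

    indices = [i for i, _, _ in results]
    fd_results = [fd for _, fd, _ in results]
    edges = [e for _, _, e in results]

    if thirds_over == "analyzed":
        profile = build_profile(fd_results)
    else:
        # thirds over acquired slice positions; maxima over analyzed members
        thirds_full = partition_thirds(n_total)
        fds = [fd.fd for fd in fd_results]
        by_region = {
            region: [fds[k] for k, i in enumerate(indices) if i in rng]
            for region, rng in thirds_full.items()
        }
        if any(len(v) == 0 for v in by_region.values()):
            raise ValueError("a third has no analyzable slices")
        base = build_profile(fd_results)  # global mean over analyzed slices
        profile = VentricleFDProfile(
            slice_fds=base.slice_fds,
            global_fd=base.global_fd,
            thirds=thirds_full,
            max_fd_basal=max(by_region["basal"]),
            max_fd_mid=max(by_region["mid"]),
            max_fd_apical=max(by_region["apical"]),
        )

    spacing = slices[0].pixel_spacing_mm
    perim = perimetry(edges, spacing, bsa_m2)
    log.info(
        "analyzed %d/%d slices: global FD %.3f, max apical FD %.3f, "
        "indexed perimeter %.1f mm/m^2",
        len(indices),
        n_total,
        profile.global_fd,
        profile.max_fd_apical,
        perim.indexed_perimeter_mm_per_m2,
    )
    return SubjectAnalysis(
        profile=profile,
        perimetry=perim,
        edges=tuple(edges),
        analyzed_indices=tuple(indices),
        failed_indices=tuple(failed),
    )
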