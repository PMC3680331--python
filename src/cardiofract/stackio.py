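"""Stack reading, annotation parsing and result writing.

Supported inputs: a DICOM series directory, a NIfTI volume (.nii /
.nii.gz) or a multi-page TIFF, each holding one end-diastolic frame per
short-axis slice.  Slices are returned ordered base->apex; stacks stored
apex-first are reversed on read.  Pixel spacing comes from the file
header where the format carries it (DICOM, NIfTI) and must be supplied
explicitly otherwise — a missing spacing is an error, never a silent
default.

Outputs: a per-slice CSV (slice index, per-orientation FDs, mean FD, fit
r^2, perimeter) and a subject-level JSON summary (global FD, per-third
maxima, indexed perimetry, comparator criteria).  Re-reading reproduces
the numbers exactly at the serialized precision (FDs are written with 3
decimals, matching the reporting precision of the analysis).
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .boxcount import ORIGINS
from .comparators import JacquierResult, PetersenResult
from .profile import PerimetryResult, VentricleFDProfile
from .segmentation import ImageSlice, RoiSpec

__all__ = [
    "StackGeometry",
    "SubjectMeta",
    "StackReadError",
    "read_stack",
    "read_roi_json",
    "write_results",
    "read_results_json",
]

FD_DECIMALS = 3


class StackReadError(IOError):
    """Unreadable, empty or under-specified image stack."""


@dataclasses.dataclass(frozen=True)
class StackGeometry:
    """Acquisition geometry of a short-axis stack."""

    pixel_spacing_mm: tuple[float, float]
    slice_thickness_mm: float
    inter_slice_gap_mm: float
    n_slices: int
    orientation: str = "base_to_apex"

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.pixel_spacing_mm):
            raise ValueError("pixel spacing must be positive")
        if self.slice_thickness_mm <= 0:
            raise ValueError("slice thickness must be positive")
        if self.inter_slice_gap_mm < 0:
            raise ValueError("inter-slice gap must be non-negative")
        if self.n_slices < 1:
            raise ValueError("need at least one slice")
        if self.orientation not in ("base_to_apex", "apex_to_base"):
            raise ValueError(f"unknown orientation {self.orientation!r}")

    @property
    def in_plane_spacing_mm(self) -> float:
        return float(np.mean(self.pixel_spacing_mm))


@dataclasses.dataclass(frozen=True)
class SubjectMeta:
    subject_id: str
    bsa_m2: float
    group_label: Optional[str] = None  # "case" / "control"

    def __post_init__(self) -> None:
        if self.bsa_m2 <= 0:
            raise ValueError("body-surface area must be positive")
        if self.group_label not in (None, "case", "control"):
            raise ValueError(f"unknown group label {self.group_label!r}")


def _infer_format(path: Path, format_hint: Optional[str]) -> str:
    if format_hint:
        return format_hint
    if path.is_dir():
        return "dicom"
    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        return "nifti"
    if name.endswith((".tif", ".tiff")):
        return "tiff"
    raise StackReadError(f"cannot infer stack format of {path}")


def _read_tiff(path: Path) -> np.ndarray:
    import tifffile

    data = np.asarray(tifffile.imread(path))
    if data.ndim == 2:
        data = data[None]
    if data.ndim != 3:
        raise StackReadError(f"TIFF at {path} is not a 2-D page stack")
    return data


def _read_nifti(path: Path) -> tuple[np.ndarray, tuple[float, float], float]:
    import nibabel as nib

    vol = nib.load(str(path))
    data = np.asarray(vol.dataobj)
    if data.ndim != 3:
        raise StackReadError(f"NIfTI at {path} is not a 3-D volume")
    zooms = vol.header.get_zooms()
    # slices along the last axis -> (slice, row, col)
    stack = np.transpose(data, (2, 1, 0))
    return stack, (float(zooms[1]), float(zooms[0])), float(zooms[2])


def _read_dicom_series(path: Path) -> tuple[np.ndarray, tuple[float, float], float, float]:
    import pydicom

    frames = []
    for f in sorted(path.iterdir()):
        if not f.is_file():
            continue
        try:
            ds = pydicom.dcmread(str(f))
            frames.append(ds)
        except Exception:
            continue
    if not frames:
        raise StackReadError(f"empty stack: no readable DICOM images in {path}")

    def sort_key(ds):
        loc = getattr(ds, "SliceLocation", None)
        if loc is not None:
            return float(loc)
        return int(getattr(ds, "InstanceNumber", 0))

    frames.sort(key=sort_key)
    data = np.stack([ds.pixel_array for ds in frames])
    ds0 = frames[0]
    spacing = getattr(ds0, "PixelSpacing", None)
    if spacing is None:
        raise StackReadError(
            "DICOM series lacks PixelSpacing; supply an explicit override"
        )
    thickness = float(getattr(ds0, "SliceThickness", 0.0) or 0.0)
    between = getattr(ds0, "SpacingBetweenSlices", None)
    gap = max(float(between) - thickness, 0.0) if between is not None else 0.0
    return data, (float(spacing[0]), float(spacing[1])), thickness, gap


def read_stack(
    path: str | Path,
    format_hint: Optional[str] = None,
    pixel_spacing_mm: Optional[float | tuple[float, float]] = None,
    slice_thickness_mm: Optional[float] = None,
    inter_slice_gap_mm: Optional[float] = None,
    orientation: str = "base_to_apex",
) -> tuple[list[ImageSlice], StackGeometry]:
    """Read an image stack; slices come back ordered base->apex.

    Explicit keyword overrides win over header values.  Formats that do
    not carry spacing (TIFF) require the ``pixel_spacing_mm`` override.
    """
    path = Path(path)
    if not path.exists():
        raise StackReadError(f"stack path does not exist: {path}")
    fmt = _infer_format(path, format_hint)

    header_spacing: Optional[tuple[float, float]] = None
    header_thickness: Optional[float] = None
    header_gap: Optional[float] = None
    if fmt == "tiff":
        data = _read_tiff(path)
    elif fmt == "nifti":
        data, header_spacing, header_thickness = _read_nifti(path)
    elif fmt == "dicom":
        data, header_spacing, header_thickness, header_gap = _read_dicom_series(path)
    else:
        raise StackReadError(f"unknown format {fmt!r}")
    if data.shape[0] == 0:
        raise StackReadError(f"empty stack at {path}")

    if pixel_spacing_mm is not None:
        spacing = (
            (float(pixel_spacing_mm),) * 2
            if np.isscalar(pixel_spacing_mm)
            else (float(pixel_spacing_mm[0]), float(pixel_spacing_mm[1]))
        )
    elif header_spacing is not None:
        spacing = header_spacing
    else:
        raise StackReadError(
            f"{fmt} stack carries no pixel spacing; pass pixel_spacing_mm "
            "explicitly (no silent default)"
        )
    thickness = (
        slice_thickness_mm
        if slice_thickness_mm is not None
        else (header_thickness if header_thickness else None)
    )
    if thickness is None:
        # thickness only matters for disc-summation masses, not FD/perimetry
        warnings.warn(
            "slice thickness unavailable from header; defaulting to 1.0 mm "
            "(do not use this geometry for mass computations)"
        )
        thickness = 1.0
    gap = (
        inter_slice_gap_mm
        if inter_slice_gap_mm is not None
        else (header_gap if header_gap is not None else 0.0)
    )

    if orientation == "apex_to_base":
        data = data[::-1]
    geometry = StackGeometry(
        pixel_spacing_mm=spacing,
        slice_thickness_mm=float(thickness),
        inter_slice_gap_mm=float(gap),
        n_slices=int(data.shape[0]),
        orientation="base_to_apex",  # after any reversal
    )
    in_plane = geometry.in_plane_spacing_mm
    slices = [
        ImageSlice(pixels=np.asarray(frame, dtype=float), slice_index=i,
                   pixel_spacing_mm=in_plane)
        for i, frame in enumerate(data)
    ]
    return slices, geometry


def read_roi_json(path: str | Path) -> dict[int, RoiSpec]:
    """Per-slice rectangular ROIs from JSON.

    Format: ``{"rois": [{"slice_index": 0, "x0": .., "y0": .., "x1": ..,
    "y1": ..}, ...]}`` with 0-based half-open pixel rectangles.
    """
    with open(path) as fh:
        payload = json.load(fh)
    rois = {}
    for entry in payload["rois"]:
        spec = RoiSpec(**{k: int(entry[k]) for k in ("slice_index", "x0", "y0", "x1", "y1")})
        rois[spec.slice_index] = spec
    return rois


def write_results(
    out_dir: str | Path,
    subject: SubjectMeta,
    profile: VentricleFDProfile,
    perimetry: PerimetryResult,
    petersen: Optional[PetersenResult] = None,
    jacquier: Optional[JacquierResult] = None,
) -> tuple[Path, Path]:
    """Write the per-slice CSV and subject-level JSON summary.

    Returns (csv_path, json_path).  FDs are serialized with
    :data:`FD_DECIMALS` decimals; re-reading reproduces the values
    bit-identically at that precision.
    """
    if len(profile.slice_fds) == 0:
        raise ValueError("empty profile: nothing to write")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    rows = []
    for i, (r, perim) in enumerate(
        zip(profile.slice_fds, perimetry.slice_perimeters_mm)
    ):
        row = {"slice_index": i}
        for origin, fd, r2 in zip(ORIGINS, r.fd_per_orientation, r.fit_r2_per_orientation):
            row[f"fd_{origin}"] = round(fd, FD_DECIMALS)
            row[f"r2_{origin}"] = round(r2, 4)
        row["fd_mean"] = round(r.fd, FD_DECIMALS)
        row["n_box_sizes"] = r.n_box_sizes
        row["perimeter_mm"] = round(perim, 2)
        row["flags"] = ";".join(r.flags)
        rows.append(row)
    csv_path = out_dir / f"{subject.subject_id}_slices.csv"
    pd.DataFrame(rows).to_csv(csv_path, index=False)

    summary = {
        "subject_id": subject.subject_id,
        "bsa_m2": subject.bsa_m2,
        "group_label": subject.group_label,
        "n_slices_analyzed": len(profile.slice_fds),
        "global_fd": round(profile.global_fd, FD_DECIMALS),
        "max_fd_basal": round(profile.max_fd_basal, FD_DECIMALS),
        "max_fd_mid": round(profile.max_fd_mid, FD_DECIMALS),
        "max_fd_apical": round(profile.max_fd_apical, FD_DECIMALS),
        "thirds": {k: [v.start, v.stop] for k, v in profile.thirds.items()},
        "total_perimeter_mm": round(perimetry.total_perimeter_mm, 2),
        "indexed_perimeter_mm_per_m2": round(
            perimetry.indexed_perimeter_mm_per_m2, 2
        ),
    }
    if petersen is not None:
        summary["petersen"] = {
            "nc_mm": petersen.nc_mm,
            "c_mm": petersen.c_mm,
            "ratio": round(petersen.ratio, 3),
            "diagnostic": petersen.diagnostic,
        }
    if jacquier is not None:
        summary["jacquier"] = {
            "compacted_mass_g": round(jacquier.compacted_mass_g, 2),
            "total_mass_g": round(jacquier.total_mass_g, 2),
            "trabeculated_mass_g": round(jacquier.trabeculated_mass_g, 2),
            "trabeculated_pct": round(jacquier.trabeculated_pct, 2),
            "diagnostic": jacquier.diagnostic,
        }
    json_path = out_dir / f"{subject.subject_id}_summary.json"
    with open(json_path, "w") as fh:
        json.dump(summary, fh, indent=2)
    return csv_path, json_path


def read_results_json(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)
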