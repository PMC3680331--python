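"""Comparator CMR criteria for excessive trabeculation.

Two established diagnostic criteria against which the fractal measure is
compared:

* **Petersen NC/C ratio** — the ratio of noncompacted to compacted wall
  thickness measured at end-diastole on the most trabeculated long-axis
  segment; a ratio strictly greater than 2.3 is diagnostic.  When several
  views are measured the maximal ratio is used.
* **Jacquier trabeculated-mass fraction** — trabeculated LV mass is total
  LV mass minus compacted LV mass (compacted contours include papillary
  muscle and exclude trabeculation; papillary muscle indistinguishable
  from trabeculae is treated as trabeculae by the *caller's* contouring —
  this module computes from the supplied masses and does not infer the
  assignment).  Trabeculated mass strictly above 20% of total LV mass is
  diagnostic.

Masses come from slice-wise epicardial/endocardial contour areas by disc
summation: each slice contributes area x (thickness + gap), converted to
grams with a myocardial density of 1.05 g/ml (standard CMR convention;
configurable).
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

__all__ = [
    "PetersenResult",
    "JacquierResult",
    "PETERSEN_DIAGNOSTIC_RATIO",
    "JACQUIER_DIAGNOSTIC_PCT",
    "MYOCARDIAL_DENSITY_G_PER_ML",
    "petersen_ratio",
    "mass_from_contour_areas",
    "jacquier_fraction",
]

PETERSEN_DIAGNOSTIC_RATIO = 2.3
JACQUIER_DIAGNOSTIC_PCT = 20.0
MYOCARDIAL_DENSITY_G_PER_ML = 1.05


@dataclasses.dataclass(frozen=True)
class PetersenResult:
    nc_mm: float
    c_mm: float
    ratio: float
    diagnostic: bool


@dataclasses.dataclass(frozen=True)
class JacquierResult:
    compacted_mass_g: float
    total_mass_g: float
    trabeculated_mass_g: float
    trabeculated_pct: float
    diagnostic: bool


def petersen_ratio(
    nc_mm: float | Sequence[float], c_mm: float | Sequence[float]
) -> PetersenResult:
    """NC/C wall-thickness ratio; > 2.3 at end-diastole is diagnostic.

    Scalars give a single measurement; equal-length sequences are treated
    as paired per-view measurements and the view with the maximal ratio is
    used.
    """
    nc = np.atleast_1d(np.asarray(nc_mm, dtype=float))
    c = np.atleast_1d(np.asarray(c_mm, dtype=float))
    if nc.shape != c.shape:
        raise ValueError("nc_mm and c_mm must be paired per view")
    if np.any(c <= 0):
        raise ValueError("compacted wall thickness must be positive")
    if np.any(nc < 0):
        raise ValueError("noncompacted wall thickness must be non-negative")
    ratios = nc / c
    i = int(np.argmax(ratios))
    ratio = float(ratios[i])
    return PetersenResult(
        nc_mm=float(nc[i]),
        c_mm=float(c[i]),
        ratio=ratio,
        diagnostic=bool(ratio > PETERSEN_DIAGNOSTIC_RATIO),
    )


def mass_from_contour_areas(
    areas_mm2: Sequence[float],
    slice_thickness_mm: float,
    inter_slice_gap_mm: float = 0.0,
    density_g_per_ml: float = MYOCARDIAL_DENSITY_G_PER_ML,
    include_gap: bool = True,
) -> float:
    """Disc-summation mass in grams from per-slice contour areas (mm^2).

    Each slice contributes ``area x (thickness [+ gap])`` mm^3; 1 mm^3 =
    1e-3 ml.  Gap inclusion is on by default so contiguous discs cover the
    full ventricular length.
    """
    areas = np.asarray(areas_mm2, dtype=float)
    if areas.size == 0:
        raise ValueError("need at least one slice area")
    if np.any(areas < 0):
        raise ValueError("contour areas must be non-negative")
    if slice_thickness_mm <= 0 or inter_slice_gap_mm < 0:
        raise ValueError("invalid slice geometry")
    height_mm = slice_thickness_mm + (inter_slice_gap_mm if include_gap else 0.0)
    volume_ml = float(areas.sum()) * height_mm * 1e-3
    return volume_ml * density_g_per_ml


def jacquier_fraction(compacted_mass_g: float, total_mass_g: float) -> JacquierResult:
    """Trabeculated mass = total - compacted; > 20% of total is diagnostic."""
    if not (0 < compacted_mass_g <= total_mass_g):
        raise ValueError(
            "contour inconsistency: need 0 < compacted mass <= total mass "
            f"(got compacted={compacted_mass_g}, total={total_mass_g})"
        )
    trab = total_mass_g - compacted_mass_g
    pct = 100.0 * trab / total_mass_g
    return JacquierResult(
        compacted_mass_g=float(compacted_mass_g),
        total_mass_g=float(total_mass_g),
        trabeculated_mass_g=float(trab),
        trabeculated_pct=float(pct),
        diagnostic=bool(pct > JACQUIER_DIAGNOSTIC_PCT),
    )
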