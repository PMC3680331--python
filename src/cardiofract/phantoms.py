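"""Synthetic short-axis phantoms with controllable trabecular complexity.

Every pipeline stage is testable without patient data via three phantom
families:

* **smooth annulus** — a bright circular blood pool inside a darker
  myocardial ring (bright-blood bSSFP contrast), plus Gaussian noise;
  its border is a smooth curve, so the measured FD should sit near 1.
* **trabeculated slice** — the lumen boundary is perturbed,
  ``r(theta) = r0 + A sin(n theta) + roughness(theta)``, where the
  roughness term is a seeded spectral (1/f^beta) radial perturbation
  whose amplitude dials border complexity up and down; optional dark
  papillary blobs sit inside the lumen.  The spectral perturbation is a
  controllable stand-in for trabecular irregularity, not a claim about
  true trabecular morphology.
* **quadric Koch ring** — an analytic calibration curve: each side of a
  square carries the classic 4-segment, scale-1/3 Koch generator, so the
  self-similarity dimension is ln 4 / ln 3 ~ 1.2619 independent of
  rasterization.

``make_stack`` assembles whole synthetic subjects.  The ``normal``
preset keeps apical roughness low; the ``lvnc`` preset raises apical
roughness and trabecular count so that, analyzed end-to-end, the maximal
apical FD separates the two presets.  All generators require a seed.
"""

from __future__ import annotations

import dataclasses
from typing import Literal, Optional

import numpy as np
from skimage import draw

from .segmentation import BinaryMask, EdgeImage, ImageSlice

__all__ = [
    "PhantomSpec",
    "PhantomSlice",
    "PhantomStack",
    "KOCH_DIMENSION",
    "make_smooth_annulus",
    "make_trabeculated_slice",
    "make_koch_ring",
    "make_stack",
    "PRESETS",
]

KOCH_DIMENSION = float(np.log(4) / np.log(3))

BorderModel = Literal["smooth", "sinusoidal_trabeculae", "fbm_rough", "koch_ring"]


@dataclasses.dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic slice / stack.

    Intensity defaults follow the bright-blood convention (blood pool
    brighter than myocardium); geometric defaults give a mid-ventricular
    cavity of ~55 px radius in a 256 px frame at 1 mm spacing.
    """

    frame_px: int = 256
    n_slices: int = 10
    pixel_spacing_mm: float = 1.0
    slice_thickness_mm: float = 7.0
    inter_slice_gap_mm: float = 3.0
    lumen_radius_px: float = 55.0
    wall_thickness_px: float = 22.0
    blood_mean: float = 180.0
    myo_mean: float = 60.0
    background_mean: float = 35.0
    noise_sd: float = 8.0
    border_model: BorderModel = "smooth"
    roughness_amplitude: float = 0.0
    roughness_beta: float = 1.2
    n_trabeculae: int = 12
    n_papillary: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.blood_mean <= self.myo_mean:
            raise ValueError("bright-blood convention requires blood_mean > myo_mean")
        if self.roughness_amplitude < 0:
            raise ValueError("roughness amplitude must be >= 0")
        if self.roughness_amplitude >= self.lumen_radius_px:
            raise ValueError("roughness amplitude must be below the lumen radius")
        if self.frame_px < 32 or self.n_slices < 1:
            raise ValueError("geometric inconsistency in phantom spec")
        if self.lumen_radius_px + self.wall_thickness_px >= self.frame_px / 2:
            raise ValueError("ventricle does not fit in the frame")


@dataclasses.dataclass(frozen=True)
class PhantomSlice:
    image: ImageSlice
    true_lumen_mask: BinaryMask


@dataclasses.dataclass(frozen=True)
class PhantomStack:
    slices: tuple[PhantomSlice, ...]
    spec: PhantomSpec
    preset: str


_N_THETA = 4096  # boundary polygon sampling


def _radial_profile(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Lumen boundary radius r(theta) on a fixed theta grid."""
    theta = np.linspace(0.0, 2.0 * np.pi, _N_THETA, endpoint=False)
    r = np.full(_N_THETA, spec.lumen_radius_px)
    if spec.border_model in ("sinusoidal_trabeculae", "fbm_rough"):
        if spec.border_model == "sinusoidal_trabeculae" and spec.n_trabeculae < 1:
            raise ValueError("sinusoidal model needs n_trabeculae >= 1")
        if spec.n_trabeculae >= 1:
            r = r + spec.roughness_amplitude * np.sin(spec.n_trabeculae * theta)
        # spectral 1/f^beta perturbation: higher harmonics decay as k^-beta
        k_max = 64
        amps = np.arange(2, k_max) ** (-spec.roughness_beta)
        phases = rng.uniform(0, 2 * np.pi, k_max - 2)
        weights = rng.normal(0.0, 1.0, k_max - 2) * amps
        rough = np.zeros(_N_THETA)
        for k, (w, ph) in enumerate(zip(weights, phases), start=2):
            rough += w * np.cos(k * theta + ph)
        rms = np.sqrt(np.mean(rough**2))
        if rms > 0 and spec.roughness_amplitude > 0:
            rough *= (0.5 * spec.roughness_amplitude) / rms
            r = r + rough
    if np.any(r <= 2.0):
        raise ValueError("self-intersecting boundary: radius collapses to <= 2 px")
    return r


def _render_slice(
    spec: PhantomSpec,
    radius: np.ndarray,
    rng: np.random.Generator,
    slice_index: int,
    papillary_rng: Optional[np.random.Generator] = None,
) -> PhantomSlice:
    n = spec.frame_px
    cy = cx = n / 2.0
    theta = np.linspace(0.0, 2.0 * np.pi, _N_THETA, endpoint=False)

    img = np.full((n, n), spec.background_mean)
    # epicardial disc (myocardium) then lumen polygon (blood)
    epi_r = float(radius.max()) + spec.wall_thickness_px
    rr, cc = draw.disk((cy, cx), epi_r, shape=(n, n))
    img[rr, cc] = spec.myo_mean
    pr = cy + radius * np.sin(theta)
    pc = cx + radius * np.cos(theta)
    rr, cc = draw.polygon(pr, pc, shape=(n, n))
    lumen = np.zeros((n, n), dtype=np.uint8)
    lumen[rr, cc] = 1
    img[lumen == 1] = spec.blood_mean

    if spec.n_papillary > 0:
        prng = papillary_rng if papillary_rng is not None else rng
        placed = 0
        for _ in range(50 * spec.n_papillary):
            if placed >= spec.n_papillary:
                break
            ang = prng.uniform(0, 2 * np.pi)
            rad = prng.uniform(0.3, 0.6) * spec.lumen_radius_px
            blob_r = prng.uniform(2.5, 4.5)
            by, bx = cy + rad * np.sin(ang), cx + rad * np.cos(ang)
            rr, cc = draw.disk((by, bx), blob_r, shape=(n, n))
            if np.all(lumen[rr, cc] == 1):  # keep blobs inside the blood pool
                img[rr, cc] = spec.myo_mean
                lumen[rr, cc] = 0
                placed += 1

    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, img.shape)
    img = np.clip(img, 0.0, None)
    return PhantomSlice(
        image=ImageSlice(
            pixels=img, slice_index=slice_index, pixel_spacing_mm=spec.pixel_spacing_mm
        ),
        true_lumen_mask=BinaryMask(lumen),
    )


def make_smooth_annulus(spec: PhantomSpec, slice_index: int = 0) -> PhantomSlice:
    """Noisy annulus with a perfectly smooth circular endocardial border."""
    spec = dataclasses.replace(spec, border_model="smooth", roughness_amplitude=0.0)
    rng = np.random.default_rng(spec.seed)
    radius = _radial_profile(spec, rng)
    return _render_slice(spec, radius, rng, slice_index)


def make_trabeculated_slice(spec: PhantomSpec, slice_index: int = 0) -> PhantomSlice:
    """Slice with sinusoidal + spectral boundary roughness (and papillaries).

    ``roughness_amplitude = 0`` with the sinusoidal model reduces exactly
    to the smooth annulus.
    """
    if spec.border_model == "smooth":
        spec = dataclasses.replace(spec, border_model="sinusoidal_trabeculae")
    rng = np.random.default_rng(spec.seed)
    radius = _radial_profile(spec, rng)
    return _render_slice(spec, radius, rng, slice_index)


def koch_polygon(iterations: int, scale_px: int = 3, margin: float = 0.4) -> np.ndarray:
    """Vertex list (row, col) of the closed Koch ring, last vertex omitted.

    Each of the square's 4 sides carries ``4**iterations`` generator
    segments, so the closed polygon has ``4 * 4**iterations`` vertices.
    """
    if not (0 <= iterations <= 6):
        raise ValueError("iterations must be in [0, 6]")
    if scale_px < 2:
        raise ValueError(
            "resolution insufficient: smallest segment must be >= 2 px"
        )
    side = (3**iterations) * scale_px

    def kochify(p0: np.ndarray, p1: np.ndarray, depth: int) -> list[np.ndarray]:
        if depth == 0:
            return [p0, p1]
        v = (p1 - p0) / 3.0
        a = p0 + v
        b = p0 + 2.0 * v
        # outward normal (ring wound counter-clockwise -> left of travel)
        normal = np.array([-v[1], v[0]])
        tip = (a + b) / 2.0 + normal * (np.sqrt(3.0) / 2.0)
        pts: list[np.ndarray] = []
        for q0, q1 in ((p0, a), (a, tip), (tip, b), (b, p1)):
            seg = kochify(q0, q1, depth - 1)
            pts.extend(seg[:-1])
        pts.append(p1)
        return pts

    bump = side * margin
    corners = [
        np.array([bump, bump]),
        np.array([bump, bump + side]),
        np.array([bump + side, bump + side]),
        np.array([bump + side, bump]),
    ]
    poly: list[np.ndarray] = []
    for i in range(4):
        seg = kochify(corners[i], corners[(i + 1) % 4], iterations)
        poly.extend(seg[:-1])
    return np.asarray(poly)


def make_koch_ring(
    iterations: int, scale_px: int = 3, margin: float = 0.4
) -> EdgeImage:
    """Closed quadric Koch-style ring rasterized as a binary edge image.

    Each side of a square of length ``3**iterations * scale_px`` px is
    replaced by the classic Koch generator (4 segments at scale 1/3, bump
    outward), iterated; the analytic self-similarity dimension of the
    border is ln 4 / ln 3.  ``iterations = 0`` gives the plain square.

    Raises if the smallest construction segment would fall below 2 px.
    """
    poly = koch_polygon(iterations, scale_px, margin)
    side = (3**iterations) * scale_px
    frame = int(np.ceil(side * (1 + 2 * margin))) + 2
    img = np.zeros((frame, frame), dtype=np.uint8)
    for i in range(len(poly)):
        r0, c0 = np.round(poly[i]).astype(int)
        r1, c1 = np.round(poly[(i + 1) % len(poly)]).astype(int)
        rr, cc = draw.line(r0, c0, r1, c1)
        img[rr, cc] = 1
    return EdgeImage(img)


def _taper(spec: PhantomSpec, i: int) -> float:
    """Base->apex lumen radius taper (apex ~55% of the basal radius)."""
    frac = i / max(spec.n_slices - 1, 1)
    return spec.lumen_radius_px * (1.0 - 0.45 * frac)


PRESETS: dict[str, dict] = {
    # roughness amplitudes in px at (base, apex); linear ramp in between
    "normal": {
        "amp_base": 1.0,
        "amp_apex": 2.0,
        "n_trabeculae": 8,
        "n_papillary_mid": 2,
    },
    "lvnc": {
        "amp_base": 1.5,
        "amp_apex": 8.0,
        "n_trabeculae": 16,
        "n_papillary_mid": 2,
    },
}


def make_stack(
    spec: PhantomSpec, preset: str = "normal"
) -> PhantomStack:
    """Full synthetic subject: base->apex slices with preset roughness.

    ``normal`` keeps apical roughness low; ``lvnc`` ramps apical roughness
    and trabecular count up, emulating apically-dominant hypertrabeculation.
    ``koch`` builds every lumen from a 3-iteration Koch polygon and serves
    as a calibration stack.
    """
    if spec.n_slices < 3:
        raise ValueError("a stack needs >= 3 slices")
    if preset == "koch":
        return _make_koch_stack(spec)
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose normal, lvnc or koch")
    p = PRESETS[preset]
    ss = np.random.SeedSequence(spec.seed)
    child_seeds = ss.generate_state(spec.n_slices)
    slices = []
    for i in range(spec.n_slices):
        frac = i / (spec.n_slices - 1)
        amp = p["amp_base"] + (p["amp_apex"] - p["amp_base"]) * frac
        mid = abs(frac - 0.5) < 0.25  # papillary muscles in the mid cavity
        sl_spec = dataclasses.replace(
            spec,
            border_model="sinusoidal_trabeculae",
            roughness_amplitude=amp,
            lumen_radius_px=_taper(spec, i),
            n_trabeculae=p["n_trabeculae"],
            n_papillary=p["n_papillary_mid"] if mid else 0,
            seed=int(child_seeds[i]),
        )
        slices.append(make_trabeculated_slice(sl_spec, slice_index=i))
    return PhantomStack(slices=tuple(slices), spec=spec, preset=preset)


def _make_koch_stack(spec: PhantomSpec) -> PhantomStack:
    """Calibration stack: every lumen is a 3-iteration Koch polygon."""
    rng = np.random.default_rng(spec.seed)
    n = spec.frame_px
    slices = []
    for i in range(spec.n_slices):
        edge = make_koch_ring(3, scale_px=3)
        # fill the koch ring into a lumen mask centred in the frame
        from scipy import ndimage as _ndi

        filled = _ndi.binary_fill_holes(edge.pixels).astype(np.uint8)
        fh, fw = filled.shape
        if fh > n or fw > n:
            raise ValueError("frame too small for the koch calibration lumen")
        img = np.full((n, n), spec.myo_mean)
        lumen = np.zeros((n, n), dtype=np.uint8)
        r0, c0 = (n - fh) // 2, (n - fw) // 2
        lumen[r0 : r0 + fh, c0 : c0 + fw] = filled
        img[lumen == 1] = spec.blood_mean
        if spec.noise_sd > 0:
            img = img + rng.normal(0.0, spec.noise_sd, img.shape)
        img = np.clip(img, 0.0, None)
        slices.append(
            PhantomSlice(
                image=ImageSlice(
                    pixels=img,
                    slice_index=i,
                    pixel_spacing_mm=spec.pixel_spacing_mm,
                ),
                true_lumen_mask=BinaryMask(lumen),
            )
        )
    return PhantomStack(slices=tuple(slices), spec=spec, preset="koch")
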