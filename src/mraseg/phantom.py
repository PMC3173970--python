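"""Synthetic NEMA-IEC-style body-phantom slice and its noise model.

The NEMA IEC body phantom is a quality-assurance object: an elliptical
water-filled cavity holding six spherical inserts of inner diameters
10, 13, 17, 22, 28 and 37 mm.  The generator renders the equatorial 2D
slice of that object — every sphere appears as a disc at its maximal
diameter — on a configurable grid (default 128×128 pixels of
4.6875 mm, i.e. a 600×600 mm field of view).

The module also houses the spheres-to-background ratio (SBR): the total
cross-sectional disc area divided by the remaining slice area,

    SBR = 100 · S / (A − S),   S = π·Σ (d/2)²,   A = M·N·h²,

which for the six standard diameters on the default grid evaluates to
0.702 %.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import GeometryError, ParameterError
from .image import Image2D

__all__ = [
    "PhantomSpec",
    "NoiseModel",
    "generate_phantom",
    "add_gaussian_noise",
    "sphere_area_total",
    "slice_area",
    "sbr",
    "NEMA_SPHERE_DIAMETERS_MM",
]

#: Inner diameters (mm) of the six spherical inserts of the IEC body phantom.
NEMA_SPHERE_DIAMETERS_MM: tuple[float, ...] = (10.0, 13.0, 17.0, 22.0, 28.0, 37.0)


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and intensity levels of the rendered phantom slice.

    Intensities default to an 8-bit-scale three-level contrast
    (background 0, cavity 100, sphere 200).  Sphere centres sit on a ring
    of radius ``sphere_ring_radius_mm`` around the cavity centre,
    angularly equispaced, mirroring the physical insert arrangement.
    """

    grid: tuple[int, int] = (128, 128)
    pixel_size_mm: float = 4.6875
    cavity_semi_axes_mm: tuple[float, float] = (150.0, 110.0)
    sphere_diameters_mm: tuple[float, ...] = NEMA_SPHERE_DIAMETERS_MM
    background_intensity: float = 0.0
    cavity_intensity: float = 100.0
    sphere_intensity: float = 200.0
    sphere_ring_radius_mm: float = 57.0
    ring_start_angle_deg: float = 0.0
    supersample: int = 1

    def __post_init__(self) -> None:
        m, n = self.grid
        if m < 1 or n < 1:
            raise ParameterError("grid dimensions must be positive")
        if self.pixel_size_mm <= 0:
            raise ParameterError("pixel_size_mm must be positive")
        if any(d <= 0 for d in self.sphere_diameters_mm):
            raise ParameterError("sphere diameters must be positive")
        if self.supersample < 1:
            raise ParameterError("supersample must be >= 1")

    @property
    def sphere_centres_mm(self) -> list[tuple[float, float]]:
        """(x, y) centres in mm relative to the cavity centre."""
        k = len(self.sphere_diameters_mm)
        out = []
        for i in range(k):
            ang = math.radians(self.ring_start_angle_deg) + 2.0 * math.pi * i / max(k, 1)
            r = self.sphere_ring_radius_mm
            out.append((r * math.cos(ang), r * math.sin(ang)))
        return out

    def validate_geometry(self) -> None:
        """Raise :class:`GeometryError` if discs overlap or escape the cavity."""
        a, b = self.cavity_semi_axes_mm
        m, n = self.grid
        if a * 2 > n * self.pixel_size_mm or b * 2 > m * self.pixel_size_mm:
            raise GeometryError("cavity does not fit inside the grid")
        centres = self.sphere_centres_mm
        radii = [d / 2.0 for d in self.sphere_diameters_mm]
        for i, ((x, y), r) in enumerate(zip(centres, radii)):
            # conservative containment: the disc's bounding extremes must
            # stay inside the ellipse
            if ((abs(x) + r) / a) ** 2 + ((abs(y) + r) / b) ** 2 > 1.0:
                raise GeometryError(
                    f"disc {i} (d={2 * r} mm) does not fit inside the cavity"
                )
        for i in range(len(centres)):
            for j in range(i + 1, len(centres)):
                dx = centres[i][0] - centres[j][0]
                dy = centres[i][1] - centres[j][1]
                if math.hypot(dx, dy) <= radii[i] + radii[j]:
                    raise GeometryError(f"discs {i} and {j} overlap")


@dataclass(frozen=True)
class NoiseModel:
    """Additive i.i.d. Gaussian noise with σ = sigma_fraction × max(image)."""

    sigma_fraction: float = 0.20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_fraction < 0:
            raise ParameterError("sigma_fraction must be non-negative")


def generate_phantom(spec: PhantomSpec = PhantomSpec()) -> Image2D:
    """Render the phantom slice described by ``spec``.

    Pixel membership is decided by the pixel-centre point by default; with
    ``spec.supersample = s > 1`` each pixel averages an s×s subgrid of
    point samples (area-fraction antialiasing), which smooths staircase
    edges.  Deterministic given ``spec``.
    """
    spec.validate_geometry()
    m, n = spec.grid
    s = spec.supersample
    h = spec.pixel_size_mm
    # physical coordinates of (super)sample points, origin at grid centre
    ys = (np.arange(m * s) + 0.5) / s * h - m * h / 2.0
    xs = (np.arange(n * s) + 0.5) / s * h - n * h / 2.0
    X, Y = np.meshgrid(xs, ys)
    a, b = spec.cavity_semi_axes_mm
    inside_cavity = (X / a) ** 2 + (Y / b) ** 2 <= 1.0
    inside_sphere = np.zeros_like(inside_cavity)
    for (cx, cy), d in zip(spec.sphere_centres_mm, spec.sphere_diameters_mm):
        r = d / 2.0
        inside_sphere |= (X - cx) ** 2 + (Y - cy) ** 2 <= r * r
    img = np.full((m * s, n * s), spec.background_intensity, dtype=np.float64)
    img[inside_cavity] = spec.cavity_intensity
    img[inside_sphere] = spec.sphere_intensity
    if s > 1:
        img = img.reshape(m, s, n, s).mean(axis=(1, 3))
    peak = max(255.0, spec.sphere_intensity)
    return Image2D(img, pixel_size_mm=h, intensity_max=255.0 if peak <= 255 else peak)


def add_gaussian_noise(img: Image2D, model: NoiseModel) -> Image2D:
    """Add zero-mean white Gaussian noise, σ = sigma_fraction · max(img).

    The output is *not* clipped to any integer range: metrics and the
    transforms operate on real arrays, and clipping is applied only when an
    integer image file is written.
    """
    sigma = model.sigma_fraction * float(img.pixels.max())
    if sigma == 0.0:
        return img.with_pixels(img.pixels.copy())
    rng = np.random.default_rng(model.seed)
    noise = rng.normal(0.0, sigma, size=img.shape)
    return img.with_pixels(img.pixels + noise)


def sphere_area_total(diameters_mm) -> float:
    """Total cross-sectional disc area π·Σ(d/2)² in mm²."""
    diameters_mm = list(diameters_mm)
    if any(d <= 0 for d in diameters_mm):
        raise ParameterError("diameters must be positive")
    return float(sum(math.pi * (d / 2.0) ** 2 for d in diameters_mm))


def slice_area(M: int, N: int, pixel_size_mm: float) -> float:
    """Physical area of an M×N slice in mm²."""
    if M < 1 or N < 1 or pixel_size_mm <= 0:
        raise ParameterError("invalid slice dimensions")
    return float(M * N * pixel_size_mm * pixel_size_mm)


def sbr(diameters_mm, M: int, N: int, pixel_size_mm: float) -> float:
    """Spheres-to-background ratio in percent: 100·S/(A−S)."""
    S = sphere_area_total(diameters_mm) if list(diameters_mm) else 0.0
    A = slice_area(M, N, pixel_size_mm)
    if S >= A:
        raise GeometryError("sphere area must be smaller than the slice area")
    return float(100.0 * S / (A - S))
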