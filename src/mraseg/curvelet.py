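"""Fast discrete curvelet transform via frequency-wedge wrapping.

The transform tiles the 2D frequency plane into one nondirectional coarse
band plus, per finer scale, a ring of angular wedges.  Each wedge window
is the product of a radial (scale) window and an angular window built from
the Meyer auxiliary polynomial; the squared windows sum to one at every
frequency sample, so the collection is a *tight frame*: analysis preserves
energy exactly and the adjoint is the exact inverse.

Window admissibility.  With the Meyer auxiliary
``ν(x) = x⁴(35 − 84x + 70x² − 20x³)`` (ν(x) + ν(1 − x) = 1), the 1D
windows used here satisfy, at every point of their covered ranges,

    Σ_j W²(2^j r) = 1   and   Σ_l V²(t − l) = 1.

Discrete construction.  Radial separation uses concentric-square lowpass
products ``Φ_s(ξ) = φ(2^{J−s} ξ₁)·φ(2^{J−s} ξ₂)`` (the outermost scale is
identically one so the finest ring reaches the frequency corners), with
ring windows ``W_s = √(Φ_s² − Φ_{s−1}²)``; the telescoping sum of squares
is exactly one.  Angular separation multiplies each ring by a smooth
periodic partition of unity in the polar angle, with the number of wedges
at least eight and a multiple of four at the second-coarsest scale and
doubling every other scale toward fine scales — the parabolic scaling that
makes fine-scale curvelets needle shaped (width ≈ length²).

Wrapping.  Each wedge's supported samples are folded periodically into a
rectangle; the rectangle dimensions are taken from the wedge's frequency
support so the fold is collision free, which keeps the frame exactly
tight.  Coefficients are the orthonormal inverse 2D FFT of the wrapped
rectangle, kept complex internally; real inputs reconstruct to real images
(the imaginary residue is checked and dropped).
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field
from functools import cached_property

import numpy as np

from .errors import ParameterError, ShapeMismatchError, StructureError
from .image import Image2D

__all__ = [
    "meyer_nu",
    "radial_profile",
    "radial_window",
    "angular_window",
    "CurveletSystem",
    "CurveletCoefficients",
    "FrequencyTile",
    "plan",
    "wedge_window",
    "fdct_forward",
    "fdct_inverse",
    "threshold_curvelet",
    "denoise_curvelet",
    "coefficient_display",
    "save_coefficients",
    "load_coefficients",
]

#: Degree-7 Meyer auxiliary polynomial used by both 1D windows.
MEYER_POLY_DEGREE = 7

#: Window samples below this are treated as zero when collecting wedge
#: supports.  Squared-window cancellation leaves ~1e-29 residues far outside
#: the true support; clipping them costs ≤ ~1e-24 of the partition of unity
#: but keeps the wrapped rectangles tight.
MASK_TOL = 1e-12


def meyer_nu(x: np.ndarray | float) -> np.ndarray:
    """Meyer auxiliary function: 0 below 0, 1 above 1, ν(x)+ν(1−x)=1."""
    x = np.clip(np.asarray(x, dtype=np.float64), 0.0, 1.0)
    return x**4 * (35.0 - 84.0 * x + 70.0 * x**2 - 20.0 * x**3)


def radial_profile(x: np.ndarray | float) -> np.ndarray:
    """Smooth 1D lowpass profile φ: 1 on |x| ≤ 1/4, 0 beyond |x| ≥ 1/2."""
    ax = np.abs(np.asarray(x, dtype=np.float64))
    return np.cos(0.5 * math.pi * meyer_nu(4.0 * ax - 1.0))


def radial_window(r: np.ndarray | float) -> np.ndarray:
    """Radial window W(r) = √(φ(r/2)² − φ(r)²); Σ_j W²(2^j r) = 1 for r > 0."""
    r = np.asarray(r, dtype=np.float64)
    val = radial_profile(r / 2.0) ** 2 - radial_profile(r) ** 2
    return np.sqrt(np.clip(val, 0.0, None))


def angular_window(t: np.ndarray | float) -> np.ndarray:
    """Angular window V(t) = cos(π·ν(|t|)/2) on |t| ≤ 1; Σ_l V²(t−l) = 1."""
    at = np.abs(np.asarray(t, dtype=np.float64))
    return np.where(at <= 1.0, np.cos(0.5 * math.pi * meyer_nu(at)), 0.0)


@dataclass
class FrequencyTile:
    """One wedge: its supported frequency samples and wrapped rectangle.

    ``rows``/``cols`` index the supported samples on the *centred* (DC at
    array centre) frequency grid; ``wrapped_rows``/``wrapped_cols`` give
    the destination of each sample inside the ``rect_shape`` rectangle —
    the wrapping index map, guaranteed collision free.
    """

    scale: int
    angle: int
    grid_shape: tuple[int, int]
    rows: np.ndarray
    cols: np.ndarray
    values: np.ndarray  # window value at each supported sample
    rect_shape: tuple[int, int]
    row_offset: int
    col_offset: int

    @property
    def wrapped_rows(self) -> np.ndarray:
        return (self.rows - self.row_offset) % self.rect_shape[0]

    @property
    def wrapped_cols(self) -> np.ndarray:
        return (self.cols - self.col_offset) % self.rect_shape[1]

    @property
    def noise_gain(self) -> float:
        """Std of one coefficient under unit-variance white image noise."""
        return math.sqrt(
            float(np.sum(self.values**2)) / (self.rect_shape[0] * self.rect_shape[1])
        )

    def full_mask(self) -> np.ndarray:
        """The wedge window Ũ on the full centred frequency grid."""
        mask = np.zeros(self.grid_shape)
        mask[self.rows, self.cols] = self.values
        return mask

    def analyze(self, fshift: np.ndarray) -> np.ndarray:
        """Window, wrap and inverse-transform one wedge of the spectrum."""
        rect = np.zeros(self.rect_shape, dtype=np.complex128)
        rect[self.wrapped_rows, self.wrapped_cols] = (
            self.values * fshift[self.rows, self.cols]
        )
        return np.fft.ifft2(rect, norm="ortho")

    def synthesize(self, coeff: np.ndarray, facc: np.ndarray) -> None:
        """Adjoint of :meth:`analyze`: unwrap and accumulate into ``facc``."""
        if coeff.shape != self.rect_shape:
            raise StructureError(
                f"band {self.scale},{self.angle}: coefficient shape "
                f"{coeff.shape} != {self.rect_shape}"
            )
        rect = np.fft.fft2(coeff, norm="ortho")
        facc[self.rows, self.cols] += (
            self.values * rect[self.wrapped_rows, self.wrapped_cols]
        )


class CurveletSystem:
    """Wedge geometry and window samplings for one image shape.

    Scales are numbered 1 (coarsest, single nondirectional band) to
    ``nscales`` (finest).  Use :func:`plan` to construct.
    """

    def __init__(self, M: int, N: int, nscales: int, nangles_coarse: int) -> None:
        if M < 32 or N < 32:
            raise ParameterError("image must be at least 32x32")
        if nangles_coarse < 8 or nangles_coarse % 4:
            raise ParameterError(
                "angle count at the second-coarsest scale must be >= 8 "
                "and a multiple of 4"
            )
        if nscales < 2:
            raise ParameterError("need at least 2 scales")
        if 2 ** (nscales + 3) > min(M, N):
            raise ParameterError(
                f"{nscales} scales is too deep for a {M}x{N} image"
            )
        self.shape = (M, N)
        self.nscales = nscales
        self.nangles_coarse = nangles_coarse

    @property
    def angles_per_scale(self) -> list[int]:
        """Band count per scale: [1, n₂, n₃, …], doubling every other scale."""
        out = [1]
        for sc in range(2, self.nscales + 1):
            out.append(self.nangles_coarse * 2 ** ((sc - 2) // 2))
        return out

    def band_keys(self) -> list[tuple[int, int]]:
        return [
            (sc + 1, l)
            for sc, n in enumerate(self.angles_per_scale)
            for l in range(n)
        ]

    # -- window sampling ---------------------------------------------------

    def _lowpass(self, sc: int) -> np.ndarray:
        """Φ_sc on the centred grid (identically 1 for sc = nscales)."""
        M, N = self.shape
        if sc >= self.nscales:
            return np.ones((M, N))
        xi1 = (np.arange(M) - M // 2) / M
        xi2 = (np.arange(N) - N // 2) / N
        scale = 2.0 ** (self.nscales - sc)
        return radial_profile(xi1 * scale)[:, None] * radial_profile(xi2 * scale)[None, :]

    @cached_property
    def tiles(self) -> dict[tuple[int, int], FrequencyTile]:
        """All frequency tiles, built on first use."""
        M, N = self.shape
        xi1 = (np.arange(M) - M // 2) / M
        xi2 = (np.arange(N) - N // 2) / N
        theta = np.arctan2(xi1[:, None], xi2[None, :])
        tiles: dict[tuple[int, int], FrequencyTile] = {}
        prev_low = self._lowpass(1)
        # coarsest, nondirectional band
        tiles[(1, 0)] = self._make_tile(1, 0, *self._support(prev_low))
        for sc in range(2, self.nscales + 1):
            low = self._lowpass(sc)
            ring = np.sqrt(np.clip(low**2 - prev_low**2, 0.0, None))
            prev_low = low
            n = self.angles_per_scale[sc - 1]
            ys, xs = np.nonzero(ring > MASK_TOL)
            w = ring[ys, xs]
            t = theta[ys, xs] * n / (2.0 * math.pi)
            base = np.floor(t)
            frac = t - base
            l0 = base.astype(np.int64) % n
            l1 = (l0 + 1) % n
            v0 = w * angular_window(frac)
            v1 = w * angular_window(frac - 1.0)
            wedge_ids = np.concatenate([l0, l1])
            rows = np.concatenate([ys, ys])
            cols = np.concatenate([xs, xs])
            vals = np.concatenate([v0, v1])
            keep = vals > MASK_TOL
            wedge_ids, rows, cols, vals = (
                wedge_ids[keep],
                rows[keep],
                cols[keep],
                vals[keep],
            )
            order = np.argsort(wedge_ids, kind="stable")
            wedge_ids, rows, cols, vals = (
                wedge_ids[order],
                rows[order],
                cols[order],
                vals[order],
            )
            bounds = np.searchsorted(wedge_ids, np.arange(n + 1))
            for l in range(n):
                s = slice(bounds[l], bounds[l + 1])
                if bounds[l] == bounds[l + 1]:
                    raise ParameterError(
                        f"wedge ({sc},{l}) has empty frequency support; the "
                        "plan is too deep or too angular for this image"
                    )
                tiles[(sc, l)] = self._make_tile(sc, l, rows[s], cols[s], vals[s])
        return tiles

    @staticmethod
    def _support(mask: np.ndarray):
        ys, xs = np.nonzero(mask > MASK_TOL)
        return ys, xs, mask[ys, xs]

    def _make_tile(self, sc, l, rows, cols, vals) -> FrequencyTile:
        r0, r1 = int(rows.min()), int(rows.max())
        c0, c1 = int(cols.min()), int(cols.max())
        return FrequencyTile(
            scale=sc,
            angle=l,
            grid_shape=self.shape,
            rows=rows,
            cols=cols,
            values=vals,
            rect_shape=(r1 - r0 + 1, c1 - c0 + 1),
            row_offset=r0,
            col_offset=c0,
        )

    def partition_of_unity(self) -> np.ndarray:
        """Σ_{j,l} |Ũ_{j,l}|² over the full grid (≡ 1 for a valid plan)."""
        acc = np.zeros(self.shape)
        for tile in self.tiles.values():
            acc[tile.rows, tile.cols] += tile.values**2
        return acc

    def to_manifest(self) -> dict:
        return {
            "kind": "curvelet-coefficients",
            "shape": list(self.shape),
            "nscales": self.nscales,
            "nangles_coarse": self.nangles_coarse,
            "angles_per_scale": self.angles_per_scale,
            "window": f"meyer-polynomial-degree-{MEYER_POLY_DEGREE}",
            "convention": "DC at array centre; ortho FFT; collision-free "
            "periodic fold into support-sized rectangles",
        }


def plan(
    M: int,
    N: int,
    nscales: int | None = None,
    nangles_coarse: int | None = None,
) -> CurveletSystem:
    """Build a curvelet system for an M×N image.

    The default depth counts the coarsest nondirectional band as a scale
    and yields ``max(2, ceil(log2(min(M,N))) − 4)`` scales — five for a
    512×512 image; pass ``nscales`` to override.  The default angle count
    at the second-coarsest scale is 16.
    """
    if nscales is None:
        nscales = max(2, math.ceil(math.log2(min(M, N))) - 4)
    if nangles_coarse is None:
        nangles_coarse = 16
    return CurveletSystem(M, N, nscales, nangles_coarse)


def wedge_window(system: CurveletSystem, j: int, l: int) -> FrequencyTile:
    """The frequency tile of scale ``j``, angle ``l`` (coarsest: j=1, l=0)."""
    try:
        return system.tiles[(j, l)]
    except KeyError:
        raise ParameterError(f"no wedge (scale={j}, angle={l}) in this plan") from None


@dataclass
class CurveletCoefficients:
    """Scale → angle → complex coefficient arrays, tied to their system."""

    system: CurveletSystem
    bands: dict[tuple[int, int], np.ndarray]

    def energy(self) -> float:
        return float(sum(np.sum(np.abs(b) ** 2) for b in self.bands.values()))

    def coefficient_count(self) -> int:
        return int(sum(b.size for b in self.bands.values()))

    def copy(self) -> "CurveletCoefficients":
        return CurveletCoefficients(
            self.system, {k: v.copy() for k, v in self.bands.items()}
        )


def fdct_forward(img: Image2D, system: CurveletSystem) -> CurveletCoefficients:
    """Forward FDCT: FFT → window each wedge → wrap → inverse FFT per wedge."""
    if img.shape != system.shape:
        raise ShapeMismatchError(
            f"image shape {img.shape} does not match plan {system.shape}"
        )
    fshift = np.fft.fftshift(np.fft.fft2(img.pixels, norm="ortho"))
    bands = {key: tile.analyze(fshift) for key, tile in system.tiles.items()}
    return CurveletCoefficients(system=system, bands=bands)


def fdct_inverse(
    coeffs: CurveletCoefficients,
    *,
    pixel_size_mm: float = 1.0,
    intensity_max: float = 255.0,
    max_imag_residue: float | None = None,
) -> Image2D:
    """Inverse FDCT (the adjoint; exact because the frame is tight).

    The output is projected onto real images by dropping the imaginary
    part, which enforces conjugate symmetry of the synthesized spectrum.
    For untouched coefficients of a real image the imaginary residue is at
    rounding level; coefficient thresholding may leave a small genuine
    residue because antipodal wedge pairs are thresholded independently.
    Pass ``max_imag_residue`` to assert a relative bound on it.
    """
    system = coeffs.system
    if set(coeffs.bands) != set(system.tiles):
        raise StructureError("coefficient bands do not match the system's wedges")
    facc = np.zeros(system.shape, dtype=np.complex128)
    for key, tile in system.tiles.items():
        tile.synthesize(coeffs.bands[key], facc)
    out = np.fft.ifft2(np.fft.ifftshift(facc), norm="ortho")
    if max_imag_residue is not None:
        scale = float(np.max(np.abs(out.real))) or 1.0
        residue = float(np.max(np.abs(out.imag))) / scale
        if residue > max_imag_residue:
            raise StructureError(
                f"imaginary residue {residue:.3e} exceeds {max_imag_residue:.3e}; "
                "the coefficients do not come from a real image"
            )
    return Image2D(out.real, pixel_size_mm, intensity_max)


def threshold_curvelet(
    coeffs: CurveletCoefficients,
    t: float,
    *,
    band_gains: dict[tuple[int, int], float] | None = None,
) -> CurveletCoefficients:
    """Hard-threshold every band except the coarsest (|c| < t → 0).

    ``band_gains`` optionally rescales the threshold per band (used for
    noise-gain equalisation by :func:`denoise_curvelet`).
    """
    if t < 0:
        raise ParameterError("threshold must be non-negative")
    bands = {}
    for key, arr in coeffs.bands.items():
        if key[0] == 1:
            bands[key] = arr.copy()
            continue
        tt = t * (band_gains[key] if band_gains else 1.0)
        bands[key] = np.where(np.abs(arr) < tt, 0.0, arr)
    return CurveletCoefficients(system=coeffs.system, bands=bands)


def denoise_curvelet(
    img: Image2D,
    system: CurveletSystem,
    t: float,
    *,
    equalize_noise: bool = True,
) -> Image2D:
    """forward → hard threshold → inverse.

    With ``equalize_noise`` (default) the threshold for band (j, l) is
    ``t × g_{j,l}`` where ``g_{j,l}`` is that band's white-noise gain, so a
    single ``t`` expressed in image-noise standard deviations (e.g. 3σ)
    acts uniformly across bands.
    """
    coeffs = fdct_forward(img, system)
    gains = (
        {key: tile.noise_gain for key, tile in system.tiles.items()}
        if equalize_noise
        else None
    )
    out = fdct_inverse(threshold_curvelet(coeffs, t, band_gains=gains))
    return img.with_pixels(out.pixels)


def coefficient_display(
    coeffs: CurveletCoefficients, *, return_layout: bool = False
):
    """Mosaic of coefficient magnitudes: coarse band at the centre,
    concentric annuli of angular panels toward the border.

    Panels never overlap and the mosaic has at least as many pixels as
    there are coefficients.
    """
    system = coeffs.system
    per_scale: list[list[np.ndarray]] = []
    for sc, n in enumerate(system.angles_per_scale, start=1):
        per_scale.append([np.abs(coeffs.bands[(sc, l)]) for l in range(n)])

    coarse = per_scale[0][0]
    side = max(coarse.shape)
    placements: dict[tuple[int, int], tuple[int, int]] = {}
    # centre-out layout: record each panel's offset relative to the current
    # canvas, then re-centre as the canvas grows
    offsets: dict[tuple[int, int], tuple[int, int]] = {(1, 0): (0, 0)}
    sides = [side]
    for sc in range(2, system.nscales + 1):
        bands = per_scale[sc - 1]
        n = len(bands)
        q = n // 4
        cell = max(max(b.shape) for b in bands)
        inner = sides[-1]
        outer = max(inner, q * cell) + 2 * cell
        shift = (outer - inner) // 2
        for key in list(offsets):
            r, c = offsets[key]
            offsets[key] = (r + shift, c + shift)
        slots = []
        for i in range(q):  # top strip
            slots.append((0, i * cell))
        for i in range(q):  # right strip
            slots.append((cell + i * cell, outer - cell))
        for i in range(q):  # bottom strip
            slots.append((outer - cell, i * cell))
        for i in range(q):  # left strip
            slots.append((cell + i * cell, 0))
        for l in range(n):
            offsets[(sc, l)] = slots[l]
        sides.append(outer)
    canvas_side = sides[-1]
    canvas = np.zeros((canvas_side, canvas_side))
    layout = {}
    for key, (r, c) in offsets.items():
        band = per_scale[key[0] - 1][key[1]]
        canvas[r : r + band.shape[0], c : c + band.shape[1]] = band
        layout[key] = (r, c, band.shape[0], band.shape[1])
    mosaic = Image2D(canvas, 1.0, 255.0)
    if return_layout:
        return mosaic, layout
    return mosaic


# ---------------------------------------------------------------------------
# serialization: JSON manifest plus one .npy file per (scale, angle) band


def save_coefficients(coeffs: CurveletCoefficients, directory: str | os.PathLike) -> None:
    directory = os.fspath(directory)
    os.makedirs(directory, exist_ok=True)
    with open(os.path.join(directory, "manifest.json"), "w") as fh:
        json.dump(coeffs.system.to_manifest(), fh, indent=2)
    for (sc, l), arr in coeffs.bands.items():
        np.save(os.path.join(directory, f"band_{sc}_{l}.npy"), arr)


def load_coefficients(directory: str | os.PathLike) -> CurveletCoefficients:
    directory = os.fspath(directory)
    with open(os.path.join(directory, "manifest.json")) as fh:
        manifest = json.load(fh)
    if manifest.get("kind") != "curvelet-coefficients":
        raise StructureError("not a curvelet coefficient container")
    system = CurveletSystem(
        *manifest["shape"], manifest["nscales"], manifest["nangles_coarse"]
    )
    bands = {}
    for sc, n in enumerate(system.angles_per_scale, start=1):
        for l in range(n):
            path = os.path.join(directory, f"band_{sc}_{l}.npy")
            if not os.path.exists(path):
                raise StructureError(f"missing band file {path}")
            bands[(sc, l)] = np.load(path)
    return CurveletCoefficients(system=system, bands=bands)
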