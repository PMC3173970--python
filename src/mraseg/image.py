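"""Image container, file I/O, intensity thresholding and fidelity metrics.

The central type is :class:`Image2D`, a thin wrapper around a 2D float array
carrying the physical pixel size and the nominal intensity peak.  All
transforms and the segmentation pipeline operate on this type.

Fidelity metrics follow the usual conventions:

* ``mse(a, b)``  — mean of squared pixel differences,
* ``psnr(a, b)`` — ``10·log10(peak² / mse)`` in dB,
* ``snr(s, n)``  — ``10·log10(Σ s² / Σ (n − s)²)`` in dB, i.e. the energy of
  the reference divided by the energy of the residual.  SNR protocols differ
  between instruments and papers; this reference-difference convention is the
  one implemented and documented here (see docs/methods.md).
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import FormatError, ParameterError, RangeError, ShapeMismatchError

__all__ = [
    "Image2D",
    "QualityReport",
    "read_image",
    "write_image",
    "hard_threshold_intensity",
    "mse",
    "psnr",
    "snr",
]


@dataclass(frozen=True)
class Image2D:
    """A 2D grayscale raster with isotropic physical pixel size.

    Parameters
    ----------
    pixels
        2D array of real intensities, stored as float64.
    pixel_size_mm
        Physical edge length of one (square) pixel in millimetres.
    intensity_max
        Nominal peak of the intensity scale (255 for 8-bit data); used as
        the default PSNR peak.
    """

    pixels: np.ndarray
    pixel_size_mm: float = 1.0
    intensity_max: float = 255.0

    def __post_init__(self) -> None:
        arr = np.asarray(self.pixels, dtype=np.float64)
        if arr.ndim != 2 or arr.shape[0] < 1 or arr.shape[1] < 1:
            raise ParameterError("pixels must be a non-empty 2D array")
        if not np.all(np.isfinite(arr)):
            raise ParameterError("pixel intensities must be finite")
        if not (self.pixel_size_mm > 0):
            raise ParameterError("pixel_size_mm must be positive")
        object.__setattr__(self, "pixels", arr)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    def with_pixels(self, pixels: np.ndarray) -> "Image2D":
        """New image with the same physical metadata but different pixels."""
        return replace(self, pixels=pixels)


#: Sentinel returned by psnr/snr for a zero-error comparison.
PSNR_INF = math.inf


@dataclass(frozen=True)
class QualityReport:
    """Flat record of the fidelity metrics for one image pair."""

    mse: float
    psnr_db: float
    snr_db: float = math.nan

    def __post_init__(self) -> None:
        if (self.mse == 0.0) != (self.psnr_db == PSNR_INF):
            raise ParameterError("mse is 0 exactly when psnr is infinite")

    def to_dict(self) -> dict:
        return {"mse": self.mse, "psnr_db": self.psnr_db, "snr_db": self.snr_db}

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, default=str)

    def to_text(self) -> str:
        return "\n".join(f"{k} = {v}" for k, v in self.to_dict().items())


def _luminance(arr: np.ndarray) -> np.ndarray:
    # ITU-R BT.601 weights, the scikit-image rgb2gray convention.
    return arr[..., 0] * 0.299 + arr[..., 1] * 0.587 + arr[..., 2] * 0.114


def read_image(
    path: str | os.PathLike,
    *,
    pixel_size_mm: float = 1.0,
    to_luminance: bool = False,
) -> Image2D:
    """Read a grayscale PNG/TIFF (or single-slice DICOM) into an :class:`Image2D`.

    Multi-channel rasters are rejected unless ``to_luminance`` is set, in
    which case they are converted with BT.601 weights.  For DICOM, the
    rescale slope/intercept are applied when present and the pixel spacing
    tag overrides ``pixel_size_mm``.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise IOError(f"no such file: {path}")
    if path.lower().endswith((".dcm", ".dicom")):
        return _read_dicom(path, pixel_size_mm)
    import imageio.v3 as iio

    try:
        arr = iio.imread(path)
    except Exception as exc:  # pragma: no cover - backend specific
        raise IOError(f"could not read image {path}: {exc}") from exc
    if arr.ndim == 3:
        if arr.shape[-1] == 4:
            arr = arr[..., :3]
        if not to_luminance:
            raise FormatError(
                f"{path} has {arr.shape[-1]} channels; pass to_luminance=True "
                "to convert"
            )
        arr = _luminance(arr.astype(np.float64))
    if arr.ndim != 2:
        raise FormatError(f"{path}: unsupported array rank {arr.ndim}")
    if arr.dtype.kind not in "uif":
        raise FormatError(f"{path}: unsupported dtype {arr.dtype}")
    peak = 65535.0 if arr.dtype == np.uint16 else 255.0
    return Image2D(arr.astype(np.float64), pixel_size_mm, peak)


def _read_dicom(path: str, pixel_size_mm: float) -> Image2D:
    try:
        import pydicom
    except ImportError as exc:  # pragma: no cover
        raise FormatError("DICOM support requires pydicom") from exc
    ds = pydicom.dcmread(path)
    arr = ds.pixel_array
    if arr.ndim != 2:
        raise FormatError("only single-slice grayscale DICOM is supported")
    arr = arr.astype(np.float64)
    slope = float(getattr(ds, "RescaleSlope", 1.0))
    intercept = float(getattr(ds, "RescaleIntercept", 0.0))
    arr = arr * slope + intercept
    spacing = getattr(ds, "PixelSpacing", None)
    if spacing is not None:
        pixel_size_mm = float(spacing[0])
    bits = int(getattr(ds, "BitsStored", 16))
    return Image2D(arr, pixel_size_mm, float(2**bits - 1))


def write_image(
    img: Image2D,
    path: str | os.PathLike,
    bit_depth: int = 8,
    *,
    clip: bool = False,
) -> None:
    """Write an image as 8- or 16-bit PNG/TIFF.

    Intensities are rounded to the nearest integer; values outside the
    representable range raise :class:`RangeError` unless ``clip`` is set.
    """
    if bit_depth not in (8, 16):
        raise ParameterError("bit_depth must be 8 or 16")
    lo, hi = 0, 2**bit_depth - 1
    arr = np.rint(img.pixels)
    if clip:
        arr = np.clip(arr, lo, hi)
    elif arr.min() < lo or arr.max() > hi:
        raise RangeError(
            f"intensities [{arr.min()}, {arr.max()}] do not fit {bit_depth}-bit "
            "output; pass clip=True to clamp"
        )
    import imageio.v3 as iio

    dtype = np.uint8 if bit_depth == 8 else np.uint16
    iio.imwrite(os.fspath(path), arr.astype(dtype))


def hard_threshold_intensity(img: Image2D, t: float) -> Image2D:
    """Zero every pixel strictly below ``t``; pixels ``>= t`` pass unchanged.

    ``t = 0`` is an exact identity.  This is the pre/post intensity
    thresholding step of the segmentation pipeline (defaults t=35 and t=7 on
    the 8-bit scale).
    """
    if t < 0:
        raise ParameterError("threshold must be non-negative")
    out = img.pixels.copy()
    out[out < t] = 0.0
    return img.with_pixels(out)


def _check_same_shape(a: Image2D, b: Image2D) -> None:
    if a.shape != b.shape:
        raise ShapeMismatchError(f"shape mismatch: {a.shape} vs {b.shape}")


def mse(a: Image2D, b: Image2D) -> float:
    """Mean squared pixel difference between two images of equal shape."""
    _check_same_shape(a, b)
    diff = a.pixels - b.pixels
    return float(np.mean(diff * diff))


def psnr(a: Image2D, b: Image2D, peak: float | None = None) -> float:
    """Peak signal-to-noise ratio in dB; ``inf`` when the images are equal.

    ``peak`` defaults to the nominal ``intensity_max`` of the first image.
    """
    if peak is None:
        peak = a.intensity_max
    if peak <= 0:
        raise ParameterError("peak must be positive")
    err = mse(a, b)
    if err == 0.0:
        return PSNR_INF
    return float(10.0 * math.log10(peak * peak / err))


def snr(signal: Image2D, noisy: Image2D) -> float:
    """Signal-to-noise ratio in dB under the reference-difference convention.

    ``10·log10(Σ signal² / Σ (noisy − signal)²)``.  Invariant under joint
    positive scaling of both inputs.
    """
    _check_same_shape(signal, noisy)
    sig_energy = float(np.sum(signal.pixels**2))
    if sig_energy == 0.0:
        raise ParameterError("signal image has zero energy")
    res_energy = float(np.sum((noisy.pixels - signal.pixels) ** 2))
    if res_energy == 0.0:
        return PSNR_INF
    return float(10.0 * math.log10(sig_energy / res_energy))
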