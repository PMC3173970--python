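"""Orthonormal discrete wavelet transform, 1D and 2D, built from scratch.

Analysis convention: with lowpass l(i) and highpass h(i) of length L,

    a[n] = Σ_i l(i)·x[(2n − i) mod N],   d[n] = Σ_i h(i)·x[(2n − i) mod N],

i.e. circular convolution followed by dyadic downsampling.  The highpass is
the quadrature mirror of the lowpass, h(i) = (−1)^i l(L−1−i).  Under this
periodic (circular) boundary policy the analysis operator of one step is an
orthogonal N×N matrix, so the inverse is its transpose and both Parseval and
perfect reconstruction hold to machine precision.

Odd lengths: a decimated step needs an even length.  When a multilevel
transform meets an odd-length signal (this happens for the ridgelet stage,
whose projections have prime length p), the last sample is carried through
unchanged on the approximation side and the step is applied to the first
N−1 samples.  The carry is an isometry, so energy conservation and exact
invertibility are unaffected; the policy is recorded in the pyramid.

The 2D transform is the nonstandard (Mallat) decomposition: one row pass,
one column pass, recursing on the LL band only.  Subband order is
(LL, LH, HL, HH) where the first letter is the *row* (vertical) filter and
the second the *column* (horizontal) filter.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError, StructureError
from .image import Image2D

__all__ = [
    "WaveletFilter",
    "WaveletPyramid",
    "get_filter",
    "dwt1d_step",
    "idwt1d_step",
    "dwt1d",
    "idwt1d",
    "dwt2d",
    "idwt2d",
    "threshold_pyramid",
    "denoise_wavelet",
    "save_pyramid",
    "load_pyramid",
]

_SQRT2 = math.sqrt(2.0)
_S3 = math.sqrt(3.0)

_FILTER_BANK: dict[str, tuple[float, ...]] = {
    # Haar: plain averages and differences.
    "haar": (1.0 / _SQRT2, 1.0 / _SQRT2),
    # 4-tap Daubechies (two vanishing moments).
    "db2": (
        (1.0 + _S3) / (4.0 * _SQRT2),
        (3.0 + _S3) / (4.0 * _SQRT2),
        (3.0 - _S3) / (4.0 * _SQRT2),
        (1.0 - _S3) / (4.0 * _SQRT2),
    ),
}


@dataclass(frozen=True)
class WaveletFilter:
    """An orthonormal analysis filter pair.

    Invariants (checked on construction): unit l2 norm, Σ lowpass = √2,
    and the highpass is the quadrature mirror of the lowpass.
    """

    name: str
    lowpass: tuple[float, ...]
    highpass: tuple[float, ...]

    def __post_init__(self) -> None:
        lo = np.asarray(self.lowpass)
        hi = np.asarray(self.highpass)
        if lo.shape != hi.shape or lo.ndim != 1 or lo.size % 2:
            raise ParameterError("filters must be equal even-length 1D sequences")
        if abs(np.sum(lo * lo) - 1.0) > 1e-12:
            raise ParameterError("lowpass must have unit l2 norm")
        if abs(np.sum(lo) - _SQRT2) > 1e-12:
            raise ParameterError("lowpass must sum to sqrt(2)")
        qmf = np.array([(-1.0) ** i * lo[lo.size - 1 - i] for i in range(lo.size)])
        if np.max(np.abs(hi - qmf)) > 1e-12:
            raise ParameterError("highpass must be the quadrature mirror of lowpass")

    def __len__(self) -> int:
        return len(self.lowpass)


def get_filter(name: str) -> WaveletFilter:
    """Look up a registered filter ('haar' or 'db2')."""
    try:
        lo = _FILTER_BANK[name]
    except KeyError:
        raise ParameterError(
            f"unknown wavelet filter {name!r}; known: {sorted(_FILTER_BANK)}"
        ) from None
    L = len(lo)
    hi = tuple((-1.0) ** i * lo[L - 1 - i] for i in range(L))
    return WaveletFilter(name, lo, hi)


def _as_filter(filt: "WaveletFilter | str") -> WaveletFilter:
    return get_filter(filt) if isinstance(filt, str) else filt


from functools import lru_cache


@lru_cache(maxsize=128)
def _analysis_matrix(n: int, lowpass: tuple, highpass: tuple) -> np.ndarray:
    """Orthogonal one-step analysis matrix for even length ``n``.

    Rows 0..n/2−1 are the decimated circular lowpass rows, rows n/2..n−1
    the highpass rows.  ``np.add.at`` accumulates taps that wrap onto the
    same sample when n is shorter than the filter support.
    """
    lo = np.asarray(lowpass)
    hi = np.asarray(highpass)
    rows = np.arange(n // 2)
    idx = (2 * rows[:, None] - np.arange(lo.size)[None, :]) % n
    W = np.zeros((n, n))
    np.add.at(W, (rows[:, None], idx), np.broadcast_to(lo, idx.shape))
    np.add.at(W, (rows[:, None] + n // 2, idx), np.broadcast_to(hi, idx.shape))
    return W


def _step_forward(x: np.ndarray, filt: WaveletFilter, axis: int):
    """Apply one analysis step along ``axis`` (length must be even)."""
    n = x.shape[axis]
    W = _analysis_matrix(n, filt.lowpass, filt.highpass)
    moved = np.moveaxis(x, axis, -1)
    y = moved @ W.T
    low = np.moveaxis(y[..., : n // 2], -1, axis)
    high = np.moveaxis(y[..., n // 2 :], -1, axis)
    return low, high


def _step_inverse(low: np.ndarray, high: np.ndarray, filt: WaveletFilter, axis: int):
    n = 2 * low.shape[axis]
    W = _analysis_matrix(n, filt.lowpass, filt.highpass)
    y = np.concatenate([np.moveaxis(low, axis, -1), np.moveaxis(high, axis, -1)], axis=-1)
    return np.moveaxis(y @ W, -1, axis)


def dwt1d_step(signal: np.ndarray, filt: "WaveletFilter | str") -> tuple[np.ndarray, np.ndarray]:
    """One analysis step on an even-length 1D signal.

    Returns (approximation, detail), each of half the input length.
    """
    filt = _as_filter(filt)
    x = np.asarray(signal, dtype=np.float64)
    if x.ndim != 1 or x.size < 2 or x.size % 2:
        raise ParameterError("signal must be 1D with even length >= 2")
    return _step_forward(x, filt, 0)


def idwt1d_step(
    approx: np.ndarray, detail: np.ndarray, filt: "WaveletFilter | str"
) -> np.ndarray:
    """Exact inverse of :func:`dwt1d_step` (transpose of the analysis matrix)."""
    filt = _as_filter(filt)
    a = np.asarray(approx, dtype=np.float64)
    d = np.asarray(detail, dtype=np.float64)
    if a.shape != d.shape or a.ndim != 1:
        raise StructureError("approx and detail must be 1D of equal length")
    return _step_inverse(a, d, filt, 0)


def _dwt1d_levels(x: np.ndarray, filt: WaveletFilter, levels: int):
    """Multilevel 1D analysis with the odd-length carry policy.

    Returns (approx, [detail_level1, ...], carries) where ``carries[j]`` is
    the number of raw samples carried at level j+1 (0 when the length was
    even).  Levels stop early once fewer than 2 samples remain.
    """
    details: list[np.ndarray] = []
    carries: list[int] = []
    cur = np.asarray(x, dtype=np.float64)
    for _ in range(levels):
        if cur.size < 2:
            break
        if cur.size % 2:
            head, tail = cur[:-1], cur[-1:]
            a, d = dwt1d_step(head, filt)
            cur = np.concatenate([a, tail])
            carries.append(1)
        else:
            a, d = dwt1d_step(cur, filt)
            cur = a
            carries.append(0)
        details.append(d)
    return cur, details, carries


def _idwt1d_levels(approx, details, carries, filt: WaveletFilter) -> np.ndarray:
    cur = np.asarray(approx, dtype=np.float64)
    for d, carry in zip(reversed(details), reversed(carries)):
        if carry:
            head, tail = cur[:-1], cur[-1:]
            cur = np.concatenate([idwt1d_step(head, d, filt), tail])
        else:
            cur = idwt1d_step(cur, d, filt)
    return cur


def dwt1d(signal: np.ndarray, filt: "WaveletFilter | str", levels: int):
    """Multilevel 1D DWT; returns (approx, details, carries)."""
    filt = _as_filter(filt)
    if levels < 1:
        raise ParameterError("levels must be >= 1")
    return _dwt1d_levels(signal, filt, levels)


def idwt1d(approx, details, carries, filt: "WaveletFilter | str") -> np.ndarray:
    """Inverse of :func:`dwt1d`."""
    return _idwt1d_levels(approx, details, carries, _as_filter(filt))


@dataclass
class WaveletPyramid:
    """Nonstandard 2D multilevel decomposition.

    ``details[j]`` holds the (LH, HL, HH) subbands of level j+1 (level 1 is
    the finest); ``approx`` is the final LL band.  For even dyadic-friendly
    shapes the total coefficient count equals the pixel count.
    """

    filter_name: str
    shape: tuple[int, int]
    pixel_size_mm: float
    intensity_max: float
    approx: np.ndarray
    details: list[tuple[np.ndarray, np.ndarray, np.ndarray]]
    row_carries: list[int] = field(default_factory=list)
    col_carries: list[int] = field(default_factory=list)

    @property
    def levels(self) -> int:
        return len(self.details)

    def coefficient_count(self) -> int:
        n = self.approx.size
        for bands in self.details:
            n += sum(b.size for b in bands)
        return n

    def energy(self) -> float:
        e = float(np.sum(self.approx**2))
        for bands in self.details:
            e += sum(float(np.sum(b * b)) for b in bands)
        return e


def max_levels(shape: tuple[int, int]) -> int:
    """Upper bound on decomposition depth for an M×N image."""
    return int(math.floor(math.log2(min(shape))))


def _split_axis(x: np.ndarray, filt: WaveletFilter, axis: int):
    """(low, high, carry) along ``axis`` with the odd-length carry policy."""
    n = x.shape[axis]
    if n % 2:
        head = np.take(x, np.arange(n - 1), axis=axis)
        tail = np.take(x, [n - 1], axis=axis)
        low, high = _step_forward(head, filt, axis)
        return np.concatenate([low, tail], axis=axis), high, 1
    low, high = _step_forward(x, filt, axis)
    return low, high, 0


def _merge_axis(low, high, carry, filt: WaveletFilter, axis: int):
    if carry:
        n_half = low.shape[axis] - 1
        head = np.take(low, np.arange(n_half), axis=axis)
        tail = np.take(low, [n_half], axis=axis)
        return np.concatenate([_step_inverse(head, high, filt, axis), tail], axis=axis)
    return _step_inverse(low, high, filt, axis)


def dwt2d(img: Image2D, filt: "WaveletFilter | str", levels: int) -> WaveletPyramid:
    """Nonstandard (Mallat) 2D DWT: rows then columns, recursing on LL."""
    filt = _as_filter(filt)
    if levels < 1:
        raise ParameterError("levels must be >= 1")
    if levels > max_levels(img.shape):
        raise ParameterError(
            f"levels={levels} exceeds bound {max_levels(img.shape)} for {img.shape}"
        )
    cur = img.pixels
    details = []
    row_carries: list[int] = []
    col_carries: list[int] = []
    for _ in range(levels):
        if min(cur.shape) < 2:
            raise ParameterError("image exhausted before requested level count")
        # column pass (filter along axis 1): produces row-direction L/H
        low_c, high_c, cc = _split_axis(cur, filt, axis=1)
        # row pass (filter along axis 0)
        ll, lh, rc1 = _split_axis(low_c, filt, axis=0)
        hl, hh, rc2 = _split_axis(high_c, filt, axis=0)
        assert rc1 == rc2
        details.append((lh, hl, hh))
        row_carries.append(rc1)
        col_carries.append(cc)
        cur = ll
    return WaveletPyramid(
        filter_name=filt.name,
        shape=img.shape,
        pixel_size_mm=img.pixel_size_mm,
        intensity_max=img.intensity_max,
        approx=cur,
        details=details,
        row_carries=row_carries,
        col_carries=col_carries,
    )


def idwt2d(pyr: WaveletPyramid) -> Image2D:
    """Exact inverse of :func:`dwt2d`."""
    filt = get_filter(pyr.filter_name)
    cur = pyr.approx
    for (lh, hl, hh), rc, cc in zip(
        reversed(pyr.details), reversed(pyr.row_carries), reversed(pyr.col_carries)
    ):
        if cur.shape != lh.shape and (cur.shape[0] - rc, cur.shape[1]) != (
            lh.shape[0],
            lh.shape[1],
        ):
            raise StructureError("inconsistent subband shapes in pyramid")
        low_c = _merge_axis(cur, lh, rc, filt, axis=0)
        high_c = _merge_axis(hl, hh, rc, filt, axis=0)
        cur = _merge_axis(low_c, high_c, cc, filt, axis=1)
    if cur.shape != pyr.shape:
        raise StructureError("pyramid does not reconstruct the recorded shape")
    return Image2D(cur, pyr.pixel_size_mm, pyr.intensity_max)


def threshold_pyramid(pyr: WaveletPyramid, t: float) -> WaveletPyramid:
    """Hard-threshold detail subbands (|c| < t → 0); LL is left untouched.

    Sparing LL keeps the DC / smooth content that the segmentation stage
    thresholds on; zeroing it would wipe the foreground itself.
    """
    if t < 0:
        raise ParameterError("threshold must be non-negative")
    details = []
    for bands in pyr.details:
        details.append(tuple(np.where(np.abs(b) < t, 0.0, b) for b in bands))
    return WaveletPyramid(
        filter_name=pyr.filter_name,
        shape=pyr.shape,
        pixel_size_mm=pyr.pixel_size_mm,
        intensity_max=pyr.intensity_max,
        approx=pyr.approx.copy(),
        details=details,
        row_carries=list(pyr.row_carries),
        col_carries=list(pyr.col_carries),
    )


def denoise_wavelet(
    img: Image2D, filt: "WaveletFilter | str", levels: int, t: float
) -> Image2D:
    """dwt2d → hard threshold of detail bands → idwt2d."""
    return idwt2d(threshold_pyramid(dwt2d(img, filt, levels), t))


# ---------------------------------------------------------------------------
# serialization: JSON manifest plus one .npy file per subband


def save_pyramid(pyr: WaveletPyramid, directory: str | os.PathLike) -> None:
    directory = os.fspath(directory)
    os.makedirs(directory, exist_ok=True)
    manifest = {
        "kind": "wavelet-pyramid",
        "filter": pyr.filter_name,
        "levels": pyr.levels,
        "shape": list(pyr.shape),
        "pixel_size_mm": pyr.pixel_size_mm,
        "intensity_max": pyr.intensity_max,
        "row_carries": pyr.row_carries,
        "col_carries": pyr.col_carries,
        "convention": "periodic extension; a[n]=sum l(i) x(2n-i); bands LL,LH,HL,HH",
    }
    with open(os.path.join(directory, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2)
    np.save(os.path.join(directory, "LL.npy"), pyr.approx)
    for j, (lh, hl, hh) in enumerate(pyr.details, start=1):
        np.save(os.path.join(directory, f"L{j}_LH.npy"), lh)
        np.save(os.path.join(directory, f"L{j}_HL.npy"), hl)
        np.save(os.path.join(directory, f"L{j}_HH.npy"), hh)


def load_pyramid(directory: str | os.PathLike) -> WaveletPyramid:
    directory = os.fspath(directory)
    with open(os.path.join(directory, "manifest.json")) as fh:
        manifest = json.load(fh)
    if manifest.get("kind") != "wavelet-pyramid":
        raise StructureError("not a wavelet pyramid container")
    details = []
    for j in range(1, manifest["levels"] + 1):
        details.append(
            tuple(
                np.load(os.path.join(directory, f"L{j}_{band}.npy"))
                for band in ("LH", "HL", "HH")
            )
        )
    return WaveletPyramid(
        filter_name=manifest["filter"],
        shape=tuple(manifest["shape"]),
        pixel_size_mm=manifest["pixel_size_mm"],
        intensity_max=manifest["intensity_max"],
        approx=np.load(os.path.join(directory, "LL.npy")),
        details=details,
        row_carries=list(manifest["row_carries"]),
        col_carries=list(manifest["col_carries"]),
    )
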