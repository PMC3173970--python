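"""Finite Radon and finite ridgelet transforms on prime grids.

The finite Radon transform (FRAT) of a p×p block (p prime) sums the block
along the lines of the finite geometry Z_p²:

    r_k[l] = (1/√p) Σ_{(i,j) ∈ L(k,l)} f(i, j)

with, for slopes k = 0..p−1, L(k, l) = {(i, j) : j = k·i + l (mod p)}, and
for k = p the vertical lines L(p, l) = {(l, j) : j ∈ Z_p}.  Each of the
p+1 directions partitions the grid, so every projection row sums to the
same total (the partition property), and any two distinct points share
exactly one line — which yields the exact back-projection inverse

    f(i, j) = ( √p · Σ_k r_k[l_k(i,j)] − S ) / p,   S = total block sum.

The 1/√p normalisation makes each line sum carry unit white-noise gain;
the 1/p variant seen in some write-ups only changes a global constant,
recorded in the container manifest.

The finite ridgelet transform (FRIT) applies a multilevel 1D orthonormal
wavelet transform to each projection row, mapping line singularities to
point singularities.  Projections have odd (prime) length, handled by the
wavelet module's carry policy, so the per-direction coefficient count
stays exactly p and the chain is an isometry up to that policy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from .errors import ParameterError, ShapeMismatchError, StructureError
from .image import Image2D
from .wavelet import WaveletFilter, _as_filter, dwt1d, idwt1d

__all__ = [
    "RadonProjections",
    "RidgeletCoefficients",
    "BlockTiling",
    "is_prime",
    "frat",
    "ifrat",
    "frit",
    "ifrit",
    "threshold_frit",
    "ridgelet_process",
    "line_points",
]

FRAT_NORMALIZATION = "1/sqrt(p)"


def is_prime(n: int) -> bool:
    if n < 2:
        return False
    return all(n % d for d in range(2, int(math.isqrt(n)) + 1))


def line_points(p: int, k: int, l: int) -> list[tuple[int, int]]:
    """The points of line L(k, l) on Z_p², by direct modular arithmetic.

    Kept deliberately elementary so it can serve as an independent check of
    the vectorised transform.
    """
    if k < p:
        return [(i, (k * i + l) % p) for i in range(p)]
    return [(l, j) for j in range(p)]


@lru_cache(maxsize=32)
def _line_index_lut(p: int) -> np.ndarray:
    """(p+1, p, p) array of flat indices: lut[k, l] lists line L(k, l)."""
    lut = np.empty((p + 1, p, p), dtype=np.intp)
    i = np.arange(p)
    for k in range(p):
        for l in range(p):
            lut[k, l] = i * p + (k * i + l) % p
    for l in range(p):
        lut[p, l] = l * p + i
    return lut


@dataclass
class RadonProjections:
    """FRAT output: one projection row per direction, plus the block mean.

    ``values[k, l] = r_k[l]`` for directions k = 0..p.  The mean is stored
    separately so downstream thresholding can always restore the DC level.
    """

    p: int
    values: np.ndarray  # (p+1, p)
    mean_offset: float

    def __post_init__(self) -> None:
        if self.values.shape != (self.p + 1, self.p):
            raise StructureError("projection array must be (p+1) x p")

    def direction_sums(self) -> np.ndarray:
        """Σ_l r_k[l] per direction; identical across k for valid input."""
        return self.values.sum(axis=1)


@dataclass
class RidgeletCoefficients:
    """Per-direction multilevel 1D wavelet decomposition of the projections."""

    p: int
    filter_name: str
    levels: int
    mean_offset: float
    #: per direction: (approx, [details...], [carries...])
    rows: list[tuple[np.ndarray, list[np.ndarray], list[int]]] = field(
        default_factory=list
    )

    def coefficient_count(self) -> int:
        n = 0
        for approx, details, _ in self.rows:
            n += approx.size + sum(d.size for d in details)
        return n


@dataclass(frozen=True)
class BlockTiling:
    """Non-overlapping p×p tiling of a (padded) image."""

    p: int
    image_shape: tuple[int, int]

    @property
    def padded_shape(self) -> tuple[int, int]:
        m, n = self.image_shape
        return (-(-m // self.p) * self.p, -(-n // self.p) * self.p)

    @property
    def origins(self) -> list[tuple[int, int]]:
        pm, pn = self.padded_shape
        return [(r, c) for r in range(0, pm, self.p) for c in range(0, pn, self.p)]


def _check_block(block: np.ndarray, p: int | None = None) -> tuple[np.ndarray, int]:
    block = np.asarray(block, dtype=np.float64)
    if block.ndim != 2 or block.shape[0] != block.shape[1]:
        raise ShapeMismatchError("block must be square")
    q = block.shape[0]
    if p is not None and q != p:
        raise ShapeMismatchError(f"block is {q}x{q}, expected {p}x{p}")
    if not is_prime(q):
        raise ParameterError(f"block size {q} is not prime")
    return block, q


def frat(block: np.ndarray) -> RadonProjections:
    """Finite Radon transform of a p×p block (p prime)."""
    block, p = _check_block(block)
    flat = block.ravel()
    values = flat[_line_index_lut(p)].sum(axis=2) / math.sqrt(p)
    return RadonProjections(p=p, values=values, mean_offset=float(block.mean()))


def ifrat(proj: RadonProjections) -> np.ndarray:
    """Exact inverse FRAT by back-projection.

    Sums, over the p+1 lines through each pixel, the line values; every
    other pixel contributes once through exactly one shared line, giving
    ``f = (√p·backprojection − S)/p``.
    """
    p = proj.p
    lut = _line_index_lut(p)
    acc = np.bincount(
        lut.ravel(),
        weights=np.repeat(proj.values.ravel(), p),
        minlength=p * p,
    )
    total = math.sqrt(p) * float(proj.values[0].sum())
    f = (math.sqrt(p) * acc - total) / p
    return f.reshape(p, p)


def frit(
    block: np.ndarray, filt: "WaveletFilter | str" = "haar", levels: int = 3
) -> RidgeletCoefficients:
    """Finite ridgelet transform: FRAT then a 1D DWT along each direction.

    ``levels`` is a request; the wavelet stage stops early if a projection
    row becomes too short (the effective depth is capped at floor(log2 p)).
    """
    filt = _as_filter(filt)
    proj = frat(block)
    levels = max(1, min(levels, int(math.floor(math.log2(proj.p)))))
    # every projection row has the same mean (the partition property), so
    # the DC level is removed once here and restored by ifrit; a constant
    # block therefore yields identically zero wavelet coefficients and no
    # threshold can shift the block's intensity level
    dc = proj.mean_offset * math.sqrt(proj.p)
    rows = []
    for k in range(proj.p + 1):
        approx, details, carries = dwt1d(proj.values[k] - dc, filt, levels)
        rows.append((approx, details, carries))
    return RidgeletCoefficients(
        p=proj.p,
        filter_name=filt.name,
        levels=levels,
        mean_offset=proj.mean_offset,
        rows=rows,
    )


def ifrit(coeffs: RidgeletCoefficients) -> np.ndarray:
    """Inverse FRIT: per-direction inverse 1D DWT, then inverse FRAT."""
    p = coeffs.p
    if len(coeffs.rows) != p + 1:
        raise StructureError("coefficient container has wrong direction count")
    values = np.empty((p + 1, p))
    dc = coeffs.mean_offset * math.sqrt(p)
    for k, (approx, details, carries) in enumerate(coeffs.rows):
        row = idwt1d(approx, details, carries, coeffs.filter_name)
        if row.size != p:
            raise StructureError("direction row does not reconstruct to length p")
        values[k] = row + dc
    return ifrat(RadonProjections(p=p, values=values, mean_offset=coeffs.mean_offset))


def threshold_frit(coeffs: RidgeletCoefficients, t: float) -> RidgeletCoefficients:
    """Hard-threshold the wavelet *detail* coefficients of every direction.

    Approximation coefficients (which hold each projection's mean, hence
    the block DC) are never touched.
    """
    if t < 0:
        raise ParameterError("threshold must be non-negative")
    rows = []
    for approx, details, carries in coeffs.rows:
        new_details = [np.where(np.abs(d) < t, 0.0, d) for d in details]
        rows.append((approx.copy(), new_details, list(carries)))
    return RidgeletCoefficients(
        p=coeffs.p,
        filter_name=coeffs.filter_name,
        levels=coeffs.levels,
        mean_offset=coeffs.mean_offset,
        rows=rows,
    )


def ridgelet_process(
    img: Image2D,
    p: int,
    filt: "WaveletFilter | str" = "haar",
    t: float = 0.0,
    levels: int = 3,
) -> Image2D:
    """Blockwise FRIT → hard threshold → inverse FRIT over the whole image.

    The image is padded to multiples of p by symmetric edge replication
    (zero padding would plant artificial edges on every block border),
    processed in non-overlapping p×p blocks, and cropped back.  With
    ``t = 0`` the chain is an exact round trip.
    """
    if not is_prime(p) or p < 3:
        raise ParameterError(f"block size must be a prime >= 3, got {p}")
    if t < 0:
        raise ParameterError("threshold must be non-negative")
    filt = _as_filter(filt)
    tiling = BlockTiling(p, img.shape)
    m, n = img.shape
    pm, pn = tiling.padded_shape
    padded = np.pad(img.pixels, ((0, pm - m), (0, pn - n)), mode="symmetric")
    out = np.empty_like(padded)
    for r, c in tiling.origins:
        block = padded[r : r + p, c : c + p]
        out[r : r + p, c : c + p] = ifrit(threshold_frit(frit(block, filt, levels), t))
    return img.with_pixels(out[:m, :n])
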