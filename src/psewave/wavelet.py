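"""Multilevel 2-D (and 1-D) discrete wavelet transform denoising.

The denoiser follows the classical wavelet threshold-denoising recipe:
decompose the input into an approximation subband plus, per level,
horizontal/vertical/diagonal detail subbands; shrink every detail
coefficient with a soft (or hard) threshold; reconstruct.  The default
threshold is the Donoho–Johnstone universal threshold

    t = σ̂ · sqrt(2 ln m),   σ̂ = median(|finest diagonal details|) / 0.6745

with m the total number of detail coefficients — the standard "default
threshold" of wavelet toolboxes.  Approximation coefficients are never
thresholded.

Boundary handling uses symmetric extension, which permits decomposition
levels beyond the classical maximum for small inputs (a warning is issued
by the transform); feature-matrix denoising at level 5 on ~22-column blocks
relies on this.

Transforms are computed by PyWavelets; this module adds the pyramid
container, the thresholding policy, and the vector↔2-D reshape helper used
to denoise a single feature vector with the 2-D transform.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pywt

#: Wavelet families supported for denoising.
SUPPORTED_FAMILIES = (
    "haar", "db2", "db4", "db6", "sym2", "sym4", "sym6",
    "coif1", "coif3", "bior2.2", "bior2.4",
)

_MODE = "symmetric"


@dataclass(frozen=True)
class WaveletSpec:
    """Wavelet family, decomposition level and thresholding policy."""

    family: str = "db4"
    level: int = 5
    threshold_rule: str = "default"  # "default" | "given"
    threshold_value: float | None = None
    threshold_fn: str = "soft"  # "soft" | "hard"

    def __post_init__(self) -> None:
        if self.family not in SUPPORTED_FAMILIES:
            raise ValueError(
                f"unsupported wavelet family {self.family!r}; supported: {SUPPORTED_FAMILIES}"
            )
        if self.level < 1:
            raise ValueError("decomposition level must be >= 1")
        if self.threshold_rule not in ("default", "given"):
            raise ValueError("threshold_rule must be 'default' or 'given'")
        if self.threshold_rule == "given":
            if self.threshold_value is None or self.threshold_value < 0:
                raise ValueError("a given threshold must be a nonnegative number")
        if self.threshold_fn not in ("soft", "hard"):
            raise ValueError("threshold_fn must be 'soft' or 'hard'")


@dataclass
class CoefficientPyramid:
    """Multilevel 2-D DWT coefficients.

    ``details[k]`` holds the (horizontal, vertical, diagonal) blocks of
    level k+1 counting from the coarsest scale, i.e. ``details[-1]`` is the
    finest level — the ordering PyWavelets uses.  ``shape`` is the original
    array shape, needed to crop the reconstruction.
    """

    approx: np.ndarray
    details: list[tuple[np.ndarray, np.ndarray, np.ndarray]]
    family: str
    shape: tuple[int, int]

    @property
    def level(self) -> int:
        return len(self.details)

    @property
    def finest_diagonal(self) -> np.ndarray:
        return self.details[-1][2]

    def detail_count(self) -> int:
        return sum(h.size + v.size + d.size for h, v, d in self.details)

    def detail_energy(self) -> float:
        return float(sum((h ** 2).sum() + (v ** 2).sum() + (d ** 2).sum()
                         for h, v, d in self.details))


def decompose2d(data: np.ndarray, spec: WaveletSpec) -> CoefficientPyramid:
    """Multilevel 2-D decomposition with symmetric boundary extension.

    PyWavelets warns (and proceeds) when ``spec.level`` exceeds the
    classical maximum for the array size; the extension makes the transform
    and its inverse exact regardless.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2 or data.shape[0] < 2 or data.shape[1] < 2:
        raise ValueError(f"input must be a 2-D array with at least 2 rows and 2 columns, got shape {data.shape}")
    coeffs = pywt.wavedec2(data, spec.family, mode=_MODE, level=spec.level)
    return CoefficientPyramid(
        approx=coeffs[0],
        details=[tuple(np.asarray(b) for b in lvl) for lvl in coeffs[1:]],
        family=spec.family,
        shape=data.shape,
    )


def reconstruct2d(pyramid: CoefficientPyramid) -> np.ndarray:
    """Inverse multilevel transform, cropped to the original shape."""
    if pyramid.approx is None or any(len(lvl) != 3 for lvl in pyramid.details):
        raise ValueError("corrupted pyramid: missing coefficient block")
    coeffs = [pyramid.approx] + [tuple(lvl) for lvl in pyramid.details]
    rec = pywt.waverec2(coeffs, pyramid.family, mode=_MODE)
    rows, cols = pyramid.shape
    return rec[:rows, :cols]


def soft_threshold(x, t: float):
    """sign(x)·max(|x|−t, 0), elementwise; identity at t=0."""
    if t < 0:
        raise ValueError("threshold must be nonnegative")
    x = np.asarray(x, dtype=float)
    out = np.sign(x) * np.maximum(np.abs(x) - t, 0.0)
    return out if out.ndim else float(out)


def hard_threshold(x, t: float):
    """x·1{|x| > t}, elementwise."""
    if t < 0:
        raise ValueError("threshold must be nonnegative")
    x = np.asarray(x, dtype=float)
    out = np.where(np.abs(x) > t, x, 0.0)
    return out if out.ndim else float(out)


_THRESHOLD_FNS = {"soft": soft_threshold, "hard": hard_threshold}


def default_threshold(detail_blocks: Sequence[np.ndarray] | CoefficientPyramid) -> float:
    """Universal threshold σ̂·sqrt(2 ln m) from the finest diagonal details.

    Accepts either a pyramid or an explicit sequence of detail blocks whose
    *last* element is the finest diagonal block (the noise-scale estimator
    uses only that block; m counts every detail coefficient).
    """
    if isinstance(detail_blocks, CoefficientPyramid):
        finest = detail_blocks.finest_diagonal
        m = detail_blocks.detail_count()
    else:
        blocks = [np.asarray(b) for b in detail_blocks]
        if not blocks:
            raise ValueError("no detail blocks")
        finest = blocks[-1]
        m = sum(b.size for b in blocks)
    if finest.size == 0 or m == 0:
        raise ValueError("empty detail blocks")
    sigma = float(np.median(np.abs(finest))) / 0.6745
    return sigma * np.sqrt(2.0 * np.log(m)) if m > 1 else 0.0


def threshold_pyramid(pyramid: CoefficientPyramid, t: float,
                      fn: str = "soft") -> CoefficientPyramid:
    """Apply the threshold function to every detail block; the approximation
    block is copied untouched."""
    thr = _THRESHOLD_FNS[fn]
    new_details = [tuple(thr(b, t) for b in lvl) for lvl in pyramid.details]
    return CoefficientPyramid(approx=pyramid.approx.copy(), details=new_details,
                              family=pyramid.family, shape=pyramid.shape)


def resolve_threshold(pyramid: CoefficientPyramid, spec: WaveletSpec) -> float:
    if spec.threshold_rule == "given":
        return float(spec.threshold_value)
    return default_threshold(pyramid)


def denoise2d(data: np.ndarray, spec: WaveletSpec) -> np.ndarray:
    """Decompose → threshold detail subbands → reconstruct.  Output shape
    equals input shape."""
    pyramid = decompose2d(data, spec)
    t = resolve_threshold(pyramid, spec)
    return reconstruct2d(threshold_pyramid(pyramid, t, spec.threshold_fn))


def denoise1d(data: np.ndarray, spec: WaveletSpec) -> np.ndarray:
    """1-D analogue of :func:`denoise2d` (one detail block per level)."""
    data = np.asarray(data, dtype=float)
    if data.ndim != 1 or data.size < 2:
        raise ValueError("input must be a 1-D array with at least 2 samples")
    coeffs = pywt.wavedec(data, spec.family, mode=_MODE, level=spec.level)
    details = coeffs[1:]
    if spec.threshold_rule == "given":
        t = float(spec.threshold_value)
    else:
        t = default_threshold(details)
    thr = _THRESHOLD_FNS[spec.threshold_fn]
    new_coeffs = [coeffs[0]] + [thr(d, t) for d in details]
    return pywt.waverec(new_coeffs, spec.family, mode=_MODE)[: data.size]


# --- vector <-> 2-D reshape -------------------------------------------------

def _grid_shape(n: int) -> tuple[int, int, int]:
    """Smallest padded length n' >= n with a factorization rows×cols,
    2 <= rows <= cols <= 2·rows; (rows, cols) is the most-square pair."""
    if n < 4:
        raise ValueError("need at least 4 values to form a 2-D grid")
    m = n
    while True:
        rows = max((d for d in range(2, int(np.sqrt(m)) + 1) if m % d == 0), default=0)
        if rows:
            cols = m // rows
            if cols <= 2 * rows:
                return rows, cols, m
        m += 1


def vector_as_2d(v: np.ndarray) -> tuple[np.ndarray, int]:
    """Row-major reshape of a vector to a near-square 2-D array.

    Lengths without an acceptable factorization are padded at the tail by
    symmetric reflection (e.g. 22 values → 4×6 with 2 pad cells).  Returns
    the array and the original length, which :func:`flatten_2d` uses to
    strip the padding.
    """
    v = np.asarray(v, dtype=float).ravel()
    n = v.size
    rows, cols, m = _grid_shape(n)
    if m > n:
        v = np.pad(v, (0, m - n), mode="symmetric")
    return v.reshape(rows, cols), n


def flatten_2d(arr: np.ndarray, n: int) -> np.ndarray:
    """Inverse of :func:`vector_as_2d`: row-major flatten, padding removed."""
    return np.asarray(arr, dtype=float).ravel()[:n]


def denoise_vector_via_2d(v: np.ndarray, spec: WaveletSpec) -> np.ndarray:
    """Denoise a single 1-D feature vector through the 2-D pipeline by
    reshaping it to a near-square grid (the single-protein demonstration
    path)."""
    v = np.asarray(v, dtype=float).ravel()
    arr, n = vector_as_2d(v)
    return flatten_2d(denoise2d(arr, spec), n)
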