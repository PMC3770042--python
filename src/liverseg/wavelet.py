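"""Multi-level 2-D wavelet denoising.

Two classic strategies are provided on top of a standard separable wavelet
pyramid: zeroing the high-frequency (detail) bands outright, and soft
thresholding every detail coefficient

    W -> sgn(W) * (|W| - lambda)   if |W| >= lambda,   else 0,

while the lowest-frequency approximation band is never touched (noise is
assumed to live in the high frequencies).  The default basis is Haar with
symmetric (half-sample) boundary extension; any PyWavelets basis name may
be used instead.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pywt

__all__ = [
    "WaveletCoeffs",
    "decompose",
    "reconstruct",
    "soft_threshold",
    "zero_high_freq",
    "universal_threshold",
    "denoise",
]


@dataclass(frozen=True)
class WaveletCoeffs:
    """A J-level 2-D wavelet pyramid.

    ``details[0]`` holds the finest level (j=1) ``(horizontal, vertical,
    diagonal)`` bands, ``details[-1]`` the coarsest; ``approx`` is the
    level-J low-frequency band.  ``shape`` remembers the original image
    shape so reconstruction can crop boundary padding.
    """

    approx: np.ndarray
    details: tuple[tuple[np.ndarray, np.ndarray, np.ndarray], ...]
    levels: int
    basis_name: str
    boundary_mode: str
    shape: tuple[int, int]


def decompose(
    image: np.ndarray,
    levels: int = 3,
    wavelet: str = "haar",
    mode: str = "symmetric",
) -> WaveletCoeffs:
    """Build the J-level coefficient pyramid of ``image``."""
    arr = np.asarray(image, dtype=np.float64)
    if arr.ndim != 2 or arr.size == 0:
        raise ValueError("image must be a non-empty 2-D array")
    if levels < 1:
        raise ValueError("levels must be >= 1")
    if min(arr.shape) < 2**levels:
        raise ValueError(
            f"image of shape {arr.shape} is too small for {levels} levels"
        )
    coeffs = pywt.wavedec2(arr, wavelet=wavelet, mode=mode, level=levels)
    approx = coeffs[0]
    # pywt orders detail triples coarsest-first; store finest-first (j=1..J).
    details = tuple(tuple(np.asarray(b) for b in trip) for trip in coeffs[:0:-1])
    return WaveletCoeffs(approx, details, levels, wavelet, mode, arr.shape)


def reconstruct(coeffs: WaveletCoeffs) -> np.ndarray:
    """Inverse transform; boundary padding is cropped to the original shape."""
    _check_structure(coeffs)
    pywt_coeffs = [coeffs.approx] + [tuple(t) for t in coeffs.details[::-1]]
    out = pywt.waverec2(pywt_coeffs, wavelet=coeffs.basis_name, mode=coeffs.boundary_mode)
    h, w = coeffs.shape
    return np.asarray(out, dtype=np.float64)[:h, :w]


def _check_structure(coeffs: WaveletCoeffs) -> None:
    if len(coeffs.details) != coeffs.levels:
        raise ValueError("pyramid does not hold exactly `levels` detail triples")
    for trip in coeffs.details:
        if len(trip) != 3:
            raise ValueError("each detail level must hold (H, V, D) bands")
        shapes = {np.asarray(b).shape for b in trip}
        if len(shapes) != 1:
            raise ValueError("inconsistent band shapes within a detail level")


def soft_threshold(coeffs: WaveletCoeffs, lam: float) -> WaveletCoeffs:
    """Shrink every detail coefficient by ``lam``; approximation untouched."""
    if lam < 0:
        raise ValueError("threshold must be non-negative")
    details = tuple(
        tuple(np.sign(b) * np.maximum(np.abs(b) - lam, 0.0) for b in trip)
        for trip in coeffs.details
    )
    return replace(coeffs, details=details)


def zero_high_freq(
    coeffs: WaveletCoeffs, levels_to_zero: "list[int] | None" = None
) -> WaveletCoeffs:
    """Zero the detail bands of the selected levels (1 = finest, default all)."""
    if levels_to_zero is None:
        levels_to_zero = list(range(1, coeffs.levels + 1))
    chosen = set(levels_to_zero)
    if not chosen <= set(range(1, coeffs.levels + 1)):
        raise ValueError(f"levels must be within 1..{coeffs.levels}")
    details = tuple(
        tuple(np.zeros_like(b) if (j + 1) in chosen else b for b in trip)
        for j, trip in enumerate(coeffs.details)
    )
    return replace(coeffs, details=details)


def universal_threshold(coeffs: WaveletCoeffs) -> float:
    """Donoho universal threshold sigma_hat * sqrt(2 log N).

    The noise scale is the median absolute deviation of the finest diagonal
    band divided by 0.6745.
    """
    diag = coeffs.details[0][2]
    sigma = np.median(np.abs(diag)) / 0.6745
    n = int(np.prod(coeffs.shape))
    return float(sigma * np.sqrt(2.0 * np.log(max(n, 2))))


def denoise(
    image: np.ndarray,
    method: str = "soft",
    lam: "float | None" = None,
    levels: int = 3,
    wavelet: str = "haar",
    mode: str = "symmetric",
) -> np.ndarray:
    """Decompose, suppress high frequencies, reconstruct, clip to [0, 255].

    ``method="zero"`` zeroes all detail bands; ``method="soft"`` applies
    soft thresholding with ``lam`` (pass ``lam=None`` to use the universal
    threshold estimate).
    """
    coeffs = decompose(image, levels=levels, wavelet=wavelet, mode=mode)
    if method == "zero":
        coeffs = zero_high_freq(coeffs)
    elif method == "soft":
        if lam is None:
            lam = universal_threshold(coeffs)
        coeffs = soft_threshold(coeffs, lam)
    else:
        raise ValueError(f"unknown denoise method {method!r}")
    return np.clip(reconstruct(coeffs), 0.0, 255.0)
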