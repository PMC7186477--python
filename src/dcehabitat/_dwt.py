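"""Minimal 2-D multilevel discrete wavelet analysis (periodic extension).

Only the decomposition direction is needed for texture scalars, so this
implements analysis filter banks for the three wavelets used by the
feature catalogue. Subband sizes halve exactly at every level (inputs are
padded to a multiple of 2^levels by the caller).
"""
from __future__ import annotations

import numpy as np

_SQRT2 = np.sqrt(2.0)
_SQRT3 = np.sqrt(3.0)

# Orthogonal scaling (low-pass) filters; each sums to sqrt(2).
DEC_LO = {
    "haar": np.array([1.0, 1.0]) / _SQRT2,
    "deubechies2": np.array(
        [1.0 - _SQRT3, 3.0 - _SQRT3, 3.0 + _SQRT3, 1.0 + _SQRT3]
    )
    / (4.0 * _SQRT2),
    "symlet4": np.array(
        [
            -0.07576571478927333,
            -0.02963552764599851,
            0.49761866763201545,
            0.8037387518059161,
            0.29785779560527736,
            -0.09921954357684722,
            -0.012603967262037833,
            0.0322231006040427,
        ]
    ),
}

WAVELET_NAMES = tuple(DEC_LO)


def dec_hi(lo: np.ndarray) -> np.ndarray:
    """Quadrature-mirror high-pass filter: hi[k] = (-1)^k lo[L-1-k]."""
    signs = (-1.0) ** np.arange(lo.size)
    return signs * lo[::-1]


def _analysis_axis(x: np.ndarray, filt: np.ndarray, axis: int) -> np.ndarray:
    """Periodic convolution + dyadic downsampling along one axis."""
    n = x.shape[axis]
    if n % 2:
        raise ValueError("axis length must be even for dyadic analysis")
    xt = np.moveaxis(x, axis, 0)
    idx = (2 * np.arange(n // 2)[:, None] + np.arange(filt.size)[None, :]) % n
    taps = xt[idx]  # (n/2, L, ...)
    shape = (1, filt.size) + (1,) * (taps.ndim - 2)
    out = (taps * filt.reshape(shape)).sum(axis=1)
    return np.moveaxis(out, 0, axis)


def dwt2(a: np.ndarray, wavelet: str) -> dict[str, np.ndarray]:
    """One analysis level. Keys: L (approx), HH (rows high-pass,
    horizontal-edge detail), HV (columns high-pass, vertical-stripe
    detail), HD (diagonal detail)."""
    lo = DEC_LO[wavelet]
    hi = dec_hi(lo)
    low_rows = _analysis_axis(a, lo, 0)
    high_rows = _analysis_axis(a, hi, 0)
    return {
        "L": _analysis_axis(low_rows, lo, 1),
        "HV": _analysis_axis(low_rows, hi, 1),
        "HH": _analysis_axis(high_rows, lo, 1),
        "HD": _analysis_axis(high_rows, hi, 1),
    }
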