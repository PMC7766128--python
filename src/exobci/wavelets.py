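"""Minimal stationary (undecimated) wavelet analysis with bior1.5 filters.

Only the decomposition side is needed here: detail coefficients at dyadic
scales, computed with the a-trous scheme (filters upsampled by 2**level,
no downsampling), which keeps coefficients time-aligned with the input.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

# Biorthogonal 1.5 decomposition filters (10 taps).
BIOR1_5_DEC_LO = np.array([
    0.016572815184059706, -0.016572815184059706,
    -0.12153397801643785, 0.12153397801643785,
    0.7071067811865476, 0.7071067811865476,
    0.12153397801643785, -0.12153397801643785,
    -0.016572815184059706, 0.016572815184059706,
])
BIOR1_5_DEC_HI = np.array([
    0.0, 0.0, 0.0, 0.0,
    -0.7071067811865476, 0.7071067811865476,
    0.0, 0.0, 0.0, 0.0,
])
BIOR1_5_REC_HI = np.array([
    0.016572815184059706, 0.016572815184059706,
    -0.12153397801643785, -0.12153397801643785,
    0.7071067811865476, -0.7071067811865476,
    0.12153397801643785, 0.12153397801643785,
    -0.016572815184059706, -0.016572815184059706,
])


def _upsample(filt: np.ndarray, level: int) -> np.ndarray:
    """Insert 2**level - 1 zeros between taps (a-trous)."""
    if level == 0:
        return filt
    step = 2 ** level
    out = np.zeros((filt.size - 1) * step + 1)
    out[::step] = filt
    return out


def _convolve_same(x: np.ndarray, filt: np.ndarray) -> np.ndarray:
    """Zero-phase 'same' correlation with reflective boundary handling."""
    return ndimage.correlate1d(x, filt, mode="reflect")


def swt_details(x: np.ndarray, max_level: int,
                dec_lo: np.ndarray = BIOR1_5_DEC_LO,
                dec_hi: np.ndarray = BIOR1_5_DEC_HI) -> list:
    """Undecimated detail coefficients d_1..d_max_level of a 1-D signal.

    Level j detail covers roughly [fs / 2**(j+1), fs / 2**j] Hz.
    """
    x = np.asarray(x, float)
    approx = x
    details = []
    for level in range(max_level):
        lo = _upsample(dec_lo, level)
        hi = _upsample(dec_hi, level)
        details.append(_convolve_same(approx, hi))
        approx = _convolve_same(approx, lo)
    return details


def detail_levels_for_band(fs: float, low_hz: float, high_hz: float) -> list:
    """Dyadic levels whose pseudo-band [fs/2^(j+1), fs/2^j] lies inside
    [low_hz, high_hz]."""
    levels = []
    j = 1
    while fs / 2 ** (j + 1) >= low_hz * 0.95:
        band_lo, band_hi = fs / 2 ** (j + 1), fs / 2 ** j
        if band_lo >= low_hz * 0.95 and band_hi <= high_hz * 1.05:
            levels.append(j)
        j += 1
    return levels


def band_detail_sum(x: np.ndarray, fs: float, low_hz: float, high_hz: float) -> np.ndarray:
    """Sum of undecimated bior1.5 detail coefficients over the levels whose
    pseudo-frequencies fall inside [low_hz, high_hz]."""
    levels = detail_levels_for_band(fs, low_hz, high_hz)
    if not levels:
        raise ValueError(f"no dyadic detail level inside [{low_hz}, {high_hz}] Hz at fs={fs}")
    details = swt_details(x, max(levels))
    return np.sum([details[j - 1] for j in levels], axis=0)


def band_detail_reconstruction(x: np.ndarray, fs: float, low_hz: float,
                               high_hz: float) -> np.ndarray:
    """Zero-phase reconstruction of the detail scales inside [low_hz, high_hz].

    Each level's coefficients are passed through the upsampled bior1.5
    synthesis high-pass, so the combined analysis/synthesis response is
    symmetric (no derivative-like phase distortion) and the output is the
    band-limited component of ``x`` at those scales.
    """
    levels = detail_levels_for_band(fs, low_hz, high_hz)
    if not levels:
        raise ValueError(f"no dyadic detail level inside [{low_hz}, {high_hz}] Hz at fs={fs}")
    details = swt_details(x, max(levels))
    out = np.zeros_like(np.asarray(x, float))
    for j in levels:
        g = _upsample(BIOR1_5_REC_HI, j - 1)
        out += ndimage.correlate1d(details[j - 1], g[::-1], mode="reflect")
    return out
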