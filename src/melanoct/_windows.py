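"""Truncated sliding-window sums over the (A-line, depth) plane of a B-scan.

All kernel-based contrasts (DOPU, angiographic correlation, smoothed
attenuation input) share this accumulator so border handling is identical
everywhere: windows are truncated at the volume edge and the mean is taken
over the voxels actually present — no padding is fabricated.

The accumulation order (A-line offset outer, depth offset inner, both from
negative to positive) is part of the contract: a scalar reference
implementation that adds window members in the same order reproduces these
sums bit-for-bit.
"""

from __future__ import annotations

import numpy as np


def _check_kernel(kernel: tuple[int, int]) -> tuple[int, int]:
    kd, ka = int(kernel[0]), int(kernel[1])
    if kd < 1 or ka < 1 or kd % 2 == 0 or ka % 2 == 0:
        raise ValueError(f"kernel must be odd in both dimensions, got {kernel}")
    return kd, ka


def window_sum(a: np.ndarray, kernel: tuple[int, int]) -> np.ndarray:
    """Sum of each (depth x A-line) window, truncated at edges.

    Parameters
    ----------
    a : array with the last two axes (aline, depth); any leading axes.
    kernel : (k_depth, k_aline), both odd.
    """
    kd, ka = _check_kernel(kernel)
    rd, ra = kd // 2, ka // 2
    n_al, n_z = a.shape[-2], a.shape[-1]
    out = np.zeros(a.shape, dtype=np.result_type(a.dtype, np.float64))
    for da in range(-ra, ra + 1):
        a_dst = slice(max(0, -da), n_al - max(0, da))
        a_src = slice(max(0, da), n_al - max(0, -da))
        for dz in range(-rd, rd + 1):
            z_dst = slice(max(0, -dz), n_z - max(0, dz))
            z_src = slice(max(0, dz), n_z - max(0, -dz))
            out[..., a_dst, z_dst] += a[..., a_src, z_src]
    return out


def window_count(shape_al_z: tuple[int, int], kernel: tuple[int, int]) -> np.ndarray:
    """Number of in-bounds voxels in each truncated window."""
    ones = np.ones(shape_al_z, dtype=np.float64)
    return window_sum(ones, kernel)


def window_mean(a: np.ndarray, kernel: tuple[int, int]) -> np.ndarray:
    return window_sum(a, kernel) / window_count(a.shape[-2:], kernel)
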