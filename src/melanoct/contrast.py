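"""Depth-resolved attenuation and complex-correlation angiography.

These are the two non-DOPU factors of the RPE-melanin index F_RPE: the
normalized attenuation coefficient highlights strongly scattering tissue
(melanin), and the binarized decorrelation signal gates out vascular
(choroidal) depolarizers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from ._windows import window_count, window_mean, window_sum
from .polarimetry import IntensityVolume, JonesTomogram, bulk_phase_align

__all__ = [
    "AttenuationVolume",
    "AngioVolume",
    "compute_attenuation",
    "compute_angiography",
    "binarize_flow",
]


@dataclass
class AttenuationVolume:
    mu_mm1: np.ndarray            # (B, A, Z), >= 0, 0 where invalid
    mu_norm: np.ndarray           # min(mu/mu_ref, 1), 0 where invalid
    mu_ref_mm1: float
    tail_cutoff_px: int
    valid_mask: np.ndarray


@dataclass
class AngioVolume:
    decorrelation: np.ndarray     # (B, A, Z) in [0, 1]
    binary_flow: np.ndarray       # decorrelation >= threshold, exactly
    threshold: float
    kernel_shape: tuple[int, int] = (3, 3)


def compute_attenuation(
    intensity: IntensityVolume,
    axial_pitch_um: float,
    mu_ref_mm1: float = 10.0,
    tail_cutoff_px: int = 16,
    smooth_kernel: tuple[int, int] | None = (3, 7),
    tail_extrapolate: bool = True,
    noise_floor: float | None = None,
    tail_ratio_max: float = 0.995,
) -> AttenuationVolume:
    """Single-scattering depth-resolved attenuation coefficient.

    Per A-line, mu[z] = I[z] / (2 dz sum_{z'>z} I[z']) with dz in mm. Two
    practical refinements: (i) the intensity is optionally pre-averaged with
    a small (depth x A-line) kernel, since single-voxel speckle intensity is
    exponential-distributed and would make per-voxel mu unusably noisy; and
    (ii) the cumulative sum is extended past the last measured row by a
    geometric tail fitted to the final rows — without it the estimator
    overestimates mu by the missing-tail fraction even on a perfect
    exponential. The bottom ``tail_cutoff_px`` rows are flagged invalid
    regardless (the tail there is too short to trust).

    ``noise_floor`` (linear intensity, e.g. total noise power of the
    composite) is subtracted before estimation: a constant noise floor does
    not decay, so it would otherwise both bias the tail sums and drive the
    fitted tail ratio to 1. The fitted ratio is capped at
    ``tail_ratio_max`` as a further guard.
    """
    i = np.asarray(intensity.intensity, dtype=np.float64)
    if np.any(i < 0):
        raise ValueError("intensity must be nonnegative (linear scale)")
    if axial_pitch_um <= 0 or mu_ref_mm1 <= 0:
        raise ValueError("axial_pitch_um and mu_ref_mm1 must be positive")
    if noise_floor is not None and noise_floor > 0:
        i = np.maximum(i - noise_floor, 0.0)
    if smooth_kernel is not None:
        i = window_mean(i, smooth_kernel)
    dz_mm = axial_pitch_um / 1000.0
    nz = i.shape[-1]

    # sum over z' > z via reversed cumulative sum, excluding z itself
    rev = np.cumsum(i[..., ::-1], axis=-1)[..., ::-1]
    tail_sum = rev - i                                     # sum_{z'>z} I[z']

    if tail_extrapolate:
        m = min(16, max(2, nz // 8))
        last = i[..., -m:]
        num, den = last[..., 1:], last[..., :-1]
        # median of per-row ratios: robust to a layer boundary inside the
        # fitting window, exact on a pure exponential
        with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)   # all-NaN A-lines
            ratios = np.where((num > 0) & (den > 0), num / np.maximum(den, 1e-300),
                              np.nan)
            r = np.nanmedian(ratios, axis=-1)
        r = np.clip(np.nan_to_num(r, nan=0.0), 0.0, tail_ratio_max)
        extra = i[..., -1] * r / (1.0 - r)
        tail_sum = tail_sum + extra[..., None]

    with np.errstate(divide="ignore", invalid="ignore"):
        mu = i / (2.0 * dz_mm * tail_sum)
    valid = tail_sum > 0
    valid[..., nz - tail_cutoff_px:] = False
    mu = np.where(valid, mu, 0.0)
    mu = np.nan_to_num(mu, nan=0.0, posinf=0.0, neginf=0.0)
    mu_norm = np.where(valid, np.clip(mu / mu_ref_mm1, 0.0, 1.0), 0.0)
    return AttenuationVolume(
        mu_mm1=mu, mu_norm=mu_norm, mu_ref_mm1=float(mu_ref_mm1),
        tail_cutoff_px=int(tail_cutoff_px), valid_mask=valid,
    )


def compute_angiography(
    tomo: JonesTomogram,
    noise: tuple[float, float] | None = None,
    kernel: tuple[int, int] = (3, 3),
    threshold: float = 0.30,
    phase_correct: bool = True,
) -> AngioVolume:
    """Noise-corrected complex-correlation OCT angiography.

    For each adjacent repeat pair and channel, over a small kernel:
    c = |sum E_k conj(E_{k+1})| / sqrt((sum|E_k|^2 - N s2)(sum|E_{k+1}|^2 - N s2)),
    averaged over pairs and channels, clipped to [0, 1];
    decorrelation = 1 - c. Voxels with nonpositive corrected denominators are
    treated as static (decorrelation 0). Bulk phase offsets between repeats
    are removed first so axial motion phase does not masquerade as flow.
    """
    if tomo.n_repeats < 2:
        raise ValueError("angiography requires >= 2 repeats")
    if noise is None:
        noise = tomo.noise_variance
    if noise is None:
        raise ValueError("noise variances required (pass noise= or set on tomogram)")
    f = bulk_phase_align(tomo.field) if phase_correct else np.asarray(
        tomo.field, dtype=np.complex128)
    n_rep = f.shape[0]
    cnt = window_count(f.shape[-2:], kernel)
    corr_sum = np.zeros(f.shape[2:], dtype=np.float64)
    n_terms = 0
    for c in range(2):
        s2 = float(noise[c])
        power = [window_sum(np.abs(f[k, c]) ** 2, kernel) - cnt * s2
                 for k in range(n_rep)]
        for k in range(n_rep - 1):
            num = np.abs(window_sum(f[k, c] * np.conj(f[k + 1, c]), kernel))
            d1, d2 = power[k], power[k + 1]
            ok = (d1 > 0) & (d2 > 0)
            corr = np.ones_like(num)                     # invalid -> static
            corr[ok] = num[ok] / np.sqrt(d1[ok] * d2[ok])
            corr_sum += np.clip(corr, 0.0, 1.0)
            n_terms += 1
    decorr = 1.0 - corr_sum / n_terms
    decorr = np.clip(decorr, 0.0, 1.0)
    return AngioVolume(
        decorrelation=decorr,
        binary_flow=decorr >= threshold,
        threshold=float(threshold),
        kernel_shape=tuple(kernel),
    )


def binarize_flow(angio: AngioVolume, threshold: float) -> AngioVolume:
    """Re-threshold an existing decorrelation volume (idempotent)."""
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must lie in (0, 1]")
    return AngioVolume(
        decorrelation=angio.decorrelation,
        binary_flow=angio.decorrelation >= threshold,
        threshold=float(threshold),
        kernel_shape=angio.kernel_shape,
    )
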