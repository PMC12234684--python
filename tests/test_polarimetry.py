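"""Stokes algebra, DOPU estimator, coherent compositing, noise estimation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from melanoct import (
    coherent_composite,
    compute_dopu,
    compute_stokes,
    estimate_noise,
)
from melanoct.polarimetry import bulk_phase_align

from conftest import make_tomogram


def dopu_oracle(s: np.ndarray, noise, kernel=(3, 3), s0_floor=None):
    """Scalar per-window reference: same member order as the implementation."""
    sh2, sv2 = noise
    if s0_floor is None:
        s0_floor = 3.0 * (sh2 + sv2)
    _, nb, na, nz = s.shape
    rd, ra = kernel[0] // 2, kernel[1] // 2
    dopu = np.zeros((nb, na, nz))
    valid = np.zeros((nb, na, nz), dtype=bool)
    for b in range(nb):
        for a in range(na):
            for z in range(nz):
                acc = [0.0, 0.0, 0.0, 0.0]
                cnt = 0.0
                for da in range(-ra, ra + 1):
                    if not 0 <= a + da < na:
                        continue
                    for dz in range(-rd, rd + 1):
                        if not 0 <= z + dz < nz:
                            continue
                        for i in range(4):
                            acc[i] += s[i, b, a + da, z + dz]
                        cnt += 1.0
                s0 = acc[0] / cnt - (sh2 + sv2)
                s1 = acc[1] / cnt - (sh2 - sv2)
                s2 = acc[2] / cnt
                s3 = acc[3] / cnt
                ok = s0 > s0_floor if s0_floor > 0 else s0 > 0.0
                valid[b, a, z] = ok
                if ok:
                    # explicit products: scalar ** 2 routes through libm pow,
                    # which is not correctly rounded
                    p = np.sqrt(s1 * s1 + s2 * s2 + s3 * s3) / s0
                    dopu[b, a, z] = np.clip(p, 0.0, 1.0)
    return dopu, valid


@pytest.mark.parametrize(
    "eh, ev, expected",
    [
        (1.0, 0.0, (1, 1, 0, 0)),                      # horizontal
        (1 / np.sqrt(2), 1 / np.sqrt(2), (1, 0, 1, 0)),  # +45 deg linear
        (1 / np.sqrt(2), 1j / np.sqrt(2), (1, 0, 0, 1)),  # circular
    ],
)
def test_stokes_pure_states(eh, ev, expected):
    f = np.zeros((1, 2, 1, 1, 1), dtype=complex)
    f[0, 0], f[0, 1] = eh, ev
    s = compute_stokes(make_tomogram(f)).s[:, 0, 0, 0]
    assert np.allclose(s, expected, atol=1e-12)


@settings(derandomize=True, max_examples=25, deadline=None)
@given(st.integers(0, 10_000))
def test_stokes_identity_pure_fields(seed):
    """Pointwise S0^2 = S1^2 + S2^2 + S3^2 for any fully polarized field."""
    r = np.random.default_rng(seed)
    f = (r.standard_normal((2, 2, 3, 4, 5)) + 1j * r.standard_normal((2, 2, 3, 4, 5)))
    s = compute_stokes(make_tomogram(f), average_repeats=False).s
    lhs = s[0] ** 2
    rhs = s[1] ** 2 + s[2] ** 2 + s[3] ** 2
    assert np.allclose(lhs, rhs, rtol=1e-12, atol=1e-12)


def test_dopu_uniform_state_is_one(clean_phantom):
    tomo, _ = clean_phantom
    d = compute_dopu(compute_stokes(tomo), (0.0, 0.0))
    assert d.valid_mask.any()
    assert np.allclose(d.dopu[d.valid_mask], 1.0, atol=1e-5)
    assert d.dopu.min() >= 0.0 and d.dopu.max() <= 1.0


def test_dopu_antipodal_window_is_zero():
    """Equal-power H and V pixels cancel the mean polarization vector.

    A 3x3 window holds 4 horizontal and 4 vertical unit-power pixels plus one
    dark pixel, so the windowed Stokes vector at the center is (8/9, 0, 0, 0)
    and DOPU = 0 exactly.
    """
    f = np.zeros((1, 2, 1, 3, 3), dtype=complex)
    checker = np.add.outer(np.arange(3), np.arange(3)) % 2 == 0
    checker[1, 1] = False
    f[0, 0, 0][checker] = 1.0                      # 4 horizontal pixels
    f[0, 1, 0][~checker] = 1.0                     # 4 vertical pixels
    f[0, 1, 0, 1, 1] = 0.0                         # center dark
    d = compute_dopu(compute_stokes(make_tomogram(f)), (0.0, 0.0))
    assert d.valid_mask[0, 1, 1]
    assert d.dopu[0, 1, 1] == 0.0


@pytest.mark.parametrize("seed", [0, 1])
def test_dopu_equals_bruteforce_oracle(seed):
    """Vectorized DOPU reproduces the scalar window oracle bit-for-bit."""
    r = np.random.default_rng(seed)
    f = r.standard_normal((2, 2, 2, 8, 10)) + 1j * r.standard_normal((2, 2, 2, 8, 10))
    noise = (0.01, 0.02) if seed else (0.0, 0.0)
    s = compute_stokes(make_tomogram(f))
    d = compute_dopu(s, noise)
    ref_dopu, ref_valid = dopu_oracle(s.s, noise)
    assert np.array_equal(d.valid_mask, ref_valid)
    assert np.array_equal(d.dopu, ref_dopu)


def test_dopu_invariant_under_global_unitary(rng):
    """A global polarization rotation rigidly rotates every Stokes vector."""
    f = rng.standard_normal((1, 2, 2, 10, 12)) + 1j * rng.standard_normal((1, 2, 2, 10, 12))
    # random SU(2)
    q = rng.standard_normal(4)
    q /= np.linalg.norm(q)
    u = np.array([[q[0] - 1j * q[3], -q[2] - 1j * q[1]],
                  [q[2] - 1j * q[1], q[0] + 1j * q[3]]])
    f_rot = np.einsum("ij,rjbaz->ribaz", u, f)
    d0 = compute_dopu(compute_stokes(make_tomogram(f)), (0.0, 0.0))
    d1 = compute_dopu(compute_stokes(make_tomogram(f_rot)), (0.0, 0.0))
    assert np.array_equal(d0.valid_mask, d1.valid_mask)
    assert np.allclose(d0.dopu[d0.valid_mask], d1.dopu[d1.valid_mask], atol=1e-6)


def test_noise_correction_reduces_dopu_bias(rng):
    """At 10 dB, corrected DOPU of a uniform-state scene is closer to 1."""
    n = (4, 64, 64)   # > 1e4 windows
    sigma2 = 0.05     # per channel; total 0.1 = 10 dB below unit signal
    g = (rng.standard_normal(n) + 1j * rng.standard_normal(n)) / np.sqrt(2)
    f = np.zeros((1, 2) + n, dtype=complex)
    f[0, 0] = g * 0.8
    f[0, 1] = g * 0.6
    for c in range(2):
        f[0, c] += np.sqrt(sigma2) * (
            rng.standard_normal(n) + 1j * rng.standard_normal(n)) / np.sqrt(2)
    s = compute_stokes(make_tomogram(f))
    corrected = compute_dopu(s, (sigma2, sigma2))
    uncorrected = compute_dopu(s, (0.0, 0.0))
    m = corrected.valid_mask & uncorrected.valid_mask
    bias_c = abs(corrected.dopu[m].mean() - 1.0)
    bias_u = abs(uncorrected.dopu[m].mean() - 1.0)
    assert bias_c < bias_u


def test_composite_identical_repeats_matches_single(rng):
    base = rng.standard_normal((1, 2, 2, 8, 32)) + 1j * rng.standard_normal((1, 2, 2, 8, 32))
    f = np.repeat(base, 4, axis=0)
    single = np.abs(base[0, 0]) ** 2 + np.abs(base[0, 1]) ** 2
    iv = coherent_composite(make_tomogram(f))
    assert iv.provenance == "composite-of-4-repeats"
    assert np.allclose(iv.intensity, single, rtol=1e-5)


def test_composite_corrects_constant_phase_offsets(rng):
    base = rng.standard_normal((1, 2, 2, 8, 32)) + 1j * rng.standard_normal((1, 2, 2, 8, 32))
    phases = [0.0, 0.7, -1.3, 2.9]
    f = np.concatenate([base * np.exp(1j * p) for p in phases], axis=0)
    iv = coherent_composite(make_tomogram(f))
    single = np.abs(base[0, 0]) ** 2 + np.abs(base[0, 1]) ** 2
    assert np.allclose(iv.intensity, single, rtol=1e-5)
    aligned = bulk_phase_align(f)
    assert np.allclose(aligned, np.broadcast_to(base, f.shape), atol=1e-8)


def test_composite_noise_floor_quarter_of_single(rng):
    """Coherent averaging of 4 repeats drops the noise floor ~4x."""
    shape = (2, 2, 32, 256)
    sig = np.zeros(256)
    sig[100:150] = 1.0
    base = (rng.standard_normal(shape) + 1j * rng.standard_normal(shape)) \
        / np.sqrt(2) * np.sqrt(sig)
    f = np.stack([base + 0.1 * (rng.standard_normal(shape)
                                + 1j * rng.standard_normal(shape)) / np.sqrt(2)
                  for _ in range(4)])
    iv = coherent_composite(make_tomogram(f))
    single = np.abs(f[0, 0]) ** 2 + np.abs(f[0, 1]) ** 2
    ratio = iv.intensity[..., :80].mean() / single[..., :80].mean()
    assert abs(ratio - 0.25) < 0.025


def test_single_repeat_passthrough(rng):
    f = rng.standard_normal((1, 2, 2, 8, 16)) + 1j * rng.standard_normal((1, 2, 2, 8, 16))
    iv = coherent_composite(make_tomogram(f))
    assert iv.provenance == "single"
    assert np.allclose(iv.intensity, np.abs(f[0, 0]) ** 2 + np.abs(f[0, 1]) ** 2)


class TestEstimateNoise:
    def test_recovers_injected_variance(self, rng):
        f = np.zeros((2, 2, 4, 32, 64), dtype=complex)
        f[..., :32] = np.sqrt(0.01) * (
            rng.standard_normal((2, 2, 4, 32, 32))
            + 1j * rng.standard_normal((2, 2, 4, 32, 32))) / np.sqrt(2)
        f[..., 40:] = 3.0   # tissue elsewhere
        sh2, sv2 = estimate_noise(make_tomogram(f), region=(0, 32))
        assert abs(sh2 / 0.01 - 1) < 0.05
        assert abs(sv2 / 0.01 - 1) < 0.05

    def test_zero_noise_phantom(self, clean_phantom):
        tomo, _ = clean_phantom
        sh2, sv2 = estimate_noise(tomo)
        assert sh2 == 0.0 and sv2 == 0.0

    def test_small_region_rejected(self):
        f = np.zeros((1, 2, 2, 5, 8), dtype=complex)
        with pytest.raises(ValueError, match="1000"):
            estimate_noise(make_tomogram(f), region=(0, 2))

    def test_tissue_overlap_warns(self, noisy_phantom):
        tomo, _ = noisy_phantom
        with pytest.warns(UserWarning, match="tissue"):
            estimate_noise(tomo, region=(150, 200))
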