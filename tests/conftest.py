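"""Shared fixtures: small seeded phantoms and helper constructors."""

from __future__ import annotations

import numpy as np
import pytest

from melanoct import JonesTomogram, PhantomConfig, generate_phantom


def make_tomogram(field: np.ndarray, **kw) -> JonesTomogram:
    kw.setdefault("axial_pitch_um", 4.0)
    kw.setdefault("aline_pitch_um", 46.875)
    kw.setdefault("bscan_pitch_um", 93.75)
    return JonesTomogram(field=np.asarray(field, dtype=complex), **kw)


@pytest.fixture(scope="session")
def clean_phantom():
    """Noise-free, unscrambled, flowless phantom: every voxel shares one state."""
    cfg = PhantomConfig(n_bscans=12, n_alines=48, n_depth=128, scramble_p=0.0,
                        snr_db=None, flow_fraction=0.0, seed=101)
    return generate_phantom(cfg)


@pytest.fixture(scope="session")
def noisy_phantom():
    """Default-physics phantom at 20 dB with melanin scrambling and flow."""
    cfg = PhantomConfig(n_bscans=24, n_alines=96, n_depth=256, scramble_p=0.9,
                        rpe_thickness_um=48.0, snr_db=20.0, seed=7)
    return generate_phantom(cfg)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2026)
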