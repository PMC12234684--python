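"""Digital retina phantom for multi-contrast PS-OCT with full ground truth.

The phantom emulates the features the melanin pipeline keys on: a layered
retina (vitreous / neural retina / RPE melanin band / Bruch's membrane /
choroid), optional serous PED elevation of the RPE off Bruch's, optional
intraretinal melanin migration foci, choroidal vasculature (decorrelating
flow), fully developed speckle, and additive complex detector noise on two
polarization channels over repeated B-scans.

Signal model
------------
Each voxel's mean intensity follows single-scattering energy conservation:
with T[z] the cumulative two-way Beer–Lambert transmission
exp(-2 dz sum_{z'<z} mu[z']), the backscattered intensity is
I[z] = T[z] - T[z+1], i.e. the fraction of remaining light extinguished in
the voxel (constant albedo). The complex field amplitude is sqrt(I) times a
circular complex Gaussian speckle factor, shared by both channels so each
voxel is fully polarized. Non-melanin tissue shares one global Jones state;
melanin voxels receive an independent random SU(2) rotation whose angle is
scaled by ``scramble_p`` (0 = no scrambling, 1 = Haar-uniform states).

Static voxels reuse the same speckle realization across repeats (only
detector noise is redrawn); flow voxels draw fresh speckle every repeat, so
their inter-repeat complex correlation is ~0 while static tissue stays ~1.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field, asdict
from typing import Any

import numpy as np
from scipy.ndimage import gaussian_filter

from .polarimetry import JonesTomogram

__all__ = ["PhantomConfig", "PhantomTruth", "generate_phantom", "generate_cohort"]

# attenuation coefficients per tissue class, mm^-1
MU_VITREOUS = 0.0
MU_RETINA = 1.0
MU_RPE = 6.0
MU_FLUID = 0.2
MU_CHOROID = 2.0
MU_SCLERA = 8.0   # deep backstop so nearly all light is extinguished in-grid

# default uniform Jones state of non-depolarizing tissue (arbitrary but generic)
_DEFAULT_JONES = np.array([np.cos(0.6), np.sin(0.6) * np.exp(0.9j)], dtype=np.complex128)
_DEFAULT_JONES /= np.linalg.norm(_DEFAULT_JONES)


@dataclass
class PhantomConfig:
    n_bscans: int = 64
    n_alines: int = 128
    n_depth: int = 256
    axial_pitch_um: float = 4.0
    scan_width_mm: float = 6.0      # A-line (fast) direction
    scan_height_mm: float = 6.0     # B-scan (slow) direction
    n_repeats: int = 4
    rpe_thickness_um: float = 40.0
    ped: dict[str, Any] | None = None   # {center_xy, radius_mm, height_um, shape,
                                        #  thickening_um: extra RPE-melanin thickness
                                        #  at the PED apex, tapering with elevation}
    migration_foci: list[dict[str, Any]] = dc_field(default_factory=list)
    choroid_melanin: bool = False
    scramble_p: float = 0.9
    flow_fraction: float = 0.2
    snr_db: float | None = 20.0     # None -> noise-free
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_bscans", "n_alines", "n_depth"):
            if getattr(self, name) < 8:
                raise ValueError(f"{name} must be >= 8")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")
        if not 0.0 <= self.scramble_p <= 1.0:
            raise ValueError("scramble_p must lie in [0, 1]")
        if not 0.0 <= self.flow_fraction < 1.0:
            raise ValueError("flow_fraction must lie in [0, 1)")
        if self.snr_db is not None and self.snr_db <= 0:
            raise ValueError("snr_db must be positive (or None for noise-free)")
        if self.axial_pitch_um <= 0 or self.scan_width_mm <= 0 or self.scan_height_mm <= 0:
            raise ValueError("pitches and scan extents must be positive")
        if self.ped is not None:
            ped = dict(self.ped)
            ped.setdefault("center_xy", (self.scan_width_mm / 2, self.scan_height_mm / 2))
            ped.setdefault("shape", "spherical-cap")
            if ped.get("height_um", 0.0) < 0:
                raise ValueError("ped.height_um must be >= 0")
            if "radius_mm" not in ped:
                raise ValueError("ped requires radius_mm")
            if 2 * ped["radius_mm"] > min(self.scan_width_mm, self.scan_height_mm):
                raise ValueError("PED larger than scan extent")
            if ped["shape"] not in ("spherical-cap", "gaussian"):
                raise ValueError(f"unknown ped shape {ped['shape']!r}")
            self.ped = ped

    @property
    def aline_pitch_mm(self) -> float:
        return self.scan_width_mm / self.n_alines

    @property
    def bscan_pitch_mm(self) -> float:
        return self.scan_height_mm / self.n_bscans


@dataclass
class PhantomTruth:
    """Ground-truth channels emitted with every synthetic volume."""

    melanin_mask: np.ndarray           # bool (B, A, Z): RPE melanin + migration foci
    melanin_thickness_um: np.ndarray   # (B, A)
    ped_inner_boundary_px: np.ndarray  # (B, A) posterior surface of elevated RPE
    bruch_depth_px: np.ndarray         # (B, A)
    flow_mask: np.ndarray              # bool (B, A, Z)
    mu_map_mm1: np.ndarray             # (B, A, Z)
    global_jones_state: np.ndarray     # (2,) complex
    noise_variance_per_channel: tuple[float, float]
    ped_params: dict[str, Any] | None = None
    config: PhantomConfig | None = None


def _smooth_surface(rng: np.random.Generator, nb: int, na: int, base: float,
                    amp_px: float) -> np.ndarray:
    """Gently undulating surface: base depth plus two random cosine modes."""
    y = np.arange(nb)[:, None] / nb
    x = np.arange(na)[None, :] / na
    s = np.full((nb, na), float(base))
    for _ in range(2):
        fy, fx = rng.uniform(0.5, 2.0, size=2)
        py, px = rng.uniform(0, 2 * np.pi, size=2)
        s += amp_px * rng.uniform(0.3, 1.0) * np.cos(2 * np.pi * fy * y + py) \
            * np.cos(2 * np.pi * fx * x + px)
    return s


def _ped_elevation_um(cfg: PhantomConfig) -> np.ndarray:
    """PED elevation map in um over the (bscan, aline) grid."""
    nb, na = cfg.n_bscans, cfg.n_alines
    if cfg.ped is None or cfg.ped.get("height_um", 0.0) == 0.0:
        return np.zeros((nb, na))
    cx, cy = cfg.ped["center_xy"]
    h = cfg.ped["height_um"] / 1000.0   # mm
    a = cfg.ped["radius_mm"]
    x = (np.arange(na) + 0.5) * cfg.aline_pitch_mm
    y = (np.arange(nb) + 0.5) * cfg.bscan_pitch_mm
    r2 = (y[:, None] - cy) ** 2 + (x[None, :] - cx) ** 2
    if cfg.ped["shape"] == "spherical-cap":
        big_r = (a * a + h * h) / (2 * h)
        e = np.sqrt(np.maximum(big_r**2 - r2, 0.0)) - (big_r - h)
        e = np.where(r2 <= a * a, np.maximum(e, 0.0), 0.0)
    else:  # gaussian
        sigma = a / 2.0
        e = h * np.exp(-r2 / (2 * sigma**2))
    return e * 1000.0  # um


def _random_su2(rng: np.random.Generator, n: int, p: float) -> tuple[np.ndarray, np.ndarray]:
    """n random SU(2) rotations interpolated toward identity by (1 - p).

    Haar-uniform at p=1. Returned as the (a, b) entries of
    [[a, b], [-conj(b), conj(a)]].
    """
    q = rng.standard_normal((n, 4))
    q /= np.linalg.norm(q, axis=1, keepdims=True)
    # fold to rotation angle in [0, pi] then scale geodesically by p
    sign = np.where(q[:, 0] < 0, -1.0, 1.0)
    q *= sign[:, None]
    w = np.clip(q[:, 0], -1.0, 1.0)
    half = np.arccos(w)                     # theta/2 in [0, pi/2]
    axis = q[:, 1:]
    norm = np.linalg.norm(axis, axis=1, keepdims=True)
    axis = np.where(norm > 1e-12, axis / np.where(norm > 1e-12, norm, 1.0),
                    np.array([0.0, 0.0, 1.0]))
    half_p = p * half
    w2 = np.cos(half_p)
    v2 = np.sin(half_p)[:, None] * axis
    a = w2 - 1j * v2[:, 2]
    b = -v2[:, 1] - 1j * v2[:, 0]
    return a, b


def generate_phantom(config: PhantomConfig) -> tuple[JonesTomogram, PhantomTruth]:
    """Build one synthetic tomogram and its exact truth channels."""
    cfg = config
    nb, na, nz = cfg.n_bscans, cfg.n_alines, cfg.n_depth
    rng = np.random.default_rng(cfg.seed)
    dz_mm = cfg.axial_pitch_um / 1000.0

    # --- geometry -------------------------------------------------------
    ilm = _smooth_surface(rng, nb, na, base=0.18 * nz, amp_px=1.5)
    bruch = _smooth_surface(rng, nb, na, base=0.70 * nz, amp_px=1.5)
    choroid_bottom = np.minimum(bruch + 0.22 * nz, nz).astype(int)
    band_px = max(1, int(round(cfg.rpe_thickness_um / cfg.axial_pitch_um)))
    elev_um = _ped_elevation_um(cfg)
    elev_px = np.round(elev_um / cfg.axial_pitch_um).astype(int)

    # optional RPE thickening over the PED (stacked/dysmorphic RPE), tapering
    # from the apex with the elevation profile
    band_map = np.full((nb, na), band_px)
    if cfg.ped is not None and cfg.ped.get("thickening_um", 0.0) > 0:
        h_um = max(cfg.ped.get("height_um", 0.0), 1e-9)
        extra_um = cfg.ped["thickening_um"] * elev_um / h_um
        band_map = band_px + np.round(extra_um / cfg.axial_pitch_um).astype(int)

    bruch_i = np.round(bruch).astype(int)
    rpe_bot = bruch_i - elev_px                 # posterior RPE surface (fluid top)
    rpe_top = rpe_bot - band_map
    ilm_i = np.round(ilm).astype(int)
    if np.any(rpe_top <= ilm_i + 1):
        raise ValueError("PED elevation pushes the RPE band into/above the ILM")

    z = np.arange(nz)[None, None, :]
    in_retina = (z >= ilm_i[..., None]) & (z < rpe_top[..., None])
    in_rpe = (z >= rpe_top[..., None]) & (z < rpe_bot[..., None])
    in_fluid = (z >= rpe_bot[..., None]) & (z < bruch_i[..., None])
    in_choroid = (z >= bruch_i[..., None]) & (z < choroid_bottom[..., None])
    in_sclera = z >= choroid_bottom[..., None]

    mu = np.full((nb, na, nz), MU_VITREOUS)
    mu[in_retina] = MU_RETINA
    mu[in_fluid] = MU_FLUID
    mu[in_choroid] = MU_CHOROID
    mu[in_sclera] = MU_SCLERA
    mu[in_rpe] = MU_RPE

    melanin = in_rpe.copy()
    for focus in cfg.migration_foci:
        fx, fy, fz_um = focus["center_xyz"]
        r_um = focus["radius_um"]
        xx = (np.arange(na) + 0.5) * cfg.aline_pitch_mm * 1000.0
        yy = (np.arange(nb) + 0.5) * cfg.bscan_pitch_mm * 1000.0
        zz = (np.arange(nz) + 0.5) * cfg.axial_pitch_um
        d2 = ((yy[:, None, None] - fy * 1000.0) ** 2
              + (xx[None, :, None] - fx * 1000.0) ** 2
              + (zz[None, None, :] - fz_um) ** 2)
        sphere = d2 <= r_um**2
        melanin |= sphere
        mu[sphere] = MU_RPE

    scramble = melanin.copy()
    if cfg.choroid_melanin:
        scramble |= in_choroid

    # --- flow mask (choroidal vessels as smooth blobs) ------------------
    flow = np.zeros((nb, na, nz), dtype=bool)
    if cfg.flow_fraction > 0:
        noise3d = rng.standard_normal((nb, na, nz))
        blobs = gaussian_filter(noise3d, sigma=(1.5, 2.5, 2.5))
        chor = in_choroid & (z >= (bruch_i[..., None] + 2))
        if chor.any():
            thr = np.quantile(blobs[chor], 1.0 - cfg.flow_fraction)
            flow = chor & (blobs >= thr)

    # --- mean intensity from energy-conserving Beer-Lambert -------------
    two_mu_dz = 2.0 * mu * dz_mm
    optical_depth = np.cumsum(two_mu_dz, axis=-1)
    trans_next = np.exp(-optical_depth)                       # T[z+1]
    trans = np.concatenate([np.ones((nb, na, 1)), trans_next[..., :-1]], axis=-1)
    mean_i = trans - trans_next                               # I[z] = T[z]-T[z+1]

    rpe_mean = float(mean_i[in_rpe].mean()) if in_rpe.any() else 1.0
    scale = 1.0 / rpe_mean                                    # mean RPE S0 -> 1
    amp = np.sqrt(scale * mean_i).astype(np.float32)

    if cfg.snr_db is None:
        sigma2 = (0.0, 0.0)
    else:
        total = 10.0 ** (-cfg.snr_db / 10.0)                  # S0_rpe / sigma_tot = SNR
        sigma2 = (total / 2.0, total / 2.0)

    # --- Jones states ----------------------------------------------------
    jones = np.broadcast_to(_DEFAULT_JONES.astype(np.complex64),
                            (nb, na, nz, 2)).copy()
    idx = np.nonzero(scramble)
    if idx[0].size and cfg.scramble_p > 0:
        a, b = _random_su2(rng, idx[0].size, cfg.scramble_p)
        j0, j1 = _DEFAULT_JONES
        jones[idx[0], idx[1], idx[2], 0] = (a * j0 + b * j1).astype(np.complex64)
        jones[idx[0], idx[1], idx[2], 1] = (
            -np.conj(b) * j0 + np.conj(a) * j1).astype(np.complex64)

    # --- speckle, repeats, detector noise -------------------------------
    def _cn(shape):
        re = rng.standard_normal(shape, dtype=np.float32)
        im = rng.standard_normal(shape, dtype=np.float32)
        return (re + 1j * im) * np.float32(1 / np.sqrt(2))

    g_static = _cn((nb, na, nz))
    field = np.empty((cfg.n_repeats, 2, nb, na, nz), dtype=np.complex64)
    fidx = np.nonzero(flow)
    for r in range(cfg.n_repeats):
        g = g_static
        if fidx[0].size:
            g = g_static.copy()
            g[fidx] = _cn(fidx[0].size)
        base = amp * g
        for c in range(2):
            e = base * jones[..., c]
            if sigma2[c] > 0:
                e = e + np.float32(np.sqrt(sigma2[c])) * _cn((nb, na, nz))
            field[r, c] = e

    noise_z1 = max(8, int(ilm_i.min() * 0.6))
    tomo = JonesTomogram(
        field=field,
        axial_pitch_um=cfg.axial_pitch_um,
        aline_pitch_um=cfg.aline_pitch_mm * 1000.0,
        bscan_pitch_um=cfg.bscan_pitch_mm * 1000.0,
        noise_variance=sigma2,
        noise_depth_range=(0, noise_z1),
        subject_id=f"seed{cfg.seed}",
    )
    truth = PhantomTruth(
        melanin_mask=melanin,
        melanin_thickness_um=melanin.sum(axis=-1) * cfg.axial_pitch_um,
        ped_inner_boundary_px=rpe_bot,
        bruch_depth_px=bruch_i,
        flow_mask=flow,
        mu_map_mm1=mu,
        global_jones_state=_DEFAULT_JONES.copy(),
        noise_variance_per_channel=sigma2,
        ped_params=dict(cfg.ped) if cfg.ped else None,
        config=cfg,
    )
    return tomo, truth


_RANGE_KEYS = {
    "rpe_thickness_um", "scramble_p", "flow_fraction", "snr_db",
    "ped.height_um", "ped.radius_mm", "ped.thickening_um",
}


def generate_cohort(
    n_subjects: int,
    config_ranges: dict[str, Any],
    seed: int = 0,
    base_config: PhantomConfig | None = None,
) -> list[tuple[JonesTomogram, PhantomTruth]]:
    """Randomized cohort: per-subject configs drawn from stated ranges.

    ``config_ranges`` maps (possibly dotted) config fields to a (lo, hi)
    uniform range, a list of choices, or a fixed scalar; e.g.
    ``{"rpe_thickness_um": (24, 64), "ped.height_um": (50, 200),
    "ped.radius_mm": [1.0, 1.5, 2.0]}``.
    """
    if n_subjects < 2:
        raise ValueError("n_subjects must be >= 2")
    if not config_ranges:
        raise ValueError("config_ranges must not be empty")
    unknown = set(config_ranges) - _RANGE_KEYS
    if unknown:
        raise ValueError(f"unknown config range keys: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    base = asdict(base_config) if base_config is not None else asdict(PhantomConfig())

    out = []
    for i in range(n_subjects):
        cfg_dict = {k: v for k, v in base.items()}
        ped: dict[str, Any] = dict(cfg_dict.get("ped") or {})
        for key, spec in config_ranges.items():
            if isinstance(spec, (tuple,)) and len(spec) == 2:
                val = float(rng.uniform(spec[0], spec[1]))
            elif isinstance(spec, list):
                val = spec[int(rng.integers(len(spec)))]
            else:
                val = spec
            if key.startswith("ped."):
                ped[key.split(".", 1)[1]] = val
            else:
                cfg_dict[key] = val
        if ped.get("height_um", 0.0) > 0:
            ped.setdefault("radius_mm", 1.5)
            cfg_dict["ped"] = ped
        else:
            cfg_dict["ped"] = None
        cfg_dict["seed"] = int(rng.integers(0, 2**31 - 1))
        cfg = PhantomConfig(**cfg_dict)
        tomo, truth = generate_phantom(cfg)
        tomo.subject_id = f"S{i:03d}"
        out.append((tomo, truth))
    return out
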