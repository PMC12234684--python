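"""F_RPE fusion, RPE-melanin thickness maps, lesion areas, PED volumes.

The RPE-melanin index fuses three contrasts voxelwise:

    F_RPE = mu_norm * (1 - DOPU) * (1 - binarized flow)

so a voxel scores high only if it attenuates strongly, scrambles
polarization, and carries no flow — the signature of RPE melanin as opposed
to choroidal melanin (which sits in vascular tissue). Thickness maps count
suprathreshold voxels per A-line; lesion areas and PED volumes are exact
pixel/slab sums (Cavalieri).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from skimage.draw import polygon2mask

from .contrast import AngioVolume, AttenuationVolume
from .polarimetry import DOPUVolume

__all__ = [
    "FRPEVolume",
    "MelaninThicknessMap",
    "LesionAreaResult",
    "PEDVolumeResult",
    "compute_frpe",
    "thickness_map",
    "lesion_area",
    "ped_volume",
    "transverse_scale",
    "enface_projection",
    "render_colormap",
]


@dataclass
class FRPEVolume:
    frpe: np.ndarray                       # (B, A, Z) in [0, 1]
    pixel_threshold: float = 0.15
    axial_pitch_um: float = 4.0
    inputs_provenance: dict = dc_field(default_factory=dict)


@dataclass
class MelaninThicknessMap:
    thickness_um: np.ndarray               # (B, A)
    axial_pitch_um: float
    aline_pitch_mm: float
    bscan_pitch_mm: float
    source: str = "original"               # "original" | "synthesized"


@dataclass
class LesionAreaResult:
    mask: np.ndarray                       # (B, A) bool (already intersected with roi)
    area_mm2: float
    thickness_threshold_um: float
    pixel_area_mm2: float
    roi: np.ndarray | None = None          # polygon vertices used, if any


@dataclass
class PEDVolumeResult:
    volume_mm3: float
    per_bscan_area_mm2: np.ndarray
    bscan_spacing_mm: float


def compute_frpe(
    dopu: DOPUVolume,
    atten: AttenuationVolume,
    angio: AngioVolume,
    pixel_threshold: float = 0.15,
    axial_pitch_um: float = 4.0,
) -> FRPEVolume:
    """Pointwise three-factor product; invalid input voxels yield 0."""
    if not (dopu.dopu.shape == atten.mu_norm.shape == angio.decorrelation.shape):
        raise ValueError(
            "volume dimensions differ: "
            f"dopu {dopu.dopu.shape}, atten {atten.mu_norm.shape}, "
            f"angio {angio.decorrelation.shape}"
        )
    frpe = atten.mu_norm * (1.0 - dopu.dopu) * (1.0 - angio.binary_flow.astype(np.float64))
    frpe = np.where(dopu.valid_mask & atten.valid_mask, frpe, 0.0)
    return FRPEVolume(
        frpe=frpe,
        pixel_threshold=float(pixel_threshold),
        axial_pitch_um=float(axial_pitch_um),
        inputs_provenance={
            "dopu_source": dopu.source,
            "mu_ref_mm1": atten.mu_ref_mm1,
            "flow_threshold": angio.threshold,
        },
    )


def thickness_map(
    frpe: FRPEVolume,
    aline_pitch_mm: float,
    bscan_pitch_mm: float,
) -> MelaninThicknessMap:
    """Per-A-line count of F_RPE >= threshold voxels, times the axial pitch.

    Suprathreshold voxels need not be contiguous — thickness is a pure pixel
    count, so values are exact integer multiples of the axial pitch.
    """
    count = (frpe.frpe >= frpe.pixel_threshold).sum(axis=-1)
    source = "synthesized" if frpe.inputs_provenance.get("dopu_source") == "synthesized" \
        else "original"
    return MelaninThicknessMap(
        thickness_um=count * frpe.axial_pitch_um,
        axial_pitch_um=frpe.axial_pitch_um,
        aline_pitch_mm=float(aline_pitch_mm),
        bscan_pitch_mm=float(bscan_pitch_mm),
        source=source,
    )


def lesion_area(
    tmap: MelaninThicknessMap,
    thickness_threshold_um: float = 70.0,
    roi_polygon: np.ndarray | None = None,
    scale: float = 1.0,
) -> LesionAreaResult:
    """Area of thickened melanin (>= threshold) by exact pixel counting.

    ``roi_polygon`` is an optional (N, 2) array of (bscan, aline) pixel
    vertices bounding the region of interest (e.g. the PED margin); the
    suprathreshold mask is intersected with it. ``scale`` is a transverse
    magnification factor (see :func:`transverse_scale`); area scales by
    scale**2.
    """
    th = tmap.thickness_um
    mask = th >= thickness_threshold_um
    if roi_polygon is not None:
        poly = np.asarray(roi_polygon, dtype=float)
        if (poly[:, 0].max() < 0 or poly[:, 1].max() < 0
                or poly[:, 0].min() > th.shape[0] or poly[:, 1].min() > th.shape[1]):
            raise ValueError("roi polygon lies outside the scan")
        mask = mask & polygon2mask(th.shape, poly)
    pixel_area = tmap.aline_pitch_mm * tmap.bscan_pitch_mm * scale**2
    return LesionAreaResult(
        mask=mask,
        area_mm2=float(mask.sum()) * pixel_area,
        thickness_threshold_um=float(thickness_threshold_um),
        pixel_area_mm2=pixel_area,
        roi=None if roi_polygon is None else np.asarray(roi_polygon, dtype=float),
    )


def ped_volume(
    inner_boundary_px: np.ndarray,
    bruch_px: np.ndarray,
    axial_pitch_um: float,
    aline_pitch_mm: float,
    bscan_pitch_mm: float,
) -> PEDVolumeResult:
    """Cavalieri PED volume from per-B-scan segmentation.

    Per B-scan cross-sectional area = sum over A-lines of
    (bruch - inner boundary) * axial pitch * A-line pitch; the total volume
    is the sum of areas times the B-scan spacing. Depth increases away from
    the vitreous, so the (elevated) inner boundary must not exceed Bruch's.
    """
    inner = np.asarray(inner_boundary_px, dtype=np.float64)
    bruch = np.asarray(bruch_px, dtype=np.float64)
    if inner.shape != bruch.shape:
        raise ValueError("boundary and Bruch maps must have identical shape")
    bad = inner > bruch
    if bad.any():
        b, a = np.argwhere(bad)[0]
        raise ValueError(
            f"inner boundary crosses below Bruch's at (bscan={b}, aline={a})"
        )
    elev_mm = (bruch - inner) * axial_pitch_um / 1000.0
    areas = elev_mm.sum(axis=1) * aline_pitch_mm
    return PEDVolumeResult(
        volume_mm3=float(areas.sum() * bscan_pitch_mm),
        per_bscan_area_mm2=areas,
        bscan_spacing_mm=float(bscan_pitch_mm),
    )


def transverse_scale(axial_length_mm: float, reference_al_mm: float = 24.46) -> float:
    """Littmann/Bennett-style transverse magnification factor.

    scale = 0.01306 (AL - 1.82) / (0.01306 (AL_ref - 1.82)); unity at the
    reference axial length (24.46 mm, the standard emmetropic eye).
    """
    if not 15.0 <= axial_length_mm <= 35.0:
        raise ValueError("axial length must lie in [15, 35] mm")
    return (axial_length_mm - 1.82) / (reference_al_mm - 1.82)


def enface_projection(
    volume: np.ndarray,
    reducer: str = "mean",
    depth_range: tuple[int, int] | None = None,
) -> np.ndarray:
    """Reduce a (B, A, Z) volume along depth into an en-face map."""
    vol = np.asarray(volume)
    if depth_range is not None:
        z0, z1 = depth_range
        if z1 <= z0 or z0 < 0 or z1 > vol.shape[-1]:
            raise ValueError(f"empty or out-of-range depth range {depth_range}")
        vol = vol[..., z0:z1]
    reducers = {"mean": np.mean, "max": np.max, "sum": np.sum}
    if reducer not in reducers:
        raise ValueError(f"reducer must be one of {sorted(reducers)}")
    return reducers[reducer](vol, axis=-1)


def render_colormap(
    tmap: MelaninThicknessMap,
    palette: str = "inferno",
    range_um: tuple[float, float] | None = None,
) -> tuple[np.ndarray, dict]:
    """Color-coded thickness map as an 8-bit RGB image plus scale metadata."""
    import matplotlib
    th = tmap.thickness_um
    if range_um is None:
        range_um = (0.0, float(th.max()) if th.max() > 0 else 1.0)
    lo, hi = range_um
    if hi <= lo:
        raise ValueError("range_um must be increasing")
    cmap = matplotlib.colormaps[palette]
    norm = np.clip((th - lo) / (hi - lo), 0.0, 1.0)
    rgb = (cmap(norm)[..., :3] * 255).round().astype(np.uint8)
    meta = {"palette": palette, "range_um": [float(lo), float(hi)],
            "units": "um", "source": tmap.source}
    return rgb, meta
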