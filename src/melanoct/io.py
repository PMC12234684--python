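"""HDF5 volume container and 2-D exports.

Layout: /field (complex, repeat x channel x bscan x aline x depth),
/truth/* (optional phantom ground truth), /derived/* (pipeline outputs,
each stamped with the config hash of the run that produced it), and root
attributes for geometry, noise, subject id, software version and the
generating config as JSON.
"""

from __future__ import annotations

import json

import h5py
import numpy as np
import tifffile

from . import __version__
from .phantom import PhantomTruth
from .polarimetry import JonesTomogram

__all__ = [
    "save_tomogram",
    "load_tomogram",
    "save_derived",
    "load_derived",
    "list_derived",
    "export_tiff_stack",
]


def save_tomogram(
    path: str,
    tomo: JonesTomogram,
    truth: PhantomTruth | None = None,
    config_json: str | None = None,
) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("field", data=tomo.field)
        f.attrs["axial_pitch_um"] = tomo.axial_pitch_um
        f.attrs["aline_pitch_um"] = tomo.aline_pitch_um
        f.attrs["bscan_pitch_um"] = tomo.bscan_pitch_um
        f.attrs["subject_id"] = tomo.subject_id
        f.attrs["software_version"] = __version__
        if tomo.noise_variance is not None:
            f.attrs["noise_variance"] = np.asarray(tomo.noise_variance)
        if tomo.noise_depth_range is not None:
            f.attrs["noise_depth_range"] = np.asarray(tomo.noise_depth_range)
        if config_json is not None:
            f.attrs["config_json"] = config_json
        if truth is not None:
            g = f.create_group("truth")
            g.create_dataset("melanin_mask", data=truth.melanin_mask)
            g.create_dataset("melanin_thickness_um", data=truth.melanin_thickness_um)
            g.create_dataset("ped_inner_boundary_px", data=truth.ped_inner_boundary_px)
            g.create_dataset("bruch_depth_px", data=truth.bruch_depth_px)
            g.create_dataset("flow_mask", data=truth.flow_mask)
            g.create_dataset("mu_map_mm1", data=truth.mu_map_mm1)
            g.create_dataset("global_jones_state", data=truth.global_jones_state)
            g.attrs["noise_variance_per_channel"] = np.asarray(
                truth.noise_variance_per_channel)
            if truth.ped_params is not None:
                g.attrs["ped_params"] = json.dumps(
                    {k: (list(v) if isinstance(v, (tuple, list)) else v)
                     for k, v in truth.ped_params.items()})


def load_tomogram(path: str) -> tuple[JonesTomogram, PhantomTruth | None]:
    with h5py.File(path, "r") as f:
        field = f["field"][...]
        spatial = field.shape[2:]
        nv = f.attrs.get("noise_variance")
        nr = f.attrs.get("noise_depth_range")
        tomo = JonesTomogram(
            field=field,
            axial_pitch_um=float(f.attrs["axial_pitch_um"]),
            aline_pitch_um=float(f.attrs["aline_pitch_um"]),
            bscan_pitch_um=float(f.attrs["bscan_pitch_um"]),
            noise_variance=tuple(map(float, nv)) if nv is not None else None,
            noise_depth_range=tuple(map(int, nr)) if nr is not None else None,
            subject_id=str(f.attrs.get("subject_id", "")),
        )
        truth = None
        if "truth" in f:
            g = f["truth"]
            for name in ("melanin_mask", "flow_mask", "mu_map_mm1"):
                if g[name].shape != spatial:
                    raise ValueError(
                        f"container is dimensionally inconsistent: truth/{name} "
                        f"has shape {g[name].shape}, field spatial shape is {spatial}"
                    )
            pp = g.attrs.get("ped_params")
            truth = PhantomTruth(
                melanin_mask=g["melanin_mask"][...].astype(bool),
                melanin_thickness_um=g["melanin_thickness_um"][...],
                ped_inner_boundary_px=g["ped_inner_boundary_px"][...],
                bruch_depth_px=g["bruch_depth_px"][...],
                flow_mask=g["flow_mask"][...].astype(bool),
                mu_map_mm1=g["mu_map_mm1"][...],
                global_jones_state=g["global_jones_state"][...],
                noise_variance_per_channel=tuple(
                    map(float, g.attrs["noise_variance_per_channel"])),
                ped_params=json.loads(pp) if pp is not None else None,
            )
        return tomo, truth


def save_derived(path: str, name: str, array: np.ndarray, config_hash: str,
                 attrs: dict | None = None) -> None:
    with h5py.File(path, "a") as f:
        spatial = f["field"].shape[2:] if "field" in f else None
        if spatial is not None and array.shape[-3:] != spatial:
            raise ValueError(
                f"derived/{name} shape {array.shape} inconsistent with field "
                f"spatial shape {spatial}"
            )
        g = f.require_group("derived")
        if name in g:
            del g[name]
        d = g.create_dataset(name, data=array)
        d.attrs["config_hash"] = config_hash
        for k, v in (attrs or {}).items():
            d.attrs[k] = v


def load_derived(path: str, name: str) -> tuple[np.ndarray, dict]:
    with h5py.File(path, "r") as f:
        if "derived" not in f or name not in f["derived"]:
            raise KeyError(f"container has no derived/{name}; run that stage first")
        d = f["derived"][name]
        return d[...], dict(d.attrs)


def list_derived(path: str) -> list[str]:
    with h5py.File(path, "r") as f:
        return sorted(f["derived"].keys()) if "derived" in f else []


def export_tiff_stack(path: str, volume: np.ndarray) -> None:
    """Write a (bscan, aline, depth) volume as a 32-bit float B-scan stack."""
    stack = np.asarray(volume, dtype=np.float32).transpose(0, 2, 1)  # (B, depth, aline)
    tifffile.imwrite(path, stack)
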