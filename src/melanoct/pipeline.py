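"""End-to-end runs: phantom/container -> contrasts -> melanin report.

``run_pipeline`` chains noise estimation, coherent compositing, Stokes/DOPU
(or synthesized DOPU), attenuation, angiography, F_RPE fusion, thickness
mapping and lesion/PED quantification for one volume, logging each stage
with wall time and shapes. ``cohort_report`` aggregates per-subject bundles
into group statistics and paired original-vs-synthesized comparisons.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sp_stats

from .config import RunConfig
from .contrast import compute_angiography, compute_attenuation
from .melanin import (
    compute_frpe,
    lesion_area,
    ped_volume,
    render_colormap,
    thickness_map,
    transverse_scale,
)
from .phantom import PhantomTruth
from .polarimetry import (
    JonesTomogram,
    coherent_composite,
    compute_dopu,
    compute_stokes,
    estimate_noise,
)
from .synthesis import synthesize_dopu

log = logging.getLogger("melanoct")

__all__ = ["run_pipeline", "cohort_report", "ped_margin_polygon"]


def _stage(name: str, t0: float, **shapes) -> None:
    desc = ", ".join(f"{k}={v}" for k, v in shapes.items())
    log.info("%s done in %.2f s (%s)", name, time.perf_counter() - t0, desc)


def ped_margin_polygon(truth: PhantomTruth, n_vertices: int = 64) -> np.ndarray | None:
    """PED margin as a polygon in (bscan, aline) pixel coordinates.

    The phantom supplies the margin from its own truth (the published
    workflow drew it manually on the en-face projection).
    """
    if truth.ped_params is None or truth.config is None:
        return None
    cfg = truth.config
    cx, cy = truth.ped_params["center_xy"]
    r = truth.ped_params["radius_mm"]
    t = np.linspace(0, 2 * np.pi, n_vertices, endpoint=False)
    b = (cy + r * np.sin(t)) / cfg.bscan_pitch_mm - 0.5
    a = (cx + r * np.cos(t)) / cfg.aline_pitch_mm - 0.5
    return np.stack([b, a], axis=1)


def run_pipeline(
    tomo: JonesTomogram,
    truth: PhantomTruth | None = None,
    config: RunConfig | None = None,
    dopu_source: str = "measured",
    model=None,
    outdir: str | None = None,
) -> dict:
    """Process one volume and return a report bundle.

    The bundle carries the derived volumes, the en-face thickness map, scalar
    metrics (mean thickness, lesion area, PED volume when segmentation is
    available), truth comparisons when truth is given, and full provenance
    (config hash, thresholds, dopu source).
    """
    cfg = config or RunConfig()
    if dopu_source not in ("measured", "synthesized"):
        raise ValueError("dopu_source must be 'measured' or 'synthesized'")
    if dopu_source == "synthesized" and model is None:
        raise ValueError("synthesized DOPU requested: pass a trained model "
                         "(stage 'synth train' must run first)")

    t0 = time.perf_counter()
    noise = tomo.noise_variance
    if noise is None:
        if tomo.noise_depth_range is None:
            raise ValueError("no noise variances and no noise region: "
                             "run noise estimation first")
        noise = estimate_noise(tomo)
    _stage("noise", t0, sigma2=tuple(np.round(noise, 8)))

    t0 = time.perf_counter()
    intensity = coherent_composite(tomo)
    _stage("composite", t0, shape=intensity.intensity.shape)

    t0 = time.perf_counter()
    if dopu_source == "measured":
        stokes = compute_stokes(tomo, average_repeats=cfg.average_repeats_for_dopu)
        dopu = compute_dopu(stokes, noise, kernel=cfg.dopu_kernel,
                            s0_floor=cfg.s0_floor)
    else:
        floor = 3.0 * (noise[0] + noise[1])
        dopu = synthesize_dopu(
            model, intensity, patch_size=cfg.synth.patch_size,
            overlap=cfg.synth.overlap, intensity_floor=floor if floor > 0 else None,
        )
    _stage(f"dopu[{dopu_source}]", t0, valid=int(dopu.valid_mask.sum()))

    t0 = time.perf_counter()
    atten = compute_attenuation(
        intensity, tomo.axial_pitch_um, mu_ref_mm1=cfg.mu_ref_mm1,
        tail_cutoff_px=cfg.tail_cutoff_px, smooth_kernel=cfg.atten_smooth_kernel,
        noise_floor=(noise[0] + noise[1]) / tomo.n_repeats,
    )
    _stage("attenuation", t0, mu_ref=cfg.mu_ref_mm1)

    t0 = time.perf_counter()
    angio = compute_angiography(tomo, noise=noise, kernel=cfg.angio_kernel,
                                threshold=cfg.flow_threshold)
    _stage("angiography", t0, flow_voxels=int(angio.binary_flow.sum()))

    t0 = time.perf_counter()
    frpe = compute_frpe(dopu, atten, angio,
                        pixel_threshold=cfg.frpe_pixel_threshold,
                        axial_pitch_um=tomo.axial_pitch_um)
    tmap = thickness_map(frpe, aline_pitch_mm=tomo.aline_pitch_um / 1000.0,
                         bscan_pitch_mm=tomo.bscan_pitch_um / 1000.0)
    scale = 1.0
    if cfg.axial_length_mm is not None:
        scale = transverse_scale(cfg.axial_length_mm)
    roi = ped_margin_polygon(truth) if truth is not None else None
    lesion = lesion_area(tmap, thickness_threshold_um=cfg.thickness_threshold_um,
                         roi_polygon=roi, scale=scale)
    _stage("melanin", t0, mean_thickness_um=float(tmap.thickness_um.mean()))

    metrics: dict = {
        "subject_id": tomo.subject_id,
        "dopu_source": dopu_source,
        "mean_thickness_um": float(tmap.thickness_um.mean()),
        "lesion_area_mm2": lesion.area_mm2,
        "transverse_scale": scale,
        "thresholds": {
            "frpe_pixel": cfg.frpe_pixel_threshold,
            "thickness_um": cfg.thickness_threshold_um,
            "flow": cfg.flow_threshold,
            "mu_ref_mm1": cfg.mu_ref_mm1,
        },
        "config_hash": cfg.config_hash(),
    }
    if truth is not None:
        pv = ped_volume(
            truth.ped_inner_boundary_px, truth.bruch_depth_px,
            axial_pitch_um=tomo.axial_pitch_um,
            aline_pitch_mm=tomo.aline_pitch_um / 1000.0,
            bscan_pitch_mm=tomo.bscan_pitch_um / 1000.0,
        )
        err_px = (tmap.thickness_um - truth.melanin_thickness_um) / tomo.axial_pitch_um
        metrics.update({
            "ped_volume_mm3": pv.volume_mm3,
            "truth_mean_thickness_um": float(truth.melanin_thickness_um.mean()),
            "thickness_median_abs_err_px": float(np.median(np.abs(err_px))),
        })

    bundle = {
        "metrics": metrics,
        "intensity": intensity,
        "dopu": dopu,
        "attenuation": atten,
        "angio": angio,
        "frpe": frpe,
        "thickness_map": tmap,
        "lesion": lesion,
        "config": cfg,
    }
    if outdir is not None:
        _write_bundle(bundle, outdir)
    return bundle


def _write_bundle(bundle: dict, outdir: str) -> None:
    from . import io as mio
    from PIL import Image

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    sid = bundle["metrics"]["subject_id"] or "volume"
    src = bundle["metrics"]["dopu_source"]
    tmap = bundle["thickness_map"]
    mio.export_tiff_stack(out / f"{sid}_{src}_dopu.tif", bundle["dopu"].dopu)
    import tifffile
    tifffile.imwrite(out / f"{sid}_{src}_thickness_um.tif",
                     tmap.thickness_um.astype(np.float32))
    rgb, meta = render_colormap(tmap)
    Image.fromarray(rgb).save(out / f"{sid}_{src}_thickness.png")
    payload = dict(bundle["metrics"])
    payload["colormap"] = meta
    with open(out / f"{sid}_{src}_metrics.json", "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)


def cohort_report(bundles: list[dict], outdir: str | None = None) -> dict:
    """Aggregate per-subject bundles into tables and paired statistics.

    Bundles may mix ``dopu_source`` values; subjects present with both
    sources contribute to the original-vs-synthesized paired comparison.
    Rejects cohorts of fewer than 2 subjects or mixed scan geometries.
    """
    if len(bundles) < 2:
        raise ValueError("cohort_report needs >= 2 subjects")
    shapes = {b["thickness_map"].thickness_um.shape for b in bundles}
    if len(shapes) > 1:
        raise ValueError(f"mixed scan geometries in cohort: {sorted(shapes)}")

    rows = []
    for b in bundles:
        m = b["metrics"]
        rows.append({
            "subject_id": m["subject_id"],
            "dopu_source": m["dopu_source"],
            "mean_thickness_um": m["mean_thickness_um"],
            "lesion_area_mm2": m["lesion_area_mm2"],
            "ped_volume_mm3": m.get("ped_volume_mm3", np.nan),
        })
    table = pd.DataFrame(rows)

    report: dict = {"n_bundles": len(bundles)}
    for src, grp in table.groupby("dopu_source"):
        report[f"{src}_mean_thickness_um"] = float(grp["mean_thickness_um"].mean())
        report[f"{src}_sd_thickness_um"] = (
            float(grp["mean_thickness_um"].std(ddof=1)) if len(grp) > 1 else 0.0)

    from .synthesis import compare_original_synthesized
    wide = table.pivot_table(index="subject_id", columns="dopu_source",
                             values="mean_thickness_um")
    if {"measured", "synthesized"} <= set(wide.columns):
        paired = wide.dropna()
        if len(paired) >= 2:
            report["original_vs_synthesized"] = compare_original_synthesized(
                paired["measured"].to_numpy(), paired["synthesized"].to_numpy())

    sub = table.dropna(subset=["ped_volume_mm3"])
    sub = sub[sub["dopu_source"] == "measured"] if (sub["dopu_source"] == "measured").any() else sub
    if len(sub) >= 3 and sub["lesion_area_mm2"].std() > 0 and sub["ped_volume_mm3"].std() > 0:
        r = sp_stats.pearsonr(sub["lesion_area_mm2"], sub["ped_volume_mm3"])
        report["lesion_vs_ped_volume"] = {
            "pearson_r": float(r.statistic), "pearson_p": float(r.pvalue),
            "n": int(len(sub)),
        }

    if outdir is not None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        table.to_csv(out / "cohort_table.csv", index=False)
        with open(out / "cohort_report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True, default=float)
    report["table"] = table
    return report
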