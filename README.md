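# melanoct

Multi-contrast polarization-sensitive OCT (PS-OCT) pipeline for mapping
melanin in the retinal pigment epithelium (RPE), with a deep-learning
shortcut that synthesizes the polarization contrast from standard OCT
intensity alone.

## Who this is for

Researchers working on retinal OCT image analysis — in particular on RPE
changes in age-related macular degeneration (AMD) and serous pigment
epithelial detachment (PED) — who want a fully synthetic, ground-truthed
test bed for RPE-melanin quantification: no scanner, no patient data, every
stage verifiable against known truth.

## The method

Melanin scrambles the polarization of backscattered light. The degree of
polarization uniformity (DOPU) quantifies this: within a small kernel the
Stokes vectors of neighbouring voxels are averaged and

```
DOPU = sqrt(<S1>c² + <S2>² + <S3>²) / <S0>c
```

with noise-bias corrections `<S0>c = <S0> − (σ_H² + σ_V²)` and
`<S1>c = <S1> − (σ_H² − σ_V²)` (Makita-style correction, 3×3 kernel).
DOPU is 1.0 where polarization is uniform and falls toward 0.0 in melanin.
Choroidal melanin also depolarizes, so DOPU alone cannot isolate the RPE.
The RPE-melanin index fuses three contrasts per voxel:

```
F_RPE = μ_norm × (1 − DOPU) × (1 − binarized OCT angiography signal)
```

where `μ_norm` is the depth-resolved attenuation coefficient
(`μ[z] = I[z] / (2Δz Σ_{z'>z} I[z'])`, normalized by a reference of
10 mm⁻¹) and the binarized complex-correlation angiography signal removes
vascular (choroidal) voxels. A voxel with `F_RPE ≥ 0.15` counts as RPE
melanin; counting such voxels along each A-line and multiplying by the
axial pitch gives the en-face **RPE-melanin thickness map**. Downstream
quantification: thickened-lesion area (thickness ≥ 70 μm, exact pixel
counting within a PED margin), Cavalieri PED volume from segmented
surfaces, and Littmann/Bennett transverse scaling for eye-length
magnification.

Because DOPU normally requires dual-polarization hardware, the package also
reproduces the *synthesis* procedure: a compact convolutional
encoder–decoder (U-Net-style, ~30k parameters, numpy implementation) is
trained on paired patches of log intensity and measured DOPU with
binary-cross-entropy loss and a strict subject-wise 8:2 split, then the
melanin pipeline is re-run with synthesized DOPU in place of measured DOPU
and the two arms are compared (Wilcoxon signed-rank, Pearson).

All inputs come from a digital retina phantom (`melanoct.phantom`):
layered surfaces, an RPE melanin band with per-voxel random SU(2)
polarization scrambling, optional serous PED elevation with apex RPE
thickening and intraretinal migration foci, choroidal flow, fully developed
speckle, and calibrated detector noise — with exact truth channels for
every derived quantity.

## Worked example

```python
import melanoct as m

cfg = m.PhantomConfig(n_bscans=24, n_alines=96, n_depth=256,
                      rpe_thickness_um=48.0, scramble_p=0.9,
                      snr_db=20.0, seed=7)
tomo, truth = m.generate_phantom(cfg)
bundle = m.run_pipeline(tomo, truth=truth)
mt = bundle["metrics"]
print(f"mean thickness  : {mt['mean_thickness_um']:.1f} um "
      f"(truth {mt['truth_mean_thickness_um']:.1f} um)")
print(f"median map error: {mt['thickness_median_abs_err_px']:.1f} axial px")
print(f"lesion area     : {mt['lesion_area_mm2']:.3f} mm2")
```

prints

```
mean thickness  : 44.8 um (truth 48.0 um)
median map error: 1.0 axial px
lesion area     : 0.000 mm2
```

i.e. the pipeline recovers the 48 μm melanin band to within one axial pixel
(4 μm) on average, and no A-line reaches the 70 μm thickened-lesion cut, so
the lesion area is exactly zero. The same flow is available from the shell:

```
melanoct phantom generate --out eye.h5 --preset ped --seed 5
melanoct process frpe --container eye.h5
melanoct quantify ped-volume --container eye.h5
```

## Layout

- `melanoct.phantom` — synthetic volumes + ground truth
- `melanoct.polarimetry` — Stokes, DOPU, coherent compositing, noise
- `melanoct.contrast` — attenuation coefficient, angiography
- `melanoct.melanin` — F_RPE, thickness maps, lesion areas, PED volumes
- `melanoct.synthesis` / `melanoct.nn` — intensity→DOPU network
- `melanoct.pipeline` / `melanoct.cli` / `melanoct.io` — orchestration,
  HDF5 container, command line

See `docs/methods.md` for the model assumptions, parameter defaults and
numerical choices.
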