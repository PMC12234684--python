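# Methods

This note documents the models, estimators, parameter defaults and
numerical choices behind `melanoct`, and what the synthetic test bed does
and does not establish about real data.

## Signal model of the phantom

Each voxel's mean backscattered intensity follows single-scattering energy
conservation. With `T[z] = exp(−2Δz Σ_{z'<z} μ[z'])` the two-way
Beer–Lambert transmission down to voxel `z`, the phantom sets

```
I[z] = T[z] − T[z+1]
```

i.e. the fraction of remaining light extinguished in the voxel (constant
albedo). The complex field is `E = sqrt(I)·g·J`, where `g` is a unit
circular complex Gaussian speckle factor shared by both polarization
channels (each voxel is fully polarized) and `J` is a unit Jones vector.
This is the model under which the depth-resolved attenuation estimator
(below) is consistent; it is a statistical speckle model, not a wave
simulation.

Layer attenuation coefficients (mm⁻¹): vitreous 0, neural retina 1, RPE
melanin band 6, serous fluid 0.2, choroid 2, deep sclera-like backstop 8.
The backstop matters: without it a non-negligible fraction of the incident
light would leave the grid unextinguished and every μ estimate above would
be biased upward by the missing tail.

Geometry defaults to a 64×128×256 (B-scan × A-line × depth) grid over a
nominal 6×6 mm scan at 4 μm axial pitch with 4 repeats — a reduced-sampling
version of a 512-A-line × 256-B-scan clinical raster, sized so a full
volume (~134 MB of complex64) generates in a few seconds. Full-scale
geometry is available through `PhantomConfig`.

**Polarization.** Non-melanin tissue shares one global Jones state. Each
melanin voxel applies an independent random SU(2) rotation whose rotation
angle is scaled by `scramble_p ∈ [0, 1]`: at 1 the states are Haar-uniform
on the Poincaré sphere (expected DOPU ≪ 1 for a 3×3 kernel), at 0 nothing
is scrambled. `scramble_p` is an abstraction of melanin packing density;
the quantitative mapping between melanin concentration and DOPU is not
established in the literature, so no calibration is claimed. Default 0.9
(strong scrambling, clearly separating the band from retina at DOPU ≈ 1).

**Repeats, flow, noise.** Static voxels reuse the same speckle realization
across repeats; voxels inside choroidal vessel blobs (smoothed-noise
threshold at `flow_fraction`, default 0.2 of the choroid) redraw their
speckle every repeat, giving inter-repeat correlation ≈ 0 versus ≈ 1 for
static tissue. Additive complex detector noise is drawn per repeat and
channel; `snr_db` (default 20) fixes the ratio of mean RPE-band signal
power to total noise power `σ_H² + σ_V²`.

**PED.** A spherical-cap (or Gaussian) elevation lifts the RPE band off
Bruch's membrane, with serous fluid in the cavity. The truth channel
`ped_inner_boundary_px` is the posterior surface of the elevated band (top
of the cavity), so `bruch − boundary` equals the fluid elevation exactly
and the Cavalieri volume of a cap phantom can be checked against
`πh(3a² + h²)/6`. Optional `thickening_um` adds extra band thickness at
the apex, tapering with the elevation profile — emulating stacked or
dysmorphic RPE over PEDs, which is what couples thickened-lesion area to
PED volume in cohorts. Optional migration foci are melanin spheres above
the band.

## DOPU

Stokes parameters are computed per repeat (`S0 = |E_H|² + |E_V|²`,
`S1 = |E_H|² − |E_V|²`, `S2 = 2Re(E_H E_V*)`, `S3 = −2Im(E_H E_V*)`),
averaged over repeats, then mean-filtered with a 3 (depth) × 3 (A-line)
kernel inside each B-scan — no averaging across B-scans. Windows are
truncated at edges (mean over the voxels present); padding would fabricate
data. Noise-bias correction subtracts `σ_H² + σ_V²` from ⟨S0⟩ and
`σ_H² − σ_V²` from ⟨S1⟩. The ratio is clipped to [0, 1]; voxels with
corrected ⟨S0⟩ at or below `s0_floor` (default 3× total noise power) are
invalid, carry 0, and are excluded from statistics and from F_RPE
(noise-dominated DOPU is unstable). Whether the original instrument
averages repeats before windowing is not public; a flag
(`average_repeats_for_dopu`) exposes both choices, default on.

The implementation's window sums accumulate shifted slices in a fixed
offset order, so a scalar reference loop reproduces them bit-for-bit —
the oracle-equivalence tests assert exact equality, not approximate.

## Attenuation coefficient

The depth-resolved single-scattering estimator
`μ[z] = I[z] / (2Δz Σ_{z'>z} I[z'])` is used on the coherently composited
intensity, with three refinements:

- **Noise-floor subtraction.** The composite's additive-noise floor
  (`(σ_H² + σ_V²)/N_repeats`) is subtracted first. A constant floor does
  not decay, so it would otherwise inflate tail sums and saturate the tail
  fit.
- **Geometric tail extrapolation** (on by default). The finite-depth sum
  misses the energy below the last row; on a perfect exponential this
  inflates μ by the missing-tail fraction (≈15% at the midpoint of the
  default grid), which would dominate the error budget. The decay ratio is
  fitted on the last 16 rows as the **median of per-row ratios** — exact on
  a pure exponential and robust to a layer boundary inside the window —
  and the implied geometric tail is appended. The fitted ratio is capped at
  0.995. With this, the closed-form exponential check passes at the
  discretization error (~0.8% for μ = 2 mm⁻¹, Δz = 4 μm).
- **Pre-averaging.** Intensity is mean-filtered with a 3 (depth) × 7
  (A-line) kernel before the ratio. Raw speckle intensity is
  exponential-distributed (100% relative sd), which makes per-voxel μ — and
  anything thresholded on it — unusable; 21 samples bring the relative sd
  to ~22%. The axial extent stays at 3 so the melanin band's edges are not
  smeared by more than ±1 px. For pure estimator-precision studies a 9×9
  window (~10% median relative error at 20 dB) is appropriate and is what
  the precision tests use.

The bottom 16 rows are flagged invalid regardless (tail too short). μ is
normalized as `μ_norm = min(μ/μ_ref, 1)` with `μ_ref = 10 mm⁻¹`; some
normalization is required for the dimensionless 0.15 F_RPE threshold to be
meaningful, and the native scale of the original index is not recoverable
from the published description, so μ_ref is configuration, logged in every
output.

## Angiography

Noise-corrected complex correlation between adjacent repeat pairs over a
3×3 kernel, per channel:
`c = |Σ E_k E*_{k+1}| / sqrt((Σ|E_k|² − Nσ²)(Σ|E_{k+1}|² − Nσ²))`,
averaged over pairs and channels; decorrelation = 1 − c, clipped to [0, 1];
binary flow at threshold 0.30 (kernel and threshold are package defaults —
not published values). Voxels with nonpositive corrected denominators are
treated as static rather than flow: in F_RPE a false "flow" vote would
erase real melanin, the more damaging error. Per-A-line bulk phase offsets
between repeats are removed first (phase estimated as the argument of the
inner product against repeat 0) so axial bulk motion does not masquerade as
flow. A useful calibration point: for fully decorrelated speckle the
expected correlation over an N-pixel kernel is `sqrt(π/(4N))` (≈0.30 for
3×3), so "full" decorrelation reads ≈0.70, not 1.0 — thresholds should be
read against that scale.

## Melanin quantification

`F_RPE = μ_norm (1 − DOPU) (1 − flow)`, zero wherever any input is
invalid. Thickness = (count of voxels with F_RPE ≥ 0.15 per A-line) ×
axial pitch; no contiguity requirement and no sub-pixel interpolation, so
maps are exact multiples of the pitch. Lesion area = exact count of map
pixels with thickness ≥ 70 μm, intersected with an optional PED-margin
polygon (the phantom supplies it from truth; clinically it is drawn
manually), × pixel area. PED volume = Σ per-B-scan cross-sections ×
B-scan spacing (Cavalieri). Littmann/Bennett scaling multiplies transverse
pitches by `(AL − 1.82)/(24.46 − 1.82)`; it is applied to transverse
dimensions only — axial thickness thresholds are not rescaled. The 0.15
and 70 μm thresholds are the published operating point and are
configurable.

## DOPU synthesis

A 3-level U-Net-style encoder–decoder (~30k parameters: 8→16→32 channels,
3×3 convolutions, average pooling, nearest-neighbour upsampling with skip
concatenation, sigmoid head) is implemented directly in numpy with
hand-written backpropagation and Adam — at this scale a framework is
unnecessary and the dependency footprint stays minimal. Inputs are
per-volume log-scaled intensities affinely mapped to [0, 1] by their
1st/99th percentiles; targets are measured DOPU with invalid voxels set
to 1 (no depolarization evidence). The loss is per-pixel binary
cross-entropy treating DOPU as a Bernoulli mean (MSE available behind a
flag). Patches (64×64, stride 64) are split subject-wise 8:2; leakage is
structurally impossible (the dataset constructor rejects any subject in
both splits). Inference tiles B-scans with 50% overlap and uniform
averaging to avoid seams; outputs are clipped to [0, 1]. Defaults: 6
epochs, batch 16, Adam lr 2×10⁻³, every 2nd B-scan — a desk-scale
operating point that trains in ~2 minutes on one CPU; none of the original
network's hyperparameters are public, so these are declared, not inferred.

Paired evaluation across a cohort uses the Wilcoxon signed-rank test
(exact null for n ≤ 25, validated in-tree against brute-force sign
enumeration) and Pearson correlation.

## Study conditions used by the test suite

- Parameter recovery: 20 eyes at 64×128×256, 20 dB, scramble 0.9, band
  thickness drawn from 24–64 μm.
- Synthesis: 12 subjects at 16×128×256 (16 B-scans keep training data and
  inference time desk-scale), same physics; held-out mean absolute DOPU
  error and original-vs-synthesized thickness correlation are evaluated on
  that cohort.
- Cohort reporting: 22 PED eyes at reduced grid with apex thickening
  60 μm, heights 80–220 μm, radii 0.7–2.0 mm.

## What the phantom does not capture

Real tissue has depth-dependent speckle correlation, birefringent
structures (retinal nerve fiber layer, sclera), projection artifacts in
angiography, eye motion beyond a per-repeat bulk phase, axial point-spread
blur, and melanin whose scrambling strength varies with packing density.
Passing tests on the phantom therefore demonstrates algorithmic
correctness — the estimators recover what the model planted, at known
noise — not clinical performance. The synthesis result in particular is
easier on the phantom than in clinic: here the melanin band is the
dominant bright layer, so intensity carries strong information about where
DOPU is low. The systematic *underestimation* of synthesized thickness
relative to measured thickness that the tests exhibit is, however, the
same direction of bias reported for the clinical procedure.

## Numerical details

- Raw fields are complex64; all derived statistics are computed in
  float64. Stokes accumulation loops over repeats to bound temporaries.
- Seeded `numpy.random.default_rng` everywhere; one seed fixes a phantom
  bit-for-bit, and pipeline reruns are byte-identical.
- Degenerate inputs: all-zero A-lines are invalid in μ (no division by
  zero); an all-invalid DOPU volume warns; crossing PED surfaces are
  rejected with the offending (B-scan, A-line); empty en-face depth ranges
  and non-increasing colormap ranges are rejected.
- Every derived HDF5 dataset is stamped with the SHA-256 hash (12 hex
  chars) of the run configuration; configs reject unknown keys.
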