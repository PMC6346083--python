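# Methods

This note records the models implemented in `oralphan`, their
assumptions, the parameters that matter, and the design decisions taken
where the procedure was genuinely open.

## The digital phantom

The phantom is a voxelization of a spherical oral test object: an acrylic
shell (outer Ø 200 mm, inner Ø 180 mm, 10 mm wall) filled with
CuSO₄ (0.7 g/L) / NaCl (3.6 g/L) solution, an 11-tooth arch in the axial
mid-plane, Teflon rods for spine/mandible, and 0–2 metallic restorations
replacing normal teeth (`left_single` at retainer slot 8,
`top_middle_double` at slots 5–6; the slots are configurable because the
physical design does not fix them). Teeth are cylinders with
hemispherical caps (radius 3 mm, half-height 4 mm) on a semi-elliptical
arch (semi-axes 32 × 26 mm), spaced so that all eleven remain separate
connected components at millimetre grids. The two physical hemispheres
and their water-tight lid are modelled as one combined volume: the lid
hardware has no imaging consequence used anywhere downstream.

Material table (g/cm³, HU, ms, ms, ppm, relative spin density):

| material          | density | HU    | T1  | T2  | χ     | ρ    |
|-------------------|---------|-------|-----|-----|-------|------|
| air (label 0)     | 0.0012  | −1000 | 1   | 1   | −9.0  | 0    |
| acrylic           | 1.20    | 120   | 400 | 30  | −9.0  | 0.02 |
| solution          | 1.00    | 0     | 300 | 250 | −9.05 | 1.0  |
| teflon (vertebra) | 2.16    | 1013  | 100 | 1   | −9.0  | 0    |
| teflon (rod)      | 2.16    | 890   | 100 | 1   | −9.0  | 0    |
| tooth             | 2.00    | 2350  | 150 | 1   | −9.0  | 0.10 |
| restoration       | 4.50    | 3095  | 1   | 1   | +180  | 0    |

The measured anchors are the restoration (3095 HU), the cervical-vertebra
mimic (1013 HU), columnar Teflon (890 HU, 2.16 g/cm³) and acrylic density
(1.20 g/cm³). The unprinted values are design choices: solution T1 is set
short (300 ms) because the CuSO₄ doping exists precisely to shorten T1;
tooth HU is 2350 — the midpoint of the 1200–3500 HU oral segmentation
window and a plausible enamel/dentin composite — so that the fixed window
cuts the partial-volume edge of a reconstructed tooth at the 50% level,
i.e. at the true boundary. (With a tooth at 1600 HU the same window cuts
at the 75% level and systematically erodes the mask at millimetre
voxels.) Susceptibilities of all non-metal materials are water-like so
the restoration (+180 ppm, titanium-like) is the sole artifact source;
this mirrors the study design in which implant-free scans serve as
artifact-free references. Real air is +0.4 ppm, so a physical phantom
additionally shows mild shell-boundary distortion that this simulator
deliberately omits.

## CT simulation

Each axial slice is forward-projected with the parallel-beam Radon
transform (attenuation `μ = μ_water(1 + HU/1000)`, `μ_water = 0.02/mm`),
corrupted, and reconstructed by ramp-filtered back-projection. Fan/cone
geometry is unnecessary: artifacts are used only as input corruption, and
parallel-beam FBP reproduces the streak/dark-band morphology. Corruption:

- beam hardening as the water-correction residual `p' = p − βp²` on line
  integrals (default β = 0.02; streak magnitude has no printed reference
  value and is an explicit calibration knob);
- photon noise: detector counts ~ Poisson(fluence · e^(−p')), zeros
  clipped to 0.25 counts before the log so starved rays through metal
  yield streaks, never infinities. Default fluence 10⁵/bin at the
  reference 120 kVp / 190 mA protocol; kVp and mA only rescale fluence
  linearly (no energy-resolved physics).

With corruption off, the mean reconstructed HU of each material region
agrees with the table to <5% at 1 mm voxels, and the solution region
round-trips to <30 HU mean absolute error. The streak signature is
measured as the variance of the paired (metal minus no-metal) difference
in a solution annulus; it is monotone in β.

## MR simulation

**Field map.** The ppm susceptibility map is convolved with the unit
dipole kernel in k-space, `D(k) = 1/3 − k_z²/|k|²` with `D(0) = 0` (B0
along z), then scaled by `(γ/2π)·B0·10⁻⁶` to Hz; 32 voxels of edge
padding suppress FFT wrap-around. A uniform χ map gives identically zero
field. Against the closed-form dipole field of a rasterized sphere the
map agrees to ~2% (95th percentile <5%) beyond 3 voxels from the source;
single-voxel sources show band-limit ringing at mid radii, which is the
expected discretization behaviour of the Fourier method.

**Signal.** SE: `ρ(1−e^(−TR/T1))·e^(−TE/T2)`; metal has ρ = 0 (no
MR-visible protons in titanium). GRE: spoiled steady state
`ρ sinα (1−E1)/(1−cosα E1) · e^(−TE·R2*)` with
`R2* = 1/T2 + Δf_spread/2`, where `Δf_spread` is the maximum
off-resonance difference to a face neighbour (Hz). The spread/2 form —
rather than a Lorentzian π·spread — reflects that the neighbour
difference overstates the true intra-voxel range on a coarse grid;
with π·spread the TE = 50 ms shadow engulfs the entire phantom and the
echo-time sweep loses its dynamic range.

**Displacement.** Each voxel's signal moves along the frequency-encode
axis (default x, configurable) by `Δf/BW` pixels, forward-splatted with
linear interpolation: coincident arrivals accumulate (pile-up), vacated
voxels empty (void), and signal shifted beyond the FOV is discarded and
counted — total displaced plus discarded signal equals the ideal total
exactly. Phase-encode and slice axes are undistorted.

**Noise.** Per acquisition, complex Gaussian noise with
`σ = 0.118·√(BW/290)` is added and magnitude-detected; NSA = 16
acquisitions are averaged. The anchor 0.118 is calibrated once so the
mid-sweep SE acquisition (290 Hz/px) gives SNR ≈ 40 in the solution; no
SNR is printed for the physical scans, so this is the one free noise
constant. The σ ∝ √BW law makes the measured SNR ratio between 145 and
490 Hz/px equal √(490/145) ≈ 1.84.

## Segmentation

- **Threshold:** foreground = 1200 ≤ HU ≤ 3500 (the oral window).
- **Fuzzy c-means:** standard alternating optimization of
  `J_F = Σ u_ab^F (x_a−c_b)²` — membership update
  `u_ab = 1/Σ_k (|x_a−c_b|/|x_a−c_k|)^(2/(F−1))` (computed on distance
  ratios scaled by the row minimum, so extreme spreads cannot overflow),
  center update `c_b = Σu^F x / Σu^F`, stop at `max|Δu| < ε`. Defaults
  c = 3, F = 2, ε = 10⁻⁵, 200 iterations, order-invariant
  k-means++-style seeding on the sorted values; coincident centers are
  re-jittered once from the seed, then reported as degenerate. Each
  alternation is an exact block minimization, so the objective trace is
  non-increasing by construction.
- **ROI → FCM → threshold:** the FCM step runs inside a compact oral
  region (`oral_roi`: the padded bounding box of the window mask) that
  deliberately contains local background. The cluster with the highest
  center is the teeth/restoration class. Because the hard
  background/teeth membership boundary falls at the midpoint of the two
  centers — below the fixed 1200 HU window edge — the FCM mask recovers
  noise-flipped boundary voxels and never does worse than the plain
  threshold. Running FCM on the pure-foreground window mask instead can
  only erode it; the ROI choice is what makes the refinement a
  refinement.
- **MR metal region:** the solution compartment is delineated on a
  1.5-voxel-smoothed image (half the 99.5th percentile), its median and a
  quantile-based σ̂ are estimated from off-arch slices (so the artifact
  cannot inflate its own detection threshold), and void (< med − 3σ̂,
  inside the filled interior) plus pile-up (> med + 3σ̂ within 2 voxels
  of a void) are closed and size-filtered (≥5 voxels). On artifact-free
  images the false-positive rate in the solution is ≪1%. For fusion,
  `artifact_mask_vs_reference` grows this footprint by 2 voxels and
  subtracts the (dilated) footprint of the implant-free reference scan,
  excluding structures that are legitimately signal-free (normal teeth,
  Teflon rods) — the same role the normal dental scans play as references
  in the physical protocol.
- **Auto contour:** morphological geodesic active contour on the inverse
  Gaussian gradient (σ = 1, balloon = −1, no extra smoothing), seeded at
  or around the lesion; on a sharp synthetic sphere it recovers the
  boundary with Dice ≈ 0.98 and the analytic volume to ~2%.

## Registration and fusion

Rigid 6-DOF only (the phantom is rigid). Mattes mutual information
(50 bins, seeded 40% random sampling), regular-step gradient descent with
physical-shift scaling, 3-level shrink pyramid (4/2/1). Random sampling
is essential — dense sampling exhibits grid-aligned interpolation extrema
that bias the optimum — but a single sampling occasionally settles a few
tenths of a degree off, so the optimization restarts from three seeded
samplings and the candidate scoring best under a common held-out sampling
is kept. The MR matrix is down-sampled to the CT matrix beforehand when
needed (560 → 512 at preserved 240 mm FOV, anti-aliased linear
interpolation). A known 5°/4 mm offset between simulated CT and MR is
recovered to ≲0.4° and ≲0.3 mm over all probed noise seeds; optimizer
failure returns the identity flagged `success=False`.

Fusion replaces MR content only inside (a) the CT teeth mask resampled
into MR space (nearest-neighbour; intensities via a linear HU→signal map,
by default flat at the observed MR tooth level so pasting is neutral
where the MR already depicts teeth correctly) and (b) the artifact mask,
which is inpainted with the image's own robust solution median, feathered
over ~2.5 voxels so no seam is created; a 2-voxel guard band around the
teeth is left untouched because their dark partial-volume halo is
anatomy, not artifact. Every voxel outside the two masks is bit-identical
to the input. A nearest-shell fill was tried and rejected: around wide
GRE dephasing shadows the shell itself is darkened and the fill inherits
the artifact.

## Metrics

MSE, RMSE = √MSE, PSNR = 10·log₁₀(L²/MSE) (L defaults to the reference
max−min), MAE, Pearson cross-correlation (NaN for constant images), and
SSIM with the standard denominator `(μx²+μy²+c1)(σx²+σy²+c2)`,
stabilizers c1 = (0.01L)², c2 = (0.03L)², 11-tap Gaussian window
σ = 1.5, mean-pooled (via scikit-image). Artifact extent: |test−ref| is
smoothed by a 1-voxel Gaussian, thresholded at median + 3·MAD-σ of the
*raw* off-arch difference (the smoothing stabilizes the footprint; the
threshold stays at the raw noise level), opened once, and the largest
connected component's per-axis bounding extents (mm) and volume (ml) are
reported. Extents are reported on grid x/y/z with the frequency-encode
axis recorded in metadata, since the physical study reports extents on
different axis pairs in different places.

## Pipeline and reproducibility

`StudyConfig` is a flat, YAML-serializable record; all stage seeds derive
from the single study seed via seed-sequence spawning, and the manifest
stores the config hash plus SHA-256 digests of every produced array, so
two runs of one config are bit-identical. The default desk-scale grid is
96³ (2.5 mm over the 240 mm FOV): fine enough to resolve every tooth and
the artifact sweeps while a full study (3 implant configurations × 1 CT ×
20 MR volumes, segmentation, registration, fusion, tables) completes in
a few minutes on one CPU; property checks and the acceptance analysis run
at 128³ (1.875 mm), and 256³ is intended for figure-quality volumes.

## What the synthetic data does and does not show

The generator reproduces the *mechanisms* — streaks from beam hardening
and photon starvation, susceptibility voids/shifts/pile-up scaling with
1/BW and with TE, SNR ∝ 1/√BW — with ground truth attached, so the
pipeline's properties (artifact monotonicity, segmentation fidelity,
registration recovery, fusion improvement) are testable exactly. It does
not reproduce the physical scans' absolute artifact sizes (those depend
on implant alloy, scanner shimming, coil and sequence details that are
not desk-derivable), k-space/EPI effects, B1 inhomogeneity, slice
profiles, scatter, or the air bubbles and lid hardware of the physical
object. Passing tests therefore validate mechanism and procedure, not
millimetre-for-millimetre agreement with any particular scanner.

Known limitations: at grids coarser than ~2 mm the GRE TE ≥ 45 ms fusion
gain can be marginally negative (the teeth halos are under-resolved and
the repair touches correlated anatomy); the pipeline's property report
surfaces this honestly, and at the 128³ study grid every sweep member
gains. Intensity-only FCM carries no spatial regularization by design.
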