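# oralphan

A digital CT/MR oral phantom for studying — and correcting — the metal
artifacts that dental restorations cause in head-and-neck imaging.

Metallic dental implants corrupt both modalities used in dental and
head-and-neck radiology: on CT they cause bright streaks and dark bands;
on MR, their magnetic susceptibility (titanium is paramagnetic, amalgams
can exceed +300 ppm) perturbs the B0 field and produces signal voids,
geometric pixel shifts along the frequency-encode direction, and bright
pile-up artifacts. The artifact footprint shrinks with increasing
spin-echo receiver bandwidth and grows with gradient-echo echo time.
`oralphan` provides a fully synthetic, ground-truth-complete version of a
physical oral phantom study of these effects:

- **phantom** — a voxelized 200 mm acrylic sphere (10 mm wall) filled with
  CuSO₄/NaCl-doped water, an 11-tooth dental arch in the axial mid-plane
  with 0–2 metallic restorations (`none`, `left_single`,
  `top_middle_double`), and Teflon rods mimicking spine and mandible.
  Every downstream result can be scored against the label map.
- **ct_sim** — parallel-beam Radon / filtered-back-projection CT with
  beam-hardening (`p' = p − βp²`) and Poisson photon-starvation streaks
  (120 kVp, 190 mA, 1 mm slices, 240 mm FOV protocol).
- **mr_sim** — B0 field maps from the susceptibility map via the Fourier
  dipole kernel `D(k) = 1/3 − k_z²/|k|²`,
  `Δf = (γ/2π)·B0·10⁻⁶·(D ⊛ Δχ)`; SE signal
  `ρ(1−e^(−TR/T1))e^(−TE/T2)` and spoiled-GRE signal with a T2* term from
  the intra-voxel field spread; off-resonance displacement by
  `Δf / BW` pixels with pile-up and void from conservative forward
  splatting; Rician noise with `σ ∝ √BW` (so SNR ∝ 1/√BW), 16 averages.
  Sweeps: SE bandwidth {145…490 Hz/px}, GRE TE {8…50 ms} at 3 T.
- **segment** — oral-window CT thresholding (1200–3500 HU), fuzzy c-means
  refinement minimizing `J_F = Σ_a Σ_b u_ab^F ‖x_a − c_b‖²` with the
  `max|Δu| < ε` stopping rule, MR metal-region (void + pile-up)
  extraction, and morphological geodesic active contours for artifact
  volumetry.
- **register / fuse** — 560→512 matrix down-sampling, Mattes
  mutual-information multi-resolution rigid registration (SimpleITK), and
  fusion: CT teeth pasted into MR, artifact regions inpainted with
  solution signal, producing an artifact-free MR composite.
- **metrics** — MSE, RMSE, PSNR, MAE, Pearson cross-correlation and SSIM
  (standard form, `c1=(0.01L)²`, `c2=(0.03L)²`, 11-tap Gaussian window),
  plus artifact extent (mm) and volume (ml) measurements.
- **pipeline** — the whole study end-to-end with seeded, bit-reproducible
  manifests, and a property report (artifact monotonicity, fusion
  improvement).

## Worked example

```python
import numpy as np
from oralphan import (PhantomGeometry, build_phantom, compute_field_map,
                      simulate_mr, simulate_ct, MrSequence,
                      threshold_segment, artifact_mask_vs_reference,
                      fuse, fidelity, artifact_extent, RigidTransform,
                      ground_truth_mask, dice)

left = build_phantom(PhantomGeometry(implant_config="left_single"), spacing=1.875)
none = build_phantom(PhantomGeometry(implant_config="none"), spacing=1.875)
field = compute_field_map(left)                      # Hz at 3 T

img = simulate_mr(left, field, MrSequence.se(145), seed=11)
ref = simulate_mr(none, None, MrSequence.se(145), seed=12)
print(artifact_extent(img, ref).extent_x)            # 71.25  (mm)

ct = simulate_ct(left, beam_hardening=0.0, photon_fluence=np.inf)
teeth = threshold_segment(ct)                        # 1200-3500 HU window
print(dice(teeth, ground_truth_mask(left, {"tooth", "restoration_metal"})))
                                                     # 1.0

amask = artifact_mask_vs_reference(img, ref)
fused = fuse(img, ct, teeth, RigidTransform(), amask).fused
print(fidelity(img, ref).ssim, fidelity(fused, ref).ssim)
                                                     # 0.6446 0.6452
```

The artifact x-extent of 71 mm at the lowest bandwidth (145 Hz/px) falls
monotonically to 28 mm at 490 Hz/px; fusion raises the SSIM against the
implant-free reference for every sweep member.

The full study (three implant configurations × one CT × twenty MR
volumes, segmentation, registration, fusion, report tables) runs with

```sh
oralphan run -o out/ --seed 42
```

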