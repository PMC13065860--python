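# mammoiq

Phantom-based physical image-quality metrics for mammography.

Quality assurance of digital mammography (DM) and of synthesized 2-D views
reconstructed from breast tomosynthesis (SM) rests on objective metrics
measured from repeated phantom acquisitions. `mammoiq` implements the full
desk-side pipeline for medical physicists and detector researchers:

- **SNR maps and nonuniformity** — pixelwise SNR = mean/SD over repeats;
  the nonuniformity index over block means,
  NUI = (max − min)/((max + min)/2), quantifies spatial SNR variation.
- **Noise power spectrum** — NPS(fx, fy) = ½ · ΔxΔy/(NxNy) · ⟨|DFT{ROI_n −
  mean}|²⟩ from subtraction noise images, with radial and axial 1-D
  profiles, anisotropy ratios NPS_x/NPS_r and NPS_y/NPS_r, and a Wilcoxon
  signed-rank anisotropy test.
- **Mass CNR** — (PV̄_signal − PV̄_background)/σ_background with the mass
  masked out of its own local background region, robust to edge-enhancement
  halos.
- **Slanted-edge MTF** — subpixel edge regression, composite oversampled
  ESF, error-function model fit ESF(x) = a + b·erf((x−x0)/(σ_e√2)),
  analytic Gaussian LSF, FFT, and f50/f10 readout up to the detector
  Nyquist 1/(2·pitch).
- **Contrast-detail scoring** — a 16×16 gold-disk grid scored by a
  transparent 4-AFC template-matching observer, psychometric thresholds at
  the 62.5% detection level, CD curves, and the inverse image-quality
  figure IQFinv = 100/Σᵢ Cᵢ·D_{i,min}.
- **Synthetic phantoms** — generators for flat-field, slanted-edge, mass
  and contrast-detail stacks with known ground truth, including DM-like and
  SM-like acquisition presets, so every chain is testable without scanner
  access.

Stacks load from DICOM, TIFF or `.npy` files (one image per acquisition,
JSON sidecar for spacing/label).

## Worked example

Measure the MTF of a noisy slanted-edge stack with known ground truth:

```python
from mammoiq import synthetic, mtf

stack, truth = synthetic.gen_edge_stack(
    synthetic.EdgePhantomConfig(angle_deg=1.2, psf_sigma_mm=0.10,
                                noise_sd_adu=5.0, n_images=10, seed=0))
s = mtf.analyze_edge_stack(stack)
print(f"angle = {s.angle_deg:.3f} deg   sigma_e = {s.fit.sigma_mm:.4f} mm")
print(f"f50 = {s.f50:.3f} cycles/mm   f10 = {s.f10:.3f} cycles/mm   "
      f"Nyquist = {s.nyquist:.1f} cycles/mm")
print(f"(ground truth: f50 = {truth['f50']:.3f}, f10 = {truth['f10']:.3f})")
```

```
angle = 1.201 deg   sigma_e = 0.1000 mm
f50 = 1.874 cycles/mm   f10 = 3.416 cycles/mm   Nyquist = 10.0 cycles/mm
(ground truth: f50 = 1.874, f10 = 3.415)
```

The chain recovered the generated 1.2° slant, the 0.10 mm PSF width, and
the closed-form f50 = √(ln2/(2π²σ²)) ≈ 1.874 cycles/mm of a Gaussian MTF —
at 1% noise, from 10 pooled frames. SNR uniformity works the same way:

```python
from mammoiq import synthetic, snr

flat, _ = synthetic.gen_flat_stack(synthetic.sm_preset().flat_config(seed=0))
m = snr.snr_map_from_stack(flat)
grid = snr.block_means(m.snr_map, 50, 50, valid=m.valid)
print(f"NUI = {snr.compute_nui(grid):.3f}  over {grid.grid_rows * grid.grid_cols} blocks")
```

```
NUI = 0.091  over 64 blocks
```

— the SM-like preset's 10% gain gradient shows up as a nonzero
nonuniformity index.

The same analyses are available from the shell:

```sh
mammoiq synth flat --preset DM --n-images 10 --seed 1 --out dm_flat/
mammoiq snr  --input dm_flat/ --block-px 100 --out snr.json
mammoiq nps  --input dm_flat/ --roi-size 128 --out nps.csv --summary-out nps.json
mammoiq mtf  --input edge_dir/ --direction x --out mtf.csv --summary-out mtf.json
mammoiq report --config run.yaml --out report.json
```

See `docs/methods.md` for the models, defaults and their rationale.

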