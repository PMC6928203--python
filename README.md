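# renaldwi

Quantification chain for renal diffusion-weighted MRI (DWI), exercised
end to end on synthetic digital phantoms: diffusion/IVIM model fitting,
border-displacement quantification of geometric distortion, layer-wise
ROI statistics for the kidney, and exact nonparametric group comparison.

## The problem

Preclinical renal DWI must choose between fast echo-planar readouts
(ss-EPI), which distort anatomy along the phase-encode axis wherever the
B0 field is inhomogeneous, and fast spin-echo readouts (RARE), which
keep anatomy intact but blur along the phase-encode axis through T2
decay over the echo train. Comparing such acquisition strategies needs
three quantitative ingredients, all implemented here:

1. **Diffusion quantification.** Signal decay with diffusion weighting
   b (s/mm²) follows the mono-exponential model
   `S(b) = S0·exp(−b·D)` (pixel-wise log-linear fit, the phantom
   pathway) or the two-compartment IVIM model
   `S(b) = S0·(f·exp(−b·Dp) + (1−f)·exp(−b·D))`, where f is the
   perfusion (flow) fraction and Dp ≫ D the pseudo-diffusion
   coefficient of capillary blood. Because the fast compartment has
   fully decayed by b ≈ 200 s/mm², a nonlinear fit of `A·exp(−b·D)`
   restricted to b ≥ 200 isolates the pure diffusion coefficient D
   (the in-vivo pathway). D is reported in 10⁻³ mm²/s; signals from
   three orthogonal diffusion directions are averaged before fitting to
   account for anisotropy.
2. **Geometric-distortion quantification.** Given binary organ masks
   from a test image A and a reference image B, the border displacement
   `BD = |A Δ B| / P(B)` counts the pixels in the symmetric difference
   of the masks, normalized by the reference perimeter. A rigid d-pixel
   shift yields BD ≈ d·(constant) independent of object size and shape,
   so BD is comparable across tubes, kidneys and resolutions.
3. **Group statistics.** Per-subject scalars are summarised as
   median [min; max] and compared with the exact two-sided Mann–Whitney
   U test (full enumeration for small groups; with n = 7 per group,
   complete separation gives p = 2/C(14,7) ≈ 0.0006). Within-kidney
   measurement quality is summarised by the variability (SD/mean) and
   variance (SD²) of D over layer ROI means.

Since no raw MRI data are distributed, the package generates its own
test objects: a three-tube liquid phantom (oil / water / acetone in
agarose) and a bean-shaped kidney phantom with nested cortex (COR),
outer medulla (OM) and inner medulla (IM) layers, rendered through the
IVIM forward model with known per-pixel ground truth, optional EPI-like
warping, RARE-like echo-train blurring, and Rician noise.

## Worked example

```python
import numpy as np
from renaldwi import (generate_kidney_phantom, add_rician_noise,
                      average_directions, fit_ivim_simplified)

kidney = generate_kidney_phantom()            # 5 b-values × 3 directions
noisy = add_rician_noise(kidney, sigma=20.0, seed=1)   # SNR 50
dmap = fit_ivim_simplified(average_directions(noisy))  # b ≥ 200 s/mm² fit
for lay in ("COR", "OM", "IM"):
    sel = kidney.masks[lay] & dmap.valid
    print(lay, round(float(np.nanmedian(dmap.D[sel])), 3),
          round(float(np.nanmedian(dmap.f[sel])), 3))
```

prints (D in 10⁻³ mm²/s, then the perfusion fraction f):

```
COR 1.604 0.2
OM 1.776 0.15
IM 1.875 0.1
```

— the fit recovers each layer's ground truth (D = 1.61/1.78/1.88,
f = 0.20/0.15/0.10) to within the noise.

The numbered scripts under `analysis/` run the full studies and write
their tables under `results/`:

- `01_simulate_phantoms.py` — generate both phantoms with ground truth;
- `02_fit_diffusion.py` — ADC validation on the tube phantom (noiseless
  fits return the literature coefficients 0.010/2.13/4.21 · 10⁻³ mm²/s
  for oil/water/acetone exactly) and IVIM layer recovery at SNR 50;
- `03_distortion_simulation.py` — shift three objects by 5/10 px and
  tabulate BD: for a 5-px shift BD spans only 3.5–4.0 across a small
  disk, a large disk and the kidney shape (13% spread), approaching the
  analytic disk limit 2d/π under the arc-length perimeter;
- `04_cohort_comparison.py` — the paired 7-subject study: an EPI-like
  warped condition vs a RARE-like blurred condition; the warped
  condition's border displacements (median 0.55 [0.13; 0.92]) separate
  completely from the blurred condition's (0.06 [0.05; 0.12]), giving
  the exact Mann–Whitney p = 0.0006.

A `renaldwi` command-line tool wraps the same stages
(`simulate`, `fit`, `bd`, `bd-sim`, `report`); see `renaldwi --help`.

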