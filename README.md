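# ctdenoise

Denoising of noisy, streak-artifacted CT-like grayscale images with an
**optimized non-local means (ONLM)** filter, alongside the classic
non-local means, bilateral-filter and total-variation baselines, the usual
objective quality metrics (RMSE, MAE, MSE, PSNR), and a fully synthetic,
seeded phantom benchmark for comparing the four methods without any
patient data.

Intended users: researchers and engineers working on low-dose CT image
quality who want a small, self-contained, reproducible reference
implementation of gradient-aware NLM denoising and a harness to compare it
against standard baselines.

## The method

Classic NLM restores pixel *i* as a weighted average over a search window
*U*:

```
P̂(i) = Σ_{j∈U} z(i,j) P(j),   z(i,j) = exp(−‖P(M_i) − P(M_j)‖²_{2,λ} / κ²) / β(i)
```

where ‖·‖²_{2,λ} is the Gaussian-kernel-weighted squared distance between
the similarity patches M_i and M_j (kernel std λ, unit-sum normalization)
and β(i) normalizes the weights to sum to 1. ONLM replaces the weight with

```
Z_K(i,j) = exp(− ‖P_K(M_i) − P_K(M_j)‖²_{2,λ} / κ₁²
              − ‖M_i − M_j‖²_{2,λ} / κ₂²
              − Angle(i,j) / τ² ) / β(i)
κ₁² = α · mean_{j∈U} ‖P_K(M_i) − P_K(M_j)‖²_{2,λ} + c
```

with three ingredients:

* **Gaussian prefiltering** — P_K is the image convolved with a normalized
  (2h+1)×(2h+1) Gaussian template; patch comparison on P_K is far less
  noise-dominated.
* **Gradient-direction penalty** — Angle(i,j) ∈ [0, π] is the angle between
  the neighborhood-averaged central-difference gradients at i and j,
  computed on P_K; candidates across differently oriented structures are
  down-weighted, which preserves edges.
* **Adaptive bandwidth** — κ₁² grows with the mean patch distance inside
  the window, smoothing aggressively in texture-free regions while backing
  off near structure.

The expected-distance relation on noisy images,
`E‖P(M_i)−P(M_j)‖² = ‖P*(M_i)−P*(M_j)‖² + 2δ²` for noise variance δ²,
is available as an optional bias correction of the patch distances.

Metrics follow the standard definitions with the PSNR peak fixed at 255:
`PSNR = 10·log10(255² / MSE)` dB.

## Worked example

```python
import numpy as np
from ctdenoise import (NoiseSpec, compute_metrics, corrupt,
                       default_phantom_spec, make_phantom, onlm_denoise)

clean = make_phantom(default_phantom_spec())          # 128x128 piecewise-constant
noisy = corrupt(clean, NoiseSpec(sigma=20.0, streaks=5, seed=1))
restored = onlm_denoise(noisy)                        # shipped ONLM defaults

for name, img in [("noisy", noisy), ("onlm", restored)]:
    m = compute_metrics(clean, img)
    print(f"{name:6s} RMSE={m.rmse:6.3f}  MAE={m.mae:6.3f}  PSNR={m.psnr:6.2f} dB")
```

prints

```
noisy  RMSE=19.089  MAE=15.380  PSNR= 22.52 dB
onlm   RMSE= 5.501  MAE= 2.839  PSNR= 33.32 dB
```

i.e. on this replicate ONLM cuts the root-mean-square error of the
corrupted phantom (Gaussian noise σ=20 plus five streak artifacts) by
roughly 3.5× and raises PSNR by ~11 dB against the known ground truth.

The same operations are available from the shell:

```bash
ctdenoise simulate --size 128 --sigma 20 --streaks 5 --seed 1 --out phantom
ctdenoise denoise --method onlm --input phantom_noisy.png --output restored.png
ctdenoise evaluate --reference phantom_clean.png --test restored.png
ctdenoise benchmark --out bench/        # four methods, CSV tables + panels
```

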