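# Methods

## Scope and model

The package denoises single 2-D grayscale images on a canonical floating
point 0–255 intensity scale. Four denoisers share one boundary convention
(symmetric / mirror-with-edge padding) and one patch-similarity primitive,
the Gaussian-kernel-weighted squared patch distance

d²(i, j) = Σ_u K_r(u) · (P(i+u) − P(j+u))²,

where K_r is a normalized (2r+1)×(2r+1) Gaussian grid (std λ). Because K_r
sums to 1, no further division by the patch area is applied; the
alternative convention (unnormalized kernel, divide by (2r+1)²) differs
only by a constant absorbed into the bandwidths, so all κ values quoted
here are on the unit-sum-kernel scale.

**NLM.** Raw candidate weight exp(−d²/κ²) over a (2s+1)² search window;
the center pixel's raw weight is the maximum raw weight among its
competitors (the standard self-weight rule — comparing a noisy patch with
itself would otherwise always dominate). Weights are normalized to sum
to 1 and average the raw window pixels, so each output pixel is a convex
combination of its (mirror-padded) window.

**ONLM.** Three multiplicative penalties per candidate: the patch distance
on a Gaussian-prefiltered copy of the image over an adaptive bandwidth
κ₁² = α·mean(window prefiltered distances) + c; the raw-image patch
distance over κ₂²; and the angle between neighborhood-averaged gradients
over τ². The adaptive mean runs over the whole window including the
center (whose distance is 0) and uses uncorrected distances, so κ₁² is a
property of the local image content only.

Gradients are central differences computed on the prefiltered image — the
prefilter exists precisely to stabilize local structure estimates, and at
σ=20 raw-image gradients are noise-dominated; with prefiltering disabled
(h=0) they reduce to raw-image gradients and the ONLM→NLM reduction
identities are unaffected. The angle is evaluated as atan2(|cross|, dot),
mathematically the arccos of the cosine similarity but accurate for
(anti)parallel vectors; a gradient with magnitude below 1e−12 is treated
as orientation-free (angle 0) so flat regions are never penalized.

An optional noise-bias correction max(d² − 2δ², 0) is applied to both
distance terms when a noise variance δ² is supplied (the expected squared
patch distance on a noisy image exceeds the clean one by 2δ²); the clamp
exists because a squared distance cannot be negative. It is off by
default: the benchmark treats the noise level as unknown to the denoiser.

**Aggregation choice.** The method description aggregates prefiltered
pixels (output = Σ Z_K(i,j)·P_K(j)). This package's default instead
averages the *raw* pixels under the ONLM weights (`aggregate="raw"`),
keeping the prefiltered image purely as the similarity/orientation guide:
averaging an already Gaussian-blurred image transfers the prefilter's edge
blur straight into the output, and on the shipped benchmark that one
change moves ONLM from clearly worst to clearly best of the four methods
on RMSE. `aggregate="prefiltered"` retains the literal formulation and is
tested against the same naive oracle.

## Defaults

| parameter | default | units | rationale |
|---|---|---|---|
| search radius s | 10 | px | 21×21 window: enough candidates to average σ=20 noise, still fast |
| patch radius r | 3 | px | 7×7 similarity patch, standard for moderate noise |
| kernel std λ | r/2 = 1.5 | px | patch kernel covers the patch with ~2σ support |
| NLM κ | 10 | intensity | conservative smoothing; keeps NLM the unmodified baseline |
| prefilter h, δ_g | 2, 1.0 | px | 5×5, σ=1 template: variance reduction ≈12× for similarity tests |
| κ₂ | 30 | intensity | κ₂² = 900 ≈ the 2δ² = 800 noise floor of raw patch distances at the benchmark noise level; the spec-free region where the term separates structure from noise |
| τ | 2 | √rad | angle penalty ≈ e^{−π/8} for orthogonal gradients; strong enough to sharpen edges, mild enough not to block averaging in noise-flat areas |
| α, c | 1, 100 | —, intensity² | κ₁² tracks the local mean distance one-to-one with a floor of c = 100 (≈(10)², matching the NLM κ scale) |
| bilateral radius/σ_s/σ_r | 5 / 3 / 30 | px/px/intensity | common CT-scale settings |
| TV weight | 20 | intensity | visibly flattens σ=20 noise without cartooning |
| TV step τ | 0.125 | — | inside the dual projection scheme's convergence bound |

The ONLM bandwidths (κ₂, τ, α, c, aggregation) were fixed by a small grid
exploration on the shipped benchmark conditions (σ=20 streaked phantom)
and then frozen; they are deliberately *not* re-derived per image.

## Synthetic data

`make_phantom` rasterizes piecewise-constant ellipses/annuli; the shipped
128×128 benchmark phantom is a bright skull-like annulus (230) around a
soft-tissue interior (90) with one hyperdense (150) and one hypodense (40)
inclusion on a near-air background (20). `corrupt` adds i.i.d. zero-mean
Gaussian noise (default σ=20) and then a configurable number of straight
additive bands (default width 2 px, amplitude uniform in ±40) at seeded
random positions/angles, clipping to [0, 255] last.

What this emulates: the grainy noise and linear bright/dark streak bands
of low-dose CT reconstructions, at a scale where every method runs in
seconds. What it does not: sinogram-domain physics (streaks here are not
correlated with anatomy), Poisson photon statistics, detector blur,
texture inside tissue classes, or 3-D context. Passing benchmarks
therefore demonstrate correct implementations and the expected *relative*
behavior of the methods under this noise model — not clinical image
quality. The piecewise-constant phantom also flatters TV denoising
specifically; that the gradient-aware NLM still wins is the stronger
result.

Because noise precedes clipping, the realized noise std near 0/255 is
compressed; the generator's statistical tests use mid-gray regions.

## Numerical choices

* **Padding** — all patch extraction, window lookup, gradients and
  prefiltering use symmetric padding; candidates outside the image take
  mirrored values. This keeps border pixels averaging over full windows
  without edge darkening.
* **Vectorized = reference** — denoisers are vectorized per window offset
  (separable kernel correlations); per-pixel reference routines
  (`nlm_weights`, `onlm_weights`, `adaptive_kappa1_sq`) implement the same
  definitions with explicit loops and the test suite pins both against
  independent naive-loop oracles (1e−10 per pixel).
* **Flat limits** — κ = ∞ (and κ₂ = τ = ∞) are accepted sentinels giving
  exact flat-weight limits; std = ∞ yields the uniform kernel.
* **TV solver** — Chambolle-type dual projection with fixed step 0.125,
  isotropic TV, forward differences with Neumann boundary; stops on
  relative iterate change < 1e−4 or 200 iterations, warning (not raising)
  on non-convergence. The logged objective trace is checked non-increasing
  in tests. Very large weights converge slowly toward the constant-mean
  limit; the test of that limit runs 5000 iterations.
* **ANOVA degeneracies** — zero within-group variance yields F = 0, p = 1
  when group means agree (0/0 read as "no evidence of difference") and
  F = ∞, p = 0 when they differ.
* **PSNR** — peak fixed at 255 regardless of image content; MSE = 0 maps
  to a +inf sentinel serialized as `"inf"`.
* **8-bit output** — clip to [0, 255] then round half-to-even, so a
  save/load round trip moves a pixel by at most 0.5; `.npy` files bypass
  quantization entirely for bit-exact fixtures.

## Benchmark design

Replicate i uses seed master+i; every method sees the bit-identical
corrupted image per replicate (paired design), metrics are computed
against the clean phantom, and a one-way ANOVA per metric tests the method
effect. The comparison asserts *ordering* (ONLM vs NLM on mean RMSE/PSNR)
and significance, never absolute metric values, because the quantitative
scale depends entirely on the synthetic noise conditions. Default 20
replicates at 128×128 — a desk-scale size at which the full four-method
benchmark completes in well under a minute.

## Known limitations

* 2-D only; no DICOM, no volumes.
* Noise-level estimation is out of scope: δ² must be supplied by the user
  if the bias correction is wanted.
* The ONLM defaults were tuned at σ=20 on a piecewise-constant phantom;
  heavily textured content or very different noise levels will want κ₂,
  c (and possibly τ) rescaled — as with any NLM-family filter, the
  bandwidths track the noise variance.
* The streak model is additive and geometric, not physical; conclusions
  about artifact suppression transfer only qualitatively to FBP streaks.
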