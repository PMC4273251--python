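# pgbm3d

Data-adaptive BM3D denoising for photon-limited 2-photon microscopy (2PM)
images corrupted by mixed Poisson–Gaussian noise.

Fast intravital 2PM is a low-light technique: only a handful of photons is
collected per pixel, so raw frames are dominated by shot noise, and the
few-pixel bright spots of fluorescent nanoparticles are easily confused with
— or destroyed together with — the noise. `pgbm3d` implements a two-level
BM3D collaborative filter adapted to this regime, together with everything
needed to calibrate, simulate and evaluate it on synthetic data.

## The model and the method

The measurement at pixel *x* is modelled as

```
z(x) = α·η_p(x) + η_G(x),    η_p(x) ~ Poisson(y(x)),  η_G(x) ~ N(μ_G, σ_G²)
```

with gain α > 0 (counts per photon), photon rate y(x) ≥ 0 and a Gaussian
read-out component, so that E[z] = αy + μ_G and Var[z] = α²y + σ_G² — the
noise variance grows linearly with the signal. The pipeline is

1. **Calibration** (`noise_model`): μ_G, σ_G from dark frames; α from the
   slope of the variance-vs-mean regression over a flat-field intensity
   ladder.
2. **Variance stabilization** (`vst`): the generalized Anscombe root
   transform `f(z) = (2/α)·√(αz + 3α²/8 + σ_G² − αμ_G)` makes the noise
   approximately unit-variance AWGN.
3. **Level 1 — basic estimate** (`block_matching`, `transforms`,
   `collaborative_filtering`): for every 8×8 reference block, similar blocks
   are grouped under the noise-adaptive threshold
   `Th_BM = 2σ_η² + Th_offset` (Bienaymé variance of the pixel difference of
   two noisy blocks plus a dissimilarity allowance, default 900 on the
   conventional 255-range scale); each group is transformed by a
   non-standard 2-D Haar decomposition plus a 1-D Haar across the stack, and
   hard-thresholded per subband with the BayesShrink threshold
   `Th_Bayes = σ²/σ̂_y`, `σ̂_y = √max(mean(c²) − σ², 0)`.
4. **Level 2 — Wiener refinement**: matching re-runs on the basic estimate
   with `Th_BM = 2·0.3·σ_η² + Th_offset` (the basic estimate retains ~30% of
   the noise variance); the noisy stack is shrunk by the empirical Wiener
   factor `P²/(P² + σ²)` with the pilot spectrum `P` from the basic
   estimate.
5. **Exact unbiased inverse**: back to intensities through the tabulated
   conditional expectation `y ↦ E[f(z) | y]`.

An **original-mode** baseline (fixed matching thresholds 2500/400 rescaled
from the 255 range, fixed `2.7σ` hard threshold) is built in for paired
comparisons, and a seeded phantom generator (`phantoms_io`) emulates the
relevant 2PM scene classes: epithelial cell mosaics with fine cytoplasmic
granularity, dim backgrounds with 1–2-pixel nanoparticle spots, edge
targets, flat fields and dark frames.

## Worked example

```python
import numpy as np
from pgbm3d import (NoiseParams, DenoiseConfig, make_phantom,
                    simulate_pg_noise, denoise, mse)
from pgbm3d.phantoms_io import DETECTOR_GAIN

truth = make_phantom("cells", size=256, seed=11)        # 12-bit count scale
params = NoiseParams(alpha=DETECTOR_GAIN, mu_g=10.0, sigma_g=25.0)
noisy = simulate_pg_noise(truth / params.alpha, params, seed=3)

recon = denoise(noisy, params, DenoiseConfig(mode="modified"))
print(f"noisy MSE {mse(noisy - params.mu_g, truth):.0f}")
print(f"denoised MSE {mse(recon, truth):.0f}")
```

prints

```
noisy MSE 71347
denoised MSE 13989
```

i.e. at a photon budget of ~100 photons at the brightest pixels the
reconstruction error drops by a factor of about 5 on this phantom. The same
comparison against the baseline (`mode="original"`) and over a grid of noise
levels is automated by `evaluate_curves` /
`pgbm3d.metrics.relative_curves`, which record MSE, multiscale structural
similarity (MS-SSIM) and a gradient-energy sharpness index per run.

The same workflow is available from the shell:

```
pgbm3d simulate  --phantom cells --size 256 --seed 7 --out noisy.tif
pgbm3d calibrate --darks darks/ --flats flats/ --manifest m.json --out params.json
pgbm3d denoise   --input noisy.tif --output out.tif --params params.json --mode modified
pgbm3d evaluate  --phantoms phantoms/ --alphas 0.5,1,2,4 --out results.csv
```

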