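# acer-mri

Noise compensation for coil-intensity-corrected endorectal prostate MRI.

Endorectal coils (ERCs) sit millimetres from the prostate and deliver a
large but strongly inhomogeneous SNR boost. Scanner-side pre-calibration
intensity correction (PURE, Prescan Normalize, …) divides the image by a
coil sensitivity estimate: the signal becomes uniform, but the noise —
uniform before correction — is amplified in proportion to the inverse
sensitivity and grows with distance from the coil. This package
implements **ACER** (Adaptive Coil Enhancement Reconstruction), a
post-processing method that compensates this spatially growing noise
when only the corrected image is available (the usual situation in
retrospective studies), plus the evaluation metrics used to judge such
reconstructions and a seeded synthetic phantom so the whole pipeline is
testable without clinical data.

## Method

The corrected magnitude image is modelled as `V(s) = G(s) + N(s)` with
non-stationary noise. The reconstruction is the Bayesian least-squares
estimate — the posterior mean `Ĝ(s) = E(G(s) | V(s))` — with the
posterior estimated per pixel by importance-weighted Monte Carlo
sampling under a Rician noise model:

1. **Noise model.** MR magnitude data are Rician, `f(x | ν, Φ)` with
   location ν and scale Φ. After correction the scale becomes spatially
   dependent: `Φ(s) = Φ₀ / γ(d(s))`, where `γ(d)` is the ERC SNR-gain
   depth profile (exponential decay from the surface gain `A` to a
   floor, with an abrupt final drop at a cutoff depth; rigid coils
   `A≈5`, inflatable `A≈2`). `Φ₀` is fitted to the image by maximum
   likelihood.
2. **Sampling.** For each pixel `s₀`, candidates `s_k` are drawn
   uniformly without replacement from a search window and accepted with
   probability equal to the Rician likelihood of the candidate's patch
   under the centre patch, normalised so a duplicate neighbourhood is
   accepted with probability one. Everything is computed in log space.
3. **Reconstruction.** Accepted samples form a weighted point-mass
   posterior over their intensities; its mean is `Ĝ(s₀)`.

Because `Φ(s)` grows with distance from the coil, acceptance is more
permissive exactly where the corrected image is noisiest: the method
smooths hardest far from the coil and preserves detail near it.

## Worked example

```python
import numpy as np
from acer import *

spec = PhantomSpec.small(seed=1)          # 128x128, 0.6 mm, sigma0 = 10
coil = CoilModel(coil_type="rigid")       # A=5, tau=20 mm, cutoff 60 mm

truth = make_phantom(spec)
raw = simulate_acquisition(truth, coil, spec.sigma0, seed=1)
corrected = apply_precalibration_correction(raw, coil)

recon = acer_reconstruct(corrected, coil, SamplerConfig(seed=7))

bg = RegionSpec.from_rect("background", truth.shape, 6, 8, 20, 40)
rmse = lambda a, b: float(np.sqrt(np.mean((a.data - b.data) ** 2)))
print(f"RMSE vs truth   corrected: {rmse(corrected, truth):6.2f}   ACER: {rmse(recon, truth):6.2f}")
print(f"background SNR  corrected: {snr_db(corrected, bg):6.2f} dB  ACER: {snr_db(recon, bg):6.2f} dB")
print(f"edge preservation (prostate mask): {edge_preservation(corrected, recon, truth.data > 0):.3f}")
```

prints

```
RMSE vs truth   corrected:   9.13   ACER:   8.67
background SNR  corrected:   5.32 dB  ACER:  22.15 dB
edge preservation (prostate mask): 0.949
```

The reconstruction lowers the error against the ground truth, raises
the SNR of the far-from-coil background region by ~17 dB (that region
carries the heaviest correction-amplified noise) and keeps the edge
preservation statistic Υ near 1 inside the gland — noise is removed
where it dominates while prostate structure is retained.

The same pipeline is available from the shell:

```sh
acer simulate --preset small --seed 1 --out-dir scratch/sim
acer denoise  --input scratch/sim/corrected.nii --output scratch/sim/acer.nii --seed 7
acer metrics  --input scratch/sim/corrected.nii --reconstruction scratch/sim/acer.nii \
              --regions regions.json
acer scores   --table scores.csv
```

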