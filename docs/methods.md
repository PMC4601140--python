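# Methods

This note records the model assumptions, parameter choices and
numerical decisions behind the package, and what the synthetic tests do
and do not demonstrate about clinical data.

## Observation model

A coil-intensity-corrected magnitude image is modelled as
`V(s) = G(s) + N(s)`: `G` is the noise-free reconstruction target and
`N` is zero-centred only in the high-SNR limit — the actual per-pixel
distribution of `V` is Rician with location `ν(s)` and scale `Φ(s)`.
The reconstruction is the posterior mean (Bayesian least squares),
which minimises expected squared error among all estimators.

Assumptions worth stating explicitly:

- **2-D, per-slice processing.** Volumes are handled slice by slice;
  no through-plane information is used.
- **The noise scale depends on position only through coil distance.**
  `Φ(s) = Φ₀ / γ(d(s))` follows from division-by-sensitivity
  correction of uniform complex Gaussian noise. Residual inhomogeneity
  from other sources (B1 transmit, motion) is not modelled.
- **The sensitivity field equals the SNR-gain profile** up to a global
  factor absorbed into `Φ₀`. Only the ratio structure matters to the
  sampler.

## ERC SNR-gain profile

`γ(d) = g∞ + (A − g∞)·exp(−d/τ)` for `d ≤ d_cut`, `γ(d) = g∞` beyond —
an exponential drop to a floor with a final abrupt drop. Published
depth profiles justify the shape qualitatively (a 3–5× gain at a rigid
coil surface, 1.5–3× at peripheral-zone depth, a fraction at the
central gland, and a weaker response for inflatable coils); the
specific parametric family is this package's choice.

Defaults (all configurable through `CoilModel` / the YAML config):

| parameter | rigid | inflatable | units | meaning |
|---|---|---|---|---|
| `A` (surface_gain) | 5 | 2 | – | SNR multiple at the coil surface |
| `τ` (decay_length_mm) | 20 | 20 | mm | e-folding depth of the gain |
| `d_cut` (cutoff_mm) | 60 | 60 | mm | depth of the abrupt final drop |
| `g∞` (floor_gain) | 1 | 1 | – | residual gain beyond the cutoff |

The "1-fold improvement" reported for inflatable coils is ambiguous
(no gain vs. doubling); the default `A = 2` reads it as a doubling and
is flagged to users. Coil geometry is a point or a line segment in
pixel coordinates (0-based, row-major), or a named anchor such as
`bottom-edge`; distances are Euclidean in mm via the pixel spacing.

## Noise-scale estimation

Local Rayleigh ML scales are fitted on windows of a grid decimated by
the window radius (default 8 px, ≥ 25 samples per fit), then `Φ₀` is
the least-squares intercept of `log Φ̂_loc` against `−log γ(d)` with
slope fixed to 1, and the dense field `Φ₀/γ(d(s))` is returned.

Two calibration conventions coexist, deliberately:

- **Signal-inclusive (default).** The ML fit uses all observed
  intensities. Windows containing tissue inflate the local Rayleigh
  scale (for a bright region the fit returns ≈ RMS/√2 of the signal),
  so `Φ₀` comes out several times the true noise scale. This is the
  method's operating regime: the acceptance probability then admits
  enough candidates to smooth strongly, which is what produces the
  large background-SNR gains the method is meant for. On the canonical
  phantom this yields `Φ₀ ≈ 42` for a true `σ₀ = 10`, +17 dB
  background SNR and Υ ≈ 0.95 in the gland.
- **Noise-only (`background_mask=`).** Restricting the fit to
  signal-free pixels recovers the physical noise scale: on simulator
  output at 256×256 the relative error of `Φ₀` is below 1 % for
  `σ₀ ∈ {2, 5, 10}`, both coil types. Use this when a reliable
  air/background mask exists and a calibrated noise map is wanted
  (e.g. the `--scale-field-out` output).

The ML search for the scale is 1-D on `log Φ` (locations treated as
known), bounded to `[10⁻³·s, 10³·s]` with `s` the RMS of the data,
bounded scalar minimisation to 10⁻⁶ relative tolerance. With all
locations zero it agrees with the Rayleigh closed form
`Φ̂² = Σx²/(2n)` to that tolerance. All-zero data raise an error
rather than returning `Φ̂ = 0`, preserving the `Φ > 0` invariant.

## Sampler

Acceptance of candidate `s_k` for centre `s₀` uses the patchwise
Rician likelihood ratio with the centre patch's self-likelihood as the
normaliser and a final clip at 1 (the Rician mode is not exactly at ν,
so without the clip near-duplicates could exceed 1). The noisy centre
patch itself provides the location parameters — no pre-smoothing. The
product over patch pixels is carried in log space with the
exponentially scaled Bessel function; arguments `xν/Φ²` of 10⁶ and
beyond stay finite.

Defaults: `patch_radius = 1` (3×3), `search_radius = 10` (21×21),
`n_accept = 64`, `max_draws = 512`, uniform instrumental distribution
without replacement, mirror padding at borders. The patch size is the
load-bearing choice: a likelihood product over a 7×7 patch at a
correctly estimated noise scale has an expected acceptance of order
10⁻¹² per candidate (each pixel contributes a factor ≈ 0.58 in the
Gaussian limit), which would reject essentially everything; 3×3 keeps
the product selective but workable. `n_accept` counts the centre
pixel, which always enters with weight 1, so the estimator is defined
even when every candidate is rejected.

Randomness: each pixel uses an independent substream seeded by
`(seed, row, col)`, so reconstructions are reproducible bit-for-bit
and independent of pixel processing order.

The posterior is kept as exact weighted point masses (no binning); its
mean is the output. Consequences: the output is a convex combination
of observed intensities, hence always within the observed range, and
the posterior masses sum to 1 to machine precision.

## Metrics

- `SNR = 20·log₁₀(x̄/σ)`, `CNR = 20·log₁₀(|x̄_A − x̄_B|/σ_A)` over
  ROIs, sample standard deviation (`n−1`; the convention is fixed and
  documented since ROI practice varies).
- Edge preservation Υ: Pearson correlation of the mean-centred 3×3
  Laplacians of input and reconstruction over an evaluation mask
  (whole image by default; clinically, the gland). Mean-centring is
  done over the mask, which makes the Υ = 1 identity exact and the
  statistic invariant to intensity offsets and common rescaling.
- Subjective 1–5 scores: rank sum, median, F-pseudosigma
  `IQR/1.349` with linear-interpolation quartiles (the convention is
  fixed for reproducibility; printed score tables are consistent with
  IQR multiples of 0.5).
- Paired significance: two-tailed normal p-value on the z-statistic of
  per-case differences. This is an interpretation — the source only
  states "a two-tailed normal distribution" — and is labelled as such.

## Synthetic phantom

The generator emulates a CIRS-style prostate training phantom: a
5.0×4.5 cm gland ellipse, three 0.7 cm hypointense lesions, a 0.7 cm
urethra disc, in a signal-free background, at 256×256/0.3 mm
(`PhantomSpec.default()`) or 128×128/0.6 mm (`PhantomSpec.small()`,
the canonical test size — same 76.8 mm field of view, chosen so the
full pipeline exercises in seconds). Acquisition adds per-channel
Gaussian noise of std `σ₀` (default 10 intensity units against a gland
intensity of 160) to the sensitised signal and takes the magnitude —
exactly Rician, stationary before correction; correction divides by
the known sensitivity. All draws flow from one seeded generator.

What the phantom does **not** emulate: calibration-scan noise in the
sensitivity estimate (correction here is exact division), partial
volume and texture inside tissue classes, susceptibility and motion
artifacts, the cushion-induced noise band seen in physical phantom
scans, and 3-D effects. Passing tests therefore demonstrate the
mechanics and the noise model — parameter recovery, normalisation,
estimator equivalence, denoising direction under the assumed noise
structure — not clinical image quality, which in the source material
was established on patient data unavailable here.

## Numerical details and degenerate inputs

- Densities at `x = 0` return `−∞` log-density (the leading `x/Φ²`
  factor); zero-intensity pixels are dropped from ML fits since they
  contribute a constant `−∞` independent of `Φ`.
- Candidates whose acceptance probability underflows to exactly 0 are
  never admitted to the sample set (weights must lie in (0, 1]).
- Constant images are fixed points of the reconstruction; constant
  regions make SNR/CNR/Υ undefined and raise typed errors rather than
  returning infinities.
- Ties need no special handling: weights are continuous; candidate
  order is the seeded draw order.
- `force_accept` (u ≡ 0) and a precomputed `scale_field` exist so the
  exhaustive estimator can be compared against a direct brute-force
  weighted mean in tests; they are not part of the clinical path.

## Known limitations

- The acceptance probability inherits the Rician likelihood's upward
  skew at low SNR: in pure-noise regions candidates slightly brighter
  than the centre are favoured, so the background converges toward the
  (nonzero) Rayleigh mean rather than zero. The error reduction there
  comes from variance suppression, not bias removal.
- With the signal-inclusive scale fit, the degree of smoothing depends
  on the tissue fraction of the image; images that are mostly signal
  will smooth more aggressively than mostly-background images.
- The profile parameters (`τ`, `d_cut`) ship as one default per coil
  family; per-vendor measured profiles would be better when available.
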