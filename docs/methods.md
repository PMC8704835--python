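# Methods

## Signal model

A measured standoff Raman spectrum on a uniform wavenumber grid
(ν₁ … ν_p, cm⁻¹) is modelled as

```
x = t + b + n,        t = S g + K_bg y_bg,        n ~ N(0, γΣ)
```

* `S` (p×C): reference signature spectra of the target analytes, one per
  column, unit maximum. These are assumed known — the corrector is built
  for detection systems that carry a signature library.
* `K_bg` (p×M): background basis. Learned from background-only
  measurements: each corpus spectrum is baseline-corrected (ArPLS by
  default), the corrected spectra are stacked as columns, and the left
  singular vectors of the M largest singular values form the basis. The
  corpus is not mean-centred (the basis must represent the background
  signal itself), and each vector is flipped so its largest-magnitude
  element is positive, making the output deterministic.
* `b`: smooth additive baseline, dominated by fluorescence.
* `Σ`: diagonal, per-channel variances; `γ` a scale factor.

Under the two detection hypotheses the corrected spectrum `x' = x − b`
is background-only (`x' = K_bg y_bg + n`) or background + agent
(`x' = K y + n`, `K = [S, K_bg]`).

## The subspace corrector

The baseline is expanded on L broad Gaussian vectors,
`b = K_bl y_bl`, with

* centers `m_l = ν₁ + (ν_p − ν₁)(l−1)/(L−1)` — equally spaced, endpoints
  pinned to the grid limits so baselines rising at the edges of the band
  are representable without exploding coefficients;
* a single shared width `σ = Δm·sqrt(1/(2 ln 2))`, `Δm` the center
  interval, so each vector equals ½ exactly at its neighbours' centers.
  The half-overlap family resolves structure at the Δm scale while
  staying smooth, and all its entries are positive, so no ringing
  artifacts arise (the reason Gaussians are preferred over polynomial or
  truncated bases here).

The augmented model `x = K' y' + n`, `K' = [S, K_bg, K_bl]`, is fitted by
least squares and the baseline estimate `b̂ = K_bl ŷ_bl` subtracted.
Joint estimation is the point: a free-form smoother must decide
channel-by-channel what is "peak" and what is "baseline", whereas here
the signature subspaces hold their own energy and only the Gaussian
span is removed.

**Choosing L.** Larger L resolves finer baseline structure; but once σ
falls below ~252 cm⁻¹ (= 350/(2 ln 2), from the ~350 cm⁻¹ upper bound on
Raman peak widths) the basis can absorb genuine peaks. The package warns
below that floor rather than refusing, since the bound is a guideline.
Default L = 11 on the 375–3500 cm⁻¹ grid (Δm = 312.5, σ ≈ 265 cm⁻¹).

## Comparator correctors

All defaults are stated per correction call; windows and radii are given
in cm⁻¹ and converted to channels on the spectrum's own grid.

| method | parameters (default) | mechanism |
|---|---|---|
| IMF | window 300 cm⁻¹, 5 iterations | iterated sliding-window median (odd channel count, reflected edges) |
| RCF | radius 100 cm⁻¹ | grayscale opening with a circular structuring element (lower rolling-circle envelope) |
| ALS | λ = 1000, α = 0.01 | Whittaker smoother, weight α above / 1−α below the baseline |
| AirPLS | λ = 50 | weight 0 above the baseline, exp(j·d_i/‖d⁻‖₁) below; stops when ‖d⁻‖₁ < 0.001·‖x‖₁ |
| ArPLS | λ = 200, tol 1e-6 | logistic weights from the mean/std of the negative residuals; weight 1 below the baseline |

The shared solve is `(W + λDᵀD) b = W x` with `D` the (p−2)×p
second-difference stencil `[1, −2, 1]` (which annihilates affine
vectors, so constants and ramps are exact fixed points).

## Numerical choices

* **Least squares by QR, never by explicit normal-equation inverses.**
  `K'` is factorized once per batch and reused. Full column rank is
  verified by a condition-number threshold (default 1e10); a
  rank-deficient model raises an error naming the offending blocks
  instead of silently regularizing.
* **Banded Whittaker solve with iterative refinement.** The pentadiagonal
  system is solved by a symmetric banded Cholesky; because conditioning
  grows with λ, one refinement step with an extended-precision residual
  (two for λ > 1e6) is applied. This keeps even λ = 1e12 solves within
  ~1e-8 of the exact solution.
* **ALS termination** stops when the boolean above/below pattern repeats;
  the weight update admits 2-cycles, so the last two patterns are
  checked (max 50 iterations, non-convergence flagged, not raised).
* **ArPLS degeneracy.** When the negative residuals have (near-)zero
  spread — below 1e-5 of the data scale, i.e. effectively noiseless
  input — the logistic weights degenerate into a hard threshold that
  would misclassify any smooth hump as a peak. The iteration stops at
  the current baseline and flags `degenerate_weights`. The 1e-5
  tolerance is orders of magnitude below any physical noise level.
* **ArPLS termination** (not otherwise specified): relative change of the
  weight vector < 1e-6, max 100 iterations.
* **RCF discretization.** The rolling circle is realized as erosion then
  dilation with the structuring element `s(t) = scale·sqrt(r² − t²)`
  (radius r in channels); edges are continued by odd reflection, so an
  affine ramp is reproduced exactly. `intensity_scale` (counts per
  channel of circle height, default 1) fixes the circle's aspect ratio
  in the mixed wavenumber/intensity plane, which the prose description
  of a "rolling circle" leaves open.
* **ASD via orthonormal bases**, not materialized p×p projectors:
  `x'ᵀP⊥x' = ‖x'‖² − ‖Qᵀx'‖²` with Q from a QR factorization. The
  numerator is clamped at 0 (it is a difference of nested projections,
  non-negative up to roundoff). A corrected spectrum lying exactly in
  span(K) gives an infinite statistic with an `in_span` flag.
* **Detection direction**: the agent is declared present when T exceeds
  the threshold — T measures the extra energy the signature subspace
  explains, so large T is evidence *for* the agent.
* **ROC convention**: threshold swept over the pooled statistic values,
  strict inequality at the threshold, curve anchored at (0,0) and (1,1),
  AUC by the trapezoid rule.
* **Noise whitening is opt-in.** The estimator and the detector operate
  unwhitened by default; passing a `NoiseModel` switches the fit to
  generalized least squares by scaling rows with the reciprocal noise
  standard deviation (baseline and corrected spectrum are always
  returned in raw counts).

## Synthetic data

Real measurement campaigns of this kind are not distributable, so
`simulate_study` generates ground-truth scenes with the model's exact
statistical structure:

* **Grid**: 375–3500 cm⁻¹, 947 channels (~3.3 cm⁻¹ per channel).
* **Signatures**: seven synthetic agents (Gaussian/Lorentzian peak
  tables; a target with a CH-stretch main peak near 2930 cm⁻¹ and
  fingerprint subpeaks at 500–1700 cm⁻¹, plus six distractors). All peak
  widths are below 350 cm⁻¹. These are constructed stand-ins, not
  measured spectra.
* **Backgrounds**: positive mixtures of six material archetypes (two
  narrow atmospheric gas lines, four broad substrate signatures). Each
  scene and each training measurement draws its own jittered copy of the
  material library (centers ±5 cm⁻¹, widths ±6%, heights ±10%), so the
  learned K_bg never matches a scene exactly — the model-mismatch floor
  real systems face.
* **Baselines**: maximum 0.8–2× the signal peak, drawn 35% from a
  fluorescence-like family (blue-edge exponential tail plus 1–3 humps of
  FWHM 500–1100 cm⁻¹), 20% from the broad-Gaussian span itself (in-span,
  exercising exact recovery), and 45% from positive polynomials, broad
  sigmoids and exponential decays (out-of-span, exercising robustness).
  The amplitude regime was chosen so that the ratio of uncorrected to
  corrected modeling error lands in the few-fold range typical of real
  campaigns of this kind.
* **Noise**: heteroscedastic Gaussian with a smooth shot-noise-like
  variance profile, median std set by the SNR (default 10: the target's
  main peak is 10× the median noise std, so the main peak is visible and
  subpeaks sit near the noise floor).
* **Counts**: 500 agent / 1000 background scenes by default; the
  acceptance script and tests use 100/200, which keeps the full
  seven-corrector evaluation under a minute while leaving ROC estimates
  stable to a few percent.
* **Training**: K_bg is learned from 40 background-only measurements run
  through the real pipeline (ArPLS correction, then SVD, M = 6).

What the generator does **not** emulate: instrument line-shape
convolution and wavelength calibration error, fluorescence photon-noise
coupling (noise is independent of the baseline level), cosmic-ray
spikes, and any physics of specific laser excitation. Passing tests on
synthetic scenes therefore demonstrates the estimators' statistical
behaviour under the stated model, not instrument-level performance.

## Evaluation metrics and their blind spots

**RMSME** refits the corrected spectrum on `K = [S, K_bg]` and reports
the RMS residual. Two structural properties matter when reading
comparisons:

1. *For the subspace corrector, RMSME equals the joint residual*
   `‖(I − P_K')x‖/√p`, because the refit coefficients coincide with the
   joint ones at the optimum. Hence RMSME can only decrease as L grows
   (a richer half-overlap Gaussian span essentially contains the coarser
   ones). Overfitting at large L shows up as distorted *baseline and
   signature estimates* and degraded detection — not as higher RMSME.
   The L-sweep's interior optimum should therefore be judged together
   with the AUC, and the package reports both.
2. *RMSME is blind to in-span distortion and rewards noise absorption.*
   Any corrector that removes energy lying inside span(K) changes the
   fitted coefficients, not the residual; and a very flexible smoother
   (small λ) lowers RMSME simply by soaking up low-frequency noise. At
   3.3 cm⁻¹ resolution the default λ values make ALS/AirPLS/ArPLS
   near-interpolating: ArPLS attains the lowest RMSME on these scenes
   while its detection AUC collapses (it absorbs part of the broad main
   peak). The subspace corrector is the only method here that combines
   near-floor RMSME with top detection AUC; on these synthetic scenes
   that combination — not RMSME alone — is the meaningful ranking.

## Known limitations

* The corrector requires a signature library and a background basis; it
  is not a blind baseline-correction method.
* Rank deficiency of `[S, K_bg, K_bl]` (e.g. a background component that
  resembles a broad Gaussian) is an error, not a silently regularized
  case.
* The ArPLS degeneracy tolerance (1e-5 of data scale) and the model
  condition-number threshold (1e10) are numerical guards, configurable
  where exposed, and were chosen for double precision on ~1000-channel
  grids.
* ROC estimates on 100/200 scenes carry sampling error of a few percent;
  the generator's seed fixes them exactly for reproducibility.
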