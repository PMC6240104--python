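# Methods

This note documents the models, the numerical choices, and the
limitations of the `maim` package: what exactly is computed, which
knobs matter, and what the synthetic validation does and does not
demonstrate about real data.

## Evanescent-field model

Illumination at a glass–sample interface beyond the critical angle
θ_c = arcsin(n₂/n₁) produces an evanescent field with intensity

    I(θ, z) = I₀(θ) · exp(−z / d(θ)),
    d(θ)    = λ / (4π √(n₁² sin²θ − n₂²)),

with z = 0 at the coverslip and increasing into the sample.  Two models
for the interface intensity I₀ are provided:

- `fresnel` (default): the s-polarized Fresnel transmitted intensity
  4 cos²θ / (1 − (n₂/n₁)²), appropriate for an instrument that rotates
  both beams to s-polarization.  It equals 4 exactly at θ_c and decays
  to 0 at grazing incidence.
- `unit`: I₀ ≡ 1, for workflows that treat the excitation strength as
  unknown and let the convex inversion absorb it.  The depth estimate is
  a ratio across angles, so the choice affects absolute intensities far
  more than recovered depths.

Defaults: λ = 488 nm, NA = 1.49, n₁ = 1.518 (immersion oil), n₂ = 1.33
(aqueous; must be overridden with the measured sample index — an index
mismatch distorts both θ_c and d and hence all recovered depths),
pixel 52 nm.  Angles are degrees at every public interface and radians
internally.

The discretized forward model is the K×M system matrix
A[k,m] = I₀(θ_k)·exp(−z_m/d(θ_k)) on an axial grid that defaults to
0–600 nm in 10 nm bins (the method's usable depth volume; 10 nm ≈ ¼ of
the achievable axial resolution).  The matrix is numerically
ill-conditioned by construction — exponentials at 20 nearby decay
lengths — which is why the inversion below regularizes and why its
columns are ℓ2-normalized internally.

## Synthetic phantoms and image formation

The generator produces point-emitter scenes with exact positions:

- **microtubules** — cubic-spline-smoothed random walks across the
  field, sampled every 20 nm along arc with 25 nm Gaussian lateral
  jitter (apparent filament radius); depth varies smoothly along each
  filament inside a configurable band;
- **spheres** — emitters uniform on the lower cap of a sphere touching
  z = 0, z(r) = R − √(R² − r²), populated to a surface density
  (default 400 μm⁻²) up to a configurable cap depth;
- **line pairs** — two dense parallel emitter lines at exact
  separation, for resolution tests;
- **points** — single emitters at chosen depth.

Image formation is scalar and linear: each emitter contributes
brightness · I(θ, z) · PSF(x−x₀, y−y₀), where the detection PSF is a
normalized 2D Gaussian with FWHM = λ_em/(2 NA) (λ_em = λ + 20 nm Stokes
shift) evaluated at the true sub-pixel position over a ±4σ window.  SIM
raw sets multiply the excitation by 1 + m·cos(2π k·r + φ) at the
emitter position, with 3 orientations (0/60/120°) × 3 phases
(0, 2π/3, 4π/3) and |k| expressed as a fraction (default 0.9) of the
detection cutoff 2 NA/λ_em.

Noise is additive Gaussian with σ = (peak noiseless pixel over the
whole stack)/SNR — the "SNR = 30" convention used throughout.  Negative
pixels are kept in stored frames (clipping would distort the noise
statistics the solvers are tested against); clamping happens only after
background subtraction and at display.  Azimuthal ring-TIRF replicates
share the noiseless image and differ only in noise, so azimuthal
averaging reduces σ by 1/√n_azimuth exactly as on the instrument, where
it additionally homogenizes illumination — an effect this scalar model
deliberately omits.

What the phantoms do **not** emulate: Poisson/EMCCD gain noise,
photobleaching, refractive-index heterogeneity, aberrated or
depth-varying PSFs, sample motion.  Passing tests demonstrate correct
inversion of the stated forward model, not robustness to every
instrument nonideality; the experimental depth error reported for real
ground-truth samples is several times the simulated one for exactly
this reason.

## TIRF-SIM reconstruction

Standard frequency-domain processing. Band separation inverts the 3×3
phase-mixing system with nominal phases (0, 2π/3, 4π/3) — phase
stepping is piezo-controlled on the instrument, so a global phase per
orientation is fitted rather than per-frame phases.  Pattern estimation
cross-correlates the center and +1 bands: the peak of the FFT of their
real-space product is searched on a 2× zero-padded grid (half-bin
sampling keeps off-grid peaks from splitting), restricted to an annulus
above 0.3× the OTF cutoff because the scene's own autocorrelation
dominates below; the peak is refined on a two-stage zoomed DFT to
~0.005 pixel, and the complex band ratio over a symmetric overlap
region (where |k| ≈ |k+p|, canceling OTF-model mismatch) yields the
modulation depth and global phase.  A peak is accepted at ≥ 8 robust σ
above the annulus median; the extreme-value floor of the ~10⁴-sample
annulus is ≈ 5–6 σ, so 8 cleanly separates real patterns (measured
≥ 10 σ at SNR 10) from noise.

Degenerate scenes — a single point emitter, or a line pair with content
along one spectral axis only — carry no information to localize the
pattern by correlation; this is a property of the estimator's input,
not a failure mode.  For synthetic raw sets the pattern is known by
construction and `nominal_pattern_estimate` reads it from the metadata
(including the half-pixel phase offset of the pixel-center convention);
`reconstruct` falls back to it with a warning when estimation fails.
The resolution acceptance tests use the construction-known pattern;
estimation accuracy is validated separately on structured scenes
(|k| error < 1% at SNR 30).

The generalized Wiener combination places each band at its true
frequency position on a 2× zero-padded grid (26 nm SR pixels from 52 nm
raw), weights it by its conjugate amplitude × OTF — so side bands drop
out smoothly as m → 0 and the reconstruction degrades to the apodized
Wiener widefield — and divides by Σ|a_b·OTF_b|² + w².  The Wiener
parameter defaults to w = 0.1 (OTF normalized to 1); the assumed OTF is
the diffraction-limited circular-pupil OTF.  A triangular apodization
tapers the spectrum to the extended cutoff |k| + k_OTF.  No
non-negativity is enforced on the SR image; the downstream threshold
mask tolerates small negatives.

## Masking and background

The SR image is thresholded (Otsu by default, or a fixed fraction of
the maximum) and downsampled 2×2→1 by *any*-OR, a conservative choice
that keeps dim peripheral pixels.  Background per frame is the median
of off-mask pixels in sliding windows (32 px ≈ 1.7 μm, larger than
organelle scale, smaller than illumination-flatness scale) interpolated
under the mask.  Background pixels are collected outside the mask
*dilated by 3 px* (≈ one PSF radius): without this guard band the PSF
halo of masked structure leaks into the local median and biases all
depths low by tens of nanometers.  After subtraction, negatives are
clamped and off-mask pixels zeroed; the operation is exactly idempotent.
The mask interface accepts externally supplied masks, so a trained
segmentation tool can replace the threshold without touching the rest
of the pipeline.

## Depth inversion

Each in-mask pixel's K-vector b solves

    min_{f ≥ 0}  ½‖A f − b‖² + μ‖f‖₁

by ADMM with splitting f = g, g ≥ 0 soft-thresholded.  Choices that
matter:

- **Column normalization.**  A's columns are ℓ2-normalized internally
  and compensated on output.  This changes μ's meaning: in the default
  `relative` mode the threshold is μ·‖Aᵀb‖∞ in the normalized system
  (default μ = 0.01), making the regularization scale-free across pixel
  brightnesses; an `absolute` mode applies μ to the original
  coefficients.  μ = 0 gives pure NNLS.
- **Sparsity rationale.**  Membranes and filaments occupy one or two
  10 nm bins per pixel; the ℓ1 term resolves the ill-conditioning of
  the exponential system toward those sparse profiles.
- **ADMM internals.**  ρ starts at 1 with residual balancing (×2/÷2
  when one scaled residual exceeds 10× the other, checked every 10
  iterations); stop when both scaled residuals < 1e−6 or at 500
  iterations.  The x-update reuses one eigendecomposition of AᵀA
  across all pixels and all ρ values, so a whole image solves as one
  vectorized batch; pixels remain mathematically independent and the
  result is bit-identical under pixel reordering.
- **Cross-checks.**  A FISTA-style projected-gradient solver (with
  monotone restart and step halving on divergence) and scipy's
  active-set NNLS (μ = 0 oracle) solve the same objective; the test
  suite holds ADMM to the NNLS optimum within 1e−6 relative objective
  (relative to max(oracle objective, 1e−10) — random underdetermined
  instances fit exactly and make a bare ratio ill-posed).

The per-pixel mean depth is h = Σ z_m f_m / Σ f_m; both per-pixel maps
and pooled ROI profiles are provided, since a single reported "mean
depth" for a structure may be computed either way.  Volume assembly
stacks the profiles into z-slices whose sum reproduces the intensity
map exactly.

## Validation harness

- **Depth RMSE.** Monte-Carlo grids over (true depth × SNR) for a
  bright point emitter: each realization renders the full multi-angle
  stack, pools the 3×3 pixel neighborhood of the emitter (its PSF
  spot), and inverts the pooled K-vector; realizations are solved as
  one batch.  At the standard settings (SNR 30, 20 angles 61.5–71°)
  the near-coverslip RMSE is ~3 nm; RMSE grows with depth and falls
  with SNR.  Ground truth for extended scenes is the PSF-weighted mean
  emitter depth per pixel (the depth an ideal axial reconstruction of
  that pixel would report), with a nearest-emitter alternative.
- **Sphere recovery.** The full pipeline on simulated 4.86 μm
  surface-labeled spheres, followed by a robust (soft-ℓ1, 30 nm scale)
  unweighted least-squares fit of h(r) = R − √(R² − r²) over in-mask
  pixels with h ≤ 400 nm.  The depth cut is ≈1.3× the deepest
  penetration depth: beyond it excitation is marginal and the mask rim
  is halo-dominated, and because the fit amplifies a systematic depth
  offset by roughly R/h ≈ 16, those pixels would otherwise swing the
  recovered diameter by ±0.2 μm.  Intensity weighting is deliberately
  not used — it would let the bright, flat contact region (no curvature
  information) dominate.  The sphere workflow masks at a fixed 5% of
  the SR maximum rather than Otsu, which on the bright-contact/dim-rim
  histogram discards the deep rim.  The sphere is simulated in aqueous
  medium (n₂ = 1.33): the standard 61.5–71° angle set must stay
  supercritical, which an index-matched n = 1.42 medium (θ_c = 69.3°)
  would not allow.
- **Resolution.** Line pairs are declared resolved when the profile
  perpendicular to the lines shows two maxima with a ≥ 20% dip
  (Rayleigh-like).  At 488 nm/NA 1.49 with the pattern at 0.9× cutoff,
  the SIM reconstruction resolves 100 nm separations that the summed
  TIRF image (Abbe limit ≈ 170 nm at λ_em) cannot; the measured
  point-image FWHM halves.

## Reproducibility and problem sizes

Every stochastic routine takes an explicit seed; identical seeds give
bit-identical stacks, reconstructions, and reports.  The shipped
validation uses desk-scale sizes chosen to exercise every code path at
full fidelity: 100 noise realizations for the near-coverslip RMSE,
four spheres on 80×80-pixel fields with ~2–3×10³ emitters each, and
256-pixel fields for resolution phantoms.  All were chosen as the
smallest sizes at which the Monte-Carlo standard errors are comfortably
below the effect sizes being tested.

## Known limitations

- The scalar forward model ignores polarization-dependent emission and
  supercritical-angle emission effects; I₀(θ) beyond s-pol Fresnel is
  out of scope.
- Pattern estimation requires spectrally structured scenes; sparse
  calibration-style targets need the pattern supplied externally.
- No inter-pixel (TV or 3D) regularization: pixels are independent by
  design, which preserves the trivially parallel structure but leaves
  per-pixel depth noise unsmoothed.
- The recovered depth of a pixel over sloped structure is biased
  shallow, because the evanescent excitation weights the PSF-mixed
  emitter population toward smaller z; the sphere-fit depth cut above
  is the practical mitigation.
- Multi-color data are processed as independent per-channel runs; no
  channel registration is performed.
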