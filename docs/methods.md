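# Methods

## Model

A B-mode envelope image of fully developed speckle is modeled as the
magnitude of a complex circular-Gaussian field: the envelope amplitude in a
homogeneous region is Rayleigh(σ) and the intensity (squared envelope) is
exponential with rate 1/(2σ²). A hypoechoic lesion and its background are
then characterized entirely by the intensity ratio R = CR² = σ_L²/σ_B².

Three contrast measures are carried:

* **Cψ** — normalized intensity contrast, `|I_L − I_B|/√(I_L² + I_B²)`.
  With exponential intensities this reduces to `|R − 1|/√(R² + 1)`.
* **CR** — ratio of mean envelope amplitudes, which for Rayleigh pairs is
  σ_L/σ_B; quoted in dB as 20·log₁₀(CR).
* **gCNR** — one minus the overlap of the two amplitude distributions.
  Two Rayleigh densities cross exactly once in the interior, at
  x₀² = 4σ_L²σ_B²·ln(σ_B²/σ_L²)/(2σ_B² − 2σ_L²); the CDF difference
  H = F_L − F_B attains its single extremum there, giving the closed form
  gCNR = |R^(−R/(R−1)) − R^(−1/(R−1))|.

All three are monotone functions of R, so each determines the others. The
bridge f with f(gCNR) = Cψ has no closed form; it is provided as a
bracketed Brent inversion of the exact chain (residual < 1e−10) and as the
four-parameter Gompertz approximation
f(g) ≈ −0.5506 + 1.627·exp(−exp(−3.181·(g − 0.0247))), which stays within
5e−3 of the exact bridge over [0, 1] — far below the sampling noise of any
empirical gCNR estimate.

Detectability is scored as SNR = Cψ·√M·√N and gSNR = f(gCNR)·√M̃·√N and
compared against the Rose threshold 5/√2 ≈ 3.54. N, the number of
independently compounded images, defaults to 1. M = S/S_c counts speckle
resolution cells in the lesion ROI, with the elliptical cell
S_c ≈ π·(res_lat/2)·(res_ax/2).

### Numerical choices in the analytic core

* A relative guard band of 1e−9 around R = 1 returns the analytic limit
  (zero contrast) instead of evaluating the indeterminate forms in the
  intersection and gCNR expressions.
* `cr2_from_cpsi` uses the rationalized root
  R = (1 − c²)/(1 + c·√(2 − c²)), which is free of floating-point
  cancellation at both ends of [0, 1]; the round trip with `cpsi_from_cr2`
  holds to ~1e−12 across the domain. Both roots R and 1/R satisfy |Cψ|;
  the default branch is the hypoechoic one (R ≤ 1), matching the lesions
  this package targets.
* Cψ is signed in principle; the magnitude convention (value in [0, 1]) is
  the default, with the sign available behind a flag.
* Refitting the Gompertz form (`refit_gompertz`) samples the exact
  relation uniformly in its independent variable gCNR by default and fits
  by Levenberg–Marquardt least squares; sampling uniformly in Cψ is
  available. An optional soft-minimax polish (iteratively raising the
  residual exponent) minimizes the worst-case deviation instead of the
  mean square. The fit is deterministic given the grid.

## Empirical estimators

* **Cψ** is always computed on intensity (mean squared envelope per mask);
  **CR** on mean envelope amplitudes. A minimum region size of 10 pixels
  is enforced (configurable).
* **gCNR** uses empirical CDFs on the pooled sample support. The
  population identity gCNR = ΣH_max − ΣH_min runs over the local extrema
  of the CDF difference H, which sit at the density crossings. On raw
  pooled samples every interleaving of the two sample sets creates a
  spurious O(1/n) extremum of the empirical step function (the naive
  plug-in extrema sum tends to 1 for any two continuous samples), so the
  estimator evaluates the extremal span max(H,0).max() + max(−H,0).max().
  For distributions whose densities cross at most twice in the interior —
  Rayleigh pairs and every monotone transform of them — this equals the
  population extrema sum. The estimator is exactly rank-based: strictly
  monotone transforms applied jointly to both samples leave it unchanged,
  bit for bit. A shared-bin histogram overlap (`gcnr_hist_oracle`) is kept
  as an independent cross-check; the two agree within ~0.02 at 10⁴
  samples.
* The ECDF estimator has a positive small-sample bias that is largest for
  nearly identical distributions and decays with the effective number of
  independent samples; on speckle that number is the cell count M, not the
  pixel count, so small lesions read slightly high. This is documented
  behavior, asserted in the tests, and the reason measured points sit
  slightly above the analytic curve at small radii.

## Resolution estimation

Five methods feed S_c; "half maximum" always refers to envelope amplitude
(the −6 dB two-way display convention), so intensity-domain users should
square first.

* **Raw FWHM** of the point-spread function, via linear interpolation of
  the half-maximum crossings of the row/column through the peak. Valid for
  DAS; manipulable (the squared envelope shrinks it by √2 per axis).
* **Histogram-matched FWHM**: a monotone quantile map learned from
  homogeneous speckle of the transformed image against DAS reference
  speckle, applied to the transformed PSF image. The map is learned from
  speckle (not from the point image) because only speckle carries the full
  amplitude distribution; since a bright point target exceeds the speckle
  amplitude range, the PSF is first rescaled so its peak coincides with
  the source maximum — for the power-law transform family the quantile map
  is itself a power law, so this rescaling provably leaves the mapped
  shape and hence the width unchanged.
* **Sparrow's criterion**: the smallest two-point separation at which a
  strict local minimum appears between the points. Just above the limit
  the two maxima migrate inward from the point positions, so detection
  scans the inter-point window for a strict local minimum (after plateau
  compression) rather than comparing against the endpoint values. With
  additive noise a quartic least-squares fit over the peak-to-peak window
  plus a 20% margin suppresses spurious minima. A scan in which every
  separation already shows a dip — which happens for
  delay-multiply-and-sum, where a minimum can always be found between
  beams — or none does raises an explicit "limit outside scan range"
  error instead of returning a number. For two coherent Gaussian
  envelopes of width σ the limit is exactly 2σ.
* **Autocovariance length**: FWHM of the lag-0-normalized, mean-removed
  intensity autocovariance along an axis, averaged over perpendicular
  lines, integer lags up to a quarter of the patch extent. For a Gaussian
  PSF this width equals the PSF FWHM (the field correlation is Gaussian
  with √2 the PSF σ and the intensity covariance is its squared
  magnitude). Invariant under global scaling only; squaring the envelope
  multiplies the width by ≈ 0.929 (corr(I²) = (4u + u²)/5 with u = |ρ|²).
* **Autoinformation length**: mutual information between pixel pairs at
  each lag, estimated from a 16-class equal-mass rank binning of the
  patch, normalized by the lag-1 value; the length is twice the first lag
  (linearly interpolated) where the normalized curve falls below 0.1.
  Rank binning makes it exactly invariant under strictly monotone
  transforms. The plug-in MI estimate carries the Miller–Madow bias
  (K−1)²/(2N); it is subtracted, and values within two null standard
  deviations ((K−1)√2/(2N), from the χ² distribution of 2N·MI under
  independence) are treated as zero so that independent pixels report an
  immediate drop. The lag-1 normalization and full-width factor 2 are
  conventions; the DAS calibration below cancels them for relative
  comparisons.
* **DAS-FWHM calibration**: Sparrow and autoinformation systematically
  predict smaller cells than the FWHM even for DAS, so per axis a scalar
  das_fwhm/das_method is computed once from DAS and applied uniformly to
  every beamformer. The DAS scaled value equals the DAS FWHM by
  construction; relative comparisons between beamformers are preserved.

## Synthetic data generator

The generator replaces an acoustic field simulator at desk scale. A
complex circular-Gaussian scatterer field on a grid oversampled relative
to the pixel grid (≥ 4 scatterer points per PSF FWHM per axis, the fully
developed speckle condition) is scaled by 10^(contrast_db/20) inside the
lesion disk, convolved with a separable Gaussian PSF of configured −6 dB
envelope widths, enveloped, and downsampled. This preserves exactly the
properties the metrics depend on: Rayleigh background envelope,
exponential intensity, lesion/background mean-intensity ratio
10^(contrast_db/10), and an intensity-autocovariance width equal to the
PSF FWHM. It omits diffraction sidelobe clutter, element directivity,
attenuation and depth-dependent focusing; consequently measured Cψ runs
slightly closer to the analytic value than in a physical simulation, and
the clutter-induced degradation of small-lesion contrast is absent.
Passing tests therefore validate the metric chain, not acoustic fidelity.

Defaults are the reference study conditions: 0.440 mm lateral and
0.385 mm axial −6 dB PSF widths (cell area 0.133 mm²), a 2 mm-radius
lesion at −4 dB amplitude contrast centered in a 16 × 16 mm field with
0.05 mm pixels, six-seed ensembles. dB contrast follows the amplitude
convention contrast_db = 20·log₁₀(amplitude scale) = 10·log₁₀(intensity
ratio). Axial coordinates are rows increasing with depth, lateral are
columns, positions in mm at pixel centers.

ROIs use a lesion mask at 80% of the true radius (keeping PSF edge
blur and, in real data, off-axis clutter out of the lesion statistics)
and a background at the same depth band outside a guard band of one PSF
FWHM around the true edge, grown laterally to exactly the lesion pixel
count (an annulus variant exists). Point-target images are rendered on
the oversampled grid, mirroring the practice of scanning point targets
more finely than lesions. Two-point phantoms add complex white Gaussian
noise at a configurable SNR (default 60 dB relative to peak intensity)
before enveloping.

The channel simulator models a focused linear array (defaults: 117
elements at 0.257 mm pitch, 3 MHz, 60% fractional bandwidth, focus at
30 mm, 128 beams 0.234 mm apart) with a Gaussian-modulated cosine pulse.
The transmit field is the coherent sum over elements with focusing delays
(converging on the focus at t = z_f/c); the echo retraces the geometric
receive path with 1/distance spreading on both legs. A single focal-depth
scatterer beamformed with DAS lands on the correct pixel with a lateral
FWHM within 20% of the λz/D diffraction estimate.

## Beamformers

* **DASⁿ** — pointwise envelope power; the canonical metric-manipulating
  family (n = 0.5, 2 in the studies).
* **GCF** — per-pixel weight = spectral energy in the low-frequency region
  of the across-aperture spectrum (DC plus M₀ = 5 bins on each side,
  chosen so a constant snapshot gives exactly 1) over total energy, times
  the DAS sum. For white-noise snapshots the expected weight is
  (2M₀+1)/channels.
* **MV** — Capon apodization on real delayed samples with sliding
  subarrays of length L (default half the aperture), covariance averaged
  over subarrays, diagonal loading ε = Δ·tr(R̂) with Δ = 1/(10L),
  distortionless constraint toward broadside. L = 1 reduces exactly to
  the channel mean; a complex-baseband variant is out of scope.
* **F-DMAS** — pairwise sign(s_i s_j)·√|s_i s_j| coupling via the
  ((Σŝ)² − Σŝ²)/2 identity, then a linear-phase FIR band-pass centered on
  2f_c (passband 2f_c ± f_c/2, taps capped at half the scanline length)
  and envelope via the analytic signal. The depth-resampled effective
  sampling rate c/(2Δz) must exceed 4f_c.

Envelopes are computed from the analytic signal along depth; log
compression (20·log₁₀, max-normalized) is applied only at display/export
time, never before metrics.

## Experiment drivers and problem sizes

`run_lesion_experiment` generates seeded realizations, applies the
configured transforms, measures SNR (always Cψ with the raw transformed
PSF FWHM, the classic definition) and gSNR (rank-based gCNR with the
configured robust resolution method, histogram-matched FWHM by default),
and aggregates mean ± std; reports embed a config hash and the seed list
and are reproducible bit for bit. `run_contrast_detail` sweeps radius ×
contrast grids and reports measured (Cψ, gCNR) pairs against the analytic
curve. The shipped studies use 16 × 16 mm fields (larger for big
lesions), 0.05 mm pixels, 4–16 seeds — sizes chosen so a full study runs
in seconds on one core while keeping ≥ 60 resolution cells in the
reference lesion; statistical conclusions scale with cell count, not
pixel count.

## Known limitations

* The analytic bridge is exact only for Rayleigh envelopes. Adaptive
  beamformers produce non-Rayleigh statistics; for them gSNR is a robust
  ranking tool, not an exact detectability probability. No closed form is
  attempted for other distributions.
* With ~60 effective cells the per-realization spread of gCNR is ~0.1;
  single-realization scores should be read with that uncertainty, and
  small (r ≲ 1 mm) lesions additionally read high from the estimator
  bias.
* The generator's clutter-free speckle makes measured contrasts slightly
  cleaner than physical data; absolute agreement with hardware-derived
  numbers is expected only at the level of the reported bands.
* Metrics operate on envelope data only; pre-envelope (RF) detectability
  is out of scope.
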