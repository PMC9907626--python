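# Methods

This note records the models, conventions, and numerical choices behind
`hsicolor`, in the spirit of a statistics package's model documentation: it
states what is computed and under which assumptions, and which design
choices were genuinely open. It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Calibration model

A spectral-scanning acquisition produces one CCD frame per tuned bandpass.
Per voxel the reflectance estimate is

    R = ρ_white · (S − D) / (W − D)

with `S` the sample counts, `D` the dark frame, `W` the white-standard
counts, and `ρ_white = 0.99` the certified reflectance of the white
standard; flat-field correction (gain map normalised to mean 1, so it is
gain-neutral) is applied to both dark-corrected terms. Conventions the
data do not dictate, chosen once:

- **Negative post-dark counts clamp to 0** with a logged warning — counts
  are physical and residuals below dark are noise.
- **Reflectance clamp ceiling 1.2, not 1.0** — specular/noise excursions
  above the white standard must survive into the uncertainty analysis;
  voxels clipped at the ceiling are counted in provenance.
- **Bands are stored ascending in wavelength** regardless of acquisition
  order; the acquisition order is kept in provenance.
- **Flat field may be single-plane or per-band**; per-band is preferred
  when available. White-reference smoothing/averaging across captures is
  exposed as an option of the caller's calibration set construction, not
  applied silently.
- Pixel coordinates are 0-based, row-major, origin top-left; rectangles
  are half-open `[r0, r0+h) × [c0, c0+w)`.
- `RawFrame` accepts non-negative float counts. The synthetic
  inverse-rendering keeps counts continuous by default so the zero-noise
  calibration round trip is exact to numerical precision; `quantize=True`
  rounds to integers and brings realistic quantization error (~10⁻³ in R
  at typical white levels).

## Colorimetry

Tristimulus values use the CIE 1964 10° observer under D65:

    X = k Σ R(λ) S(λ) x̄(λ) Δλ,   k = 100 / Σ S(λ) ȳ(λ) Δλ

on a 5 nm grid, with `k` computed **over the same integration range as the
sums**, so the perfect diffuser maps to Y = 100 and Lab (100, 0, 0)
exactly, by construction rather than by tolerance.

- **Integration range defaults to 420–730 nm**, the imager's own spectral
  support; a 380–780 nm mode serves full-range spectroradiometer spectra.
  Band values are treated as point samples at band centers and linearly
  interpolated to the grid; no bandwidth (FWHM) deconvolution is applied.
- **Embedded tables.** The observer and D65 tables ship as CSV resources on
  the 5 nm grid, built from the standard published 10 nm values
  (shape-preserving PCHIP interpolation for the color matching functions,
  linear interpolation for the illuminant, which is the conventional
  treatment of intermediate illuminant values). Over the full 380–780 nm
  range they reproduce the official D65/10° white point to better than
  0.01 in X and Z.
- **ΔE is CIE76** (Euclidean distance in Lab); no variant is implied by
  the measurement protocol, and CIE76 keeps ΔE consistent with the
  per-channel analyses. CIEDE2000 is available behind a flag
  (`delta_e(..., method="ciede2000")`, via scikit-image), never default.
- **sRGB rendering** maps the neutral Lab axis exactly onto the gray axis:
  the XYZ→linear-RGB matrix rows are renormalised so the white point hits
  RGB (1, 1, 1) exactly, then standard gamma encoding applies.
  Out-of-gamut channels clip (the clipped fraction is logged); no gamut
  mapping.
- `cube_to_lab` is vectorised (the resampling and quadrature compose into
  one 3 × bands operator) and is contract-tested against a per-pixel loop
  at 10⁻⁹.

## ROI protocol

The study ROI is a 75 × 75 px square (12 × 12 mm at the 160 µm pixel
pitch; `pixel_pitch(12, 75) = 160`) on the right cheek. Landmark detection
is a pluggable backend — synthetic scenes use stored landmarks — and the
ROI anchor is the centroid of a configurable landmark triple (defaults:
jaw points 2 and 4 plus nose-wing point 31 of the iBUG 68-point scheme for
the subject-right cheek, mirrored for the left). The anchor rule is a
package choice recorded in output provenance; what matters for a
repeatability instrument is that the rule is deterministic, not that it
matches any particular historical choice. ROIs that would cross the image
edge shift inward (logged) rather than erroring. Each image is landmarked
independently; there is no cross-time registration. Histograms default to
64 uniform bins and can share pooled edges across a before/after pair so
paired plots are on one scale. Left-cheek support exists throughout but
the replication analysis reports the right cheek.

## Uncertainty model

Spectral noise is modeled as multiplicative Gaussian, fractional sigma
0.02 (consistent with a band signal-to-noise ratio near 47), independent
across bands and pixels — independence is the assumption under which ROI
averaging reduces sigma by √n_pixels and before/after differences add in
quadrature, and those two rules are the ones the downstream analysis uses.
Propagation to Lab is first-order via a central-finite-difference Jacobian
(step 10⁻⁴ in reflectance, robust across the CIELAB `f(t)` kink), checked
against a 10⁴-draw Monte-Carlo oracle at 10% relative. Sigmas are rounded
only at presentation.

Two scales must not be conflated:

- The **instrument-noise propagation** for the default synthetic skin tone
  gives per-pixel sigmas of order (0.14, 0.38, 0.37) for (L\*, a\*, b\*)
  at 2% band noise — the quantity this model can compute.
- The **empirical per-pixel scatter of real skin images** is several times
  larger in a\* because real skin has spatial texture (vasculature,
  pigmentation) that a noise model does not describe. The reference
  chain the package reproduces — per-pixel sigmas (0.3, 2.2, 0.9) →
   75 × 75 ROI mean → quadrature difference → (0.01, 0.04, 0.02) at two
  decimals — therefore takes the empirical per-pixel sigmas as *inputs*;
  its arithmetic (√n and quadrature) is what the package asserts.

## Study statistics

Effects are ranked per instrument–operator–repetition subset:

- **ANOVA.** One-way across products, models treated as independent
  samples (matching the screening protocol; a repeated-measures variant is
  out of scope). Two routes: raw samples (delegated to
  `scipy.stats.f_oneway`) and summary statistics
  (`SSB = Σ nᵢ(x̄ᵢ − x̄)²`, `SSW = Σ (nᵢ−1)sᵢ²`), which agree exactly when
  the summaries derive from the raw data — that exactness is a test
  contract. All-identical data short-circuit to F = 0, p = 1.
- **Tukey HSD at α = 0.01**, gated on the ANOVA rejecting (grouping "if
  warranted"). Pairwise decisions use the studentized range with the
  Tukey–Kramer standard error; the critical value `q(α, k, df)` is cached.
- **Group structure is the compact letter display**: each group is a
  maximal set of pairwise non-significant products and `n_groups` counts
  those sets. For clean separations this equals splitting the ordered
  means at significant gaps. When the sets overlap (A~C and C~B but A≠B)
  the count still reflects the number of distinct letters; the ranking
  string is rendered as a partition by placing the shared product with the
  group whose members it resembles most, and the result carries
  `overlapping=True`. Worked example from the reference summary table
  (second repetition, operator 2, n = 9): ΔL\* means (0.27, 3.95, 1.46)
  with SDs (0.69, 1.04, 0.77) give a critical difference ≈ 1.28 >
  |1.46 − 0.27|, hence `"AC,B"` with 2 groups; the Δa\* summaries give an
  overlapping 2-letter display. The printed 3-group Δb\* result of the
  original analysis is not recoverable from rounded summaries and is not
  asserted anywhere.
- **Correlations.** Ordinary least squares of one subset on its partner,
  Pearson r, Spearman ρ (average-rank ties), percent nonlinearity
  `%NL = 100 (δ₊ + |δ₋|) / MaximumSignal` with δ± the extreme residuals.
  `MaximumSignal` is not standardised; the package uses max |ordinate|
  over the pairs (configurable), which keeps %NL scale-invariant. The
  mean absolute pairwise difference (Δ̄) is reported as *absolute*
  difference, flagged in output metadata; MAE between per-group means is
  reported separately.
- **Boxplot summaries** use linear-interpolation quartiles and 1.5·IQR
  whiskers clipped to the data, with points beyond flagged as outliers.

Design accounting: imager images = models × products × time points ×
repetitions × operators (9·3·2·2·2 = 216); single-spot spectra =
models × products × time points × repetitions (108); independent tests =
products × repetitions × instruments (12). A time-difference data point
exists only when both images of a session exist, so removing 3 images from
distinct sessions leaves 105 of 108 pairs.

## Synthetic data: what it emulates, and what it does not

The generator defines the conditions under which the pipeline is tested:

- **Skin spectra**: baseline + logistic melanin-like rise toward the red
  end + Gaussian hemoglobin-like dips at 545/575 nm. Defaults give Lab ≈
  (60, 13, 18); per-model variation keeps the panel inside a realistic
  skin-tone box (checked by test).
- **Product effects** are solved, not assumed: a three-mode smooth spectral
  modulation (flat lift, blue–yellow ramp, green-band bump) is fitted so
  the Lab shift lands within 0.2 units of the target; unreachable targets
  raise. Default targets (ΔL\*, Δa\*, Δb\*): A (0.3, −0.25, 1.1),
  B (3.9, −2.1, −1.2), C (1.5, −1.5, −2.2) — the magnitudes of a real
  foundation screening, with B strongly brightening.
- **Variance hierarchy**: per-model product response SD 0.9 (persisting
  across repetitions), per-repetition effect drift SD 0.3, per-model-
  repetition baseline drift SD 0.3 (cancels in the time difference),
  per-image landmark jitter SD 2 px clipped at 2 SD (operator effect), and
  2% per-voxel band noise. The model/repetition SDs are tuned so that
  per-product effect SDs over the panel come out near 1 CIELAB unit, the
  scale of real screening data; they are tuning choices, not measurements.
- **Faces are schematic**: an elliptical mask with a stored 68-point
  layout, no photorealism, and — importantly — **no spatial skin
  texture**. Consequences: per-pixel Lab scatter inside the ROI reflects
  only instrument noise (see the uncertainty section), and the simulated
  between-operator agreement is tighter than real reproducibility, where
  re-aiming the ROI on textured skin adds variance. Passing tests
  therefore demonstrate the correctness of the analysis chain and its
  statistical calibration, not the texture-driven components of real
  instrument performance.
- **Determinism**: every stochastic element flows from one seeded
  generator; identical configuration + seed give identical cubes and
  tables.

Problem sizes: simulated studies run at 31 × 64 × 64 (ROI scaled to a
quarter of the frame) for end-to-end statistical checks and 31 × 256 × 256
for desk-scale work; the full-frame 31 × 2016 × 2016 geometry is supported
and its bookkeeping (126 megavoxels) verified without allocation. The
type-I calibration of the gated ANOVA+Tukey pipeline uses 500 null
replicates at the effect-record level; end-to-end ranking recovery uses 6
simulated studies (24 subsets) at cube level.

## Known limitations

- No spatially correlated noise, fixed-pattern systematics, or
  illumination drift (handled by daily calibration on the real system).
- One-way ANOVA ignores that the same models receive all products; a
  mixed/repeated-measures analysis would gain power but is out of scope.
- The ENVI reader accepts band-sequential interleave only.
- Landmark detection on real images requires plugging in an external
  detector backend; the package ships only the deterministic fixture
  backend.
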