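# Methods

## The measurement model

A tumor spheroid probed in backscattering with a low-NA objective yields a
Brillouin spectrum whose inelastic doublet (Stokes/anti-Stokes at ±ω_B) is
modelled by a damped harmonic oscillator,

    I(ν) = B + A·Γ·ω_B² / ((ν² − ω_B²)² + (Γν)²),

with ω_B the frequency shift (GHz), Γ the full linewidth (GHz), A an
amplitude and B a flat background. The spheroid is treated as a biphasic
material: cells with a fixed water/dry-mass volume split (w_cell = 0.70,
d_cell = 0.30) and ECM that is predominantly water (w_ecm = 1.0), with
volume fractions Φ_cell + Φ_ECM = 1. Because the two compartments' shifts
differ by far less than Γ, the measured spectrum shows one merged peak
whose fitted position follows, to first order, the linear mixing rule

    ω_B = ω_ECM·Φ_ECM + ω_cell·Φ_cell.

The package validates this linearization rather than assuming it: synthetic
spectra are generated as genuine two-component DHO sums, and the
acceptance suite checks that a single-DHO fit lands on the mixture within
0.02 GHz whenever the component separation is at most Γ/4.

The composition enters through high-wavenumber Raman: the OH stretching
band area (window 3020–3700 cm⁻¹) is taken proportional to total water
volume, the CH stretching band area (2800–3020 cm⁻¹) to total dry-mass
volume, with one scattering-efficiency constant κ:

    R = A_CH/A_OH = κ·d_cell·Φ_cell / (w_cell·Φ_cell + w_ecm·Φ_ECM),

which inverts in closed form, Φ_ECM = (κ·d_cell − R·w_cell) /
(κ·d_cell − R·w_cell + R·w_ecm). This is the minimal relation consistent
with the compartment assumptions; κ is never assumed but calibrated on
spheroids of known composition — compressed spheroids, whose interstitial
spaces are squeezed out (Φ_ECM ≈ 0), where κ = R_ref·w_cell/d_cell. The
default calibration uses 10 replicate spectra: the calibration enters every
downstream estimate, so its own noise must be driven well below the
per-sample noise.

## Brillouin fitting protocol

1. **Peak location.** Grid peaks on each side of the elastic line (outside
   a |ν| < 2 GHz exclusion window; the elastic peak is never modelled) must
   exceed a prominence of 8× the robust noise level *and* rise 8× noise
   above the side's median — the double criterion rejects pure-noise
   excursions, which can reach 6× noise prominence over a 1000-point trace.
   Each side is then refined by a single-sided DHO fit.
2. **Symmetry restoration.** Stokes/anti-Stokes asymmetry (ν_S + ν_AS)
   signals spectrometer drift; the axis is shifted by half the asymmetry,
   iterating to below 2×10⁻³ GHz (converges in 1–2 steps for drift-scale
   offsets). Offsets beyond 0.5 GHz raise a calibration error rather than
   being silently absorbed.
3. **Final fit.** One DHO over the whole recentered spectrum, trust-region
   least squares (tolerances 10⁻¹⁴, bounds ω_B ∈ (exclusion, ν_max),
   Γ ∈ (0.02, 10) GHz, A, B ≥ 0), initialized from the located peaks, with
   three seeded random restarts on non-convergence. Standard errors come
   from the chi-square-scaled residual covariance; at peak SNR 50 the
   reported se agrees with the Monte-Carlo spread within a factor ~1.5
   (the fit is unweighted, so Poisson heteroskedasticity costs some
   calibration).

## Raman processing chain

Order: baseline → factor calibration → subtraction → integration.

* **Baseline.** Laser-induced fluorescence is removed with a cubic
  least-squares spline fitted only to band-free anchor regions (defaults
  2600–2750 and 3750–3900 cm⁻¹, interior knots every 50 cm⁻¹ inside each
  anchor). Across the knot-free gap between anchors the spline reduces to a
  single cubic, which tracks smooth fluorescence without touching the
  bands.
* **Factor calibration.** The chip (PDMS) and medium subtraction factors
  are determined against an off-chip spheroid reference by band-restricted
  least squares *with free spheroid scales*: in the CH window the sample is
  decomposed over {PDMS, medium, offchip} — the narrow PDMS doublet
  (2905/2965 cm⁻¹) is spectrally distinct from the broad cellular CH
  complex, which pins α_pdms while the free off-chip scale absorbs the
  sample's own CH amplitude; in the OH window the PDMS-corrected sample is
  decomposed over {medium, offchip}, where the distinct OH sub-band balance
  of medium versus spheroid water pins α_medium. A design worth stating
  plainly: a single scalar condition (matching the reference's CH area)
  cannot determine two factors, and matching both band areas exactly would
  force the sample's areas to the reference's and destroy the measurement;
  the free-scale decomposition keeps the sample's own band content while
  recovering the contamination levels exactly on noiseless composites. It
  also makes the result robust to an off-chip reference whose composition
  does not match the sample's.
* **Integration.** Trapezoidal band areas of the decontaminated spectrum
  over CH = [2800, 3020] and OH = [3020, 3700] cm⁻¹ (config-exposed), with
  negative excursions clipped at zero inside the integral only — stored
  residuals keep their sign for diagnostics. Both areas are measured after
  both subtractions: the calibrated α_medium quantifies medium
  *contamination*, so subtracting it leaves exactly the sample's own water
  in the OH window. The OH band's tail under the CH window (~1.5% of A_CH)
  is the dominant systematic; it largely cancels through the κ calibration,
  which inherits the same windows.

A caveat on identifiability: medium water and interstitial water are
chemically almost identical, so splitting them relies on the modest
restructuring of the OH band by solutes (the generator gives the medium a
3420-heavy sub-band balance, 0.42/0.58 versus 0.55/0.45 for spheroid
water). With zero contrast the split is unidentifiable and the medium
factor becomes a convention; real analyses should prefer acquisition
geometries that minimize medium in the probe volume.

## Mixture inversion

ω_ECM is recovered from matched compressed/uncompressed spheroids:
the compressed fit provides ω_cell (its interstitial spaces are
negligible), the uncompressed fit provides ω_B, and the mixing rule is
inverted at the Raman-estimated Φ_ECM. The inversion divides by Φ_ECM, so
it refuses fractions below 0.02 (ill-conditioned) — consistent with
treating estimates below 0.02 as the compressed limit. Uncertainty is
propagated to first order from the two fitted shifts.

## Morphometry conventions

Operations consume segmented 2D label/mask images from the central z-plane;
segmentation itself is out of scope. Aspect ratios are
moment-equivalent-ellipse major/minor from second central moments (labels
under 20 px dropped and counted; collinear shapes excluded with a warning).
The center/periphery split assigns a nucleus to the periphery when its
centroid lies within a band (default: the image's median nuclear major
axis) of the spheroid-mask boundary by Euclidean distance transform.
Marker-positive nuclei exceed the mean + 2 SD of the secondary-antibody
control distribution after normalizing all intensities to the control mean;
both the band and the SD multiplier are configuration parameters, since
only relative comparisons are meaningful for these thresholds. The
invasive/core ratio is (total − core)/core after intersecting the core into
the total outline.

## Synthetic data: what it does and does not emulate

The generator reproduces the *statistical structure the analysis assumes*:
two-component DHO doublets obeying the mixing rule with an elastic-line
Lorentzian tail and Poisson counting noise (peak counts = SNR², default
SNR 50); Raman bands as Gaussian sets (CH at 2850/2885/2935, OH at
3230/3420, PDMS at 2905/2965 cm⁻¹) whose closed-form areas encode the
biphasic composition, plus polynomial fluorescence, contamination at known
levels, and additive Gaussian CCD noise; nuclei as non-overlapping
rasterized ellipses with zone-dependent aspect-ratio distributions.
Condition presets anchor the composition values (control Φ_ECM = 0.15,
ROCK 0.24, compressed 0; ω_ECM = 8.0 GHz; w_cell = 0.70); component shifts
(8.10–8.30 GHz), Γ = 1.2 GHz (1.5 for RhoA), κ = 0.7 and the noise levels
are plausible 532 nm backscattering values chosen to preserve the ordinal
relationships between conditions — not measured constants.

Passing recovery tests therefore demonstrates that the chain is
self-consistent and unbiased under its own assumptions. It does not
demonstrate robustness to what real data add: non-Gaussian band shapes,
NA-dependent broadening, elastic-line leakage into the fit window beyond a
smooth tail, turbidity, spatial heterogeneity within the scattering volume,
or segmentation errors upstream of the morphometry.

## Numerical and scale choices

* Acceptance studies run at desk scale: 20 Raman spectra per condition,
  10 calibration spectra, 10 Brillouin pairs, 2000-point spectra — each
  study completes in seconds and the whole suite in under a minute.
* Monotonicity, linearization and identity sweeps are noiseless by design
  (they probe structure, not statistics); stochastic checks fix their seeds
  and state tolerances at the level the study sizes support.
* Composition estimates in [−0.05, 0) are clamped to 0 with a warning
  (noise around the pure-cell limit); anything farther out raises a
  model-violation error instead of being silently clamped.
* Degenerate inputs fail loudly: empty spectra, missing peaks, constant
  traces, gross axis offsets, empty masks and unplaceable nuclei all raise
  typed exceptions (`brisma.exceptions`).

## Known limitations

* The closed-form R↔Φ relation assumes a single scattering-efficiency
  constant; wavelength- or condition-dependent CH cross-section changes
  would be absorbed into κ and misread as composition.
* No conversion of ω_B to the longitudinal modulus M′ is attempted (it
  needs refractive index and mass density maps), and no Young's-modulus
  comparison is implied.
* 2D morphometry only; 3D reconstruction and nuclear segmentation are out
  of scope.
* The DHO fit is unweighted; at very low SNR a Poisson-weighted variant
  would calibrate standard errors better.
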