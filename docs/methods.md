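# Methods

This note documents the models behind `ops_imaging`, the conventions and
defaults that matter for interpreting its output, and the places where the
design was genuinely open.

## Units and conventions

Lengths are cm, times ps (lifetimes cross API boundaries in ns and are
converted once), energies keV, angles radians.  CRT (coincidence resolving
time) is the FWHM of the *difference* of two independent single-hit times —
the standard PET usage — so single-hit times are smeared with
σ_single = CRT/(2√(2 ln 2))/√2 ≈ 0.300 · CRT/√2.  This convention directly
scales every TOF-derived width, so it is worth stating twice: a CRT of
500 ps means σ_single ≈ 150 ps, and an along-LOR localisation error of
σ = c·CRT/(2·2.3548) ≈ 3.2 cm.

## Analytic sensitivity model

The scanner is a cylindrical scintillator shell (radius R = 40 cm for the
analytic study) spanning |z| ≤ AFOV/2, with a uniform 200-cm line source of
decays on its axis inside a 10-cm-radius water cylinder.  For a decay at
height z, a photon at polar angle θ crosses the shell at axial coordinate
z + R/tanθ; requiring that coordinate to lie inside the scanner gives the
acceptance bounds.  The back-to-back pair must satisfy the condition at both
θ and π−θ, which symmetrises the pair bounds to
[atan(R/(AFOV/2−z)), π − atan(R/(AFOV/2−z))].  The sensitivity is

    S = ∫₀^{AFOV/2} dz [∫ (ε_a Att_a)² sinθ dθ] · [∫ ε_p Att_p sinθ dθ],

with ε(θ) = 1 − e^(−μd/sinθ) and Att(θ) = e^(−μ_w·10/sinθ), the second
bracket present only in triple mode.  Attenuation coefficients are the
tabulated values μ = 0.833/0.413 cm⁻¹ (LYSO, 511/1160 keV), 0.098/0.068
(plastic) and 0.096/0.066 (water); they are configuration data, not fitted.
Selection efficiencies (0.34 per 511 keV photon in LYSO — the
photofraction; 0.44 in plastic — the Compton fraction above a 200 keV
deposit; 0.66 for the prompt) multiply the integrand by ε_sel−a²·ε_sel−p.
Gains are always quoted relative to the same model's 2γ sensitivity at
AFOV = 20 cm with LYSO; including the selection factors in both numerator
and reference reproduces the quoted 13.5× (LYSO) and 5.2× (plastic)
total-body gains to three digits, so that is the default convention.

The overall prefactor of S is arbitrary (no solid-angle or source-length
normalisation is applied); only ratios of S values are meaningful, and all
reported quantities are such ratios.  Quadrature is adaptive with relative
tolerance 1e−8; a brute-force ray-sampling estimator with analytic per-ray
weights serves as an independent oracle in the tests (3σ agreement at 10⁶
rays).

**Prompt acceptance bounds — an ambiguity made explicit.**  The prompt
photon needs only itself to be registered, so its natural upper bound is the
far-cap single-photon limit π − atan(R/(AFOV/2+z)) ("single").  With that
choice the model gives the 13.5/5.2 total-body gains but gain-parity
("crossover") AFOVs of 49.6 cm (LYSO) and 77.3 cm (plastic).  Restricting
the prompt to the same mirrored bounds as the pair ("mirror") lowers the
total-body gains to 12.3/4.7 — i.e. "twelvefold"/"fourfold" — and moves the
parity points to 56.0/86.2 cm.  The two printed pairs of results are thus
each internally consistent with one of the two conventions but not with a
single one.  Both are implemented (`prompt_bounds="single"|"mirror"`);
"single" is the default, and the parity-AFOV computations in the acceptance
script use "mirror", the convention those quoted numbers correspond to.

Projected statistics use plain arithmetic: 370 MBq × 1200 s × 0.5%
efficiency × 30% oPs formation ≈ 6.7·10⁸ triple coincidences, ≈ 10⁴ per cm³
of the 200-cm, 10-cm-radius phantom (×2.6 for LYSO via the gain ratio).

## Monte Carlo scanner model

The simulated total-body scanner is an idealised plastic design: four
contiguous annular layers of 1.5 cm starting at r = 43 cm (6 cm total
plastic — the four-layer/strip-cross-section geometry is kept as metadata
only), axial extent |z| ≤ 100 cm.  Decay generation, transport and response:

- **Generator.**  Six point sources in the y = 0 plane at x = 1, 10, 20 cm
  and z = 0, 75 cm with mean oPs lifetimes 2.0, 2.4, 2.8, 2.2, 2.6, 3.0 ns
  (tissue-like range), equal activity weights (relative activities are not
  otherwise specified).  Origins are jittered uniformly in a 1-mm-radius
  sphere (toggleable to point-like).  Directions of the back-to-back pair
  and of the prompt are isotropic and independent; lifetimes are
  inverse-CDF exponential draws.  The event clock starts at positron
  emission; the ~3 ps Ca-44* de-excitation delay is off by default (an
  exponential toggle exists) since it is negligible at tens-of-ps
  precision.  Positron range and photon acollinearity are not modelled:
  all three photons leave the same point.
- **Transport.**  Single-interaction model: the in-plastic chord is computed
  analytically (ray/annulus intersection clipped by the end caps), the
  interaction depth is an exponential draw with the total attenuation
  coefficient, and one Compton interaction deposits energy drawn from the
  Klein–Nishina electron spectrum (rejection sampling on the scattering
  angle; deposits are bounded by the Compton edge, 340.7 keV at 511 keV and
  950.6 keV at 1160 keV).  No secondary tracking, no inter-photon scatter,
  no patient attenuation or scatter (the study's sensitivity figures
  explicitly exclude in-body losses).
- **Response.**  Hit positions are smeared with 5 mm FWHM Gaussians axially
  and tangentially; the radial coordinate stays at the interaction radius,
  as for a strip readout that resolves along-strip position and azimuth but
  not depth.  Hit times are smeared per the CRT convention above.  Smearing
  is applied after detection, so one detected sample can be re-smeared for
  several CRT settings with common transport randomness.
- **Selection.**  Both annihilation deposits > 200 keV (bounding the scatter
  fraction in the real system) and prompt deposit > 400 keV.  Because
  400 keV exceeds the 511 keV Compton edge, an annihilation photon can never
  be mis-tagged as prompt.  Per-cut counters are kept.

The resulting triple-coincidence efficiency for the 200-cm line source is
**0.66%** at the (200, 400) keV working point.  The corresponding quoted
value is "about 0.5%".  The selection factors agree with Klein–Nishina
closed forms exactly (0.44² for the pair, 0.64 for the prompt), so the
difference sits in the geometric/interaction factor, most plausibly because
this model's annuli have no inter-strip gaps (fill factor 1) whereas a
strip-filled scanner loses a fraction of photons between strips.  The
efficiency is reported as computed; the 0.5% band test in the acceptance
suite is expected to fail by this margin and is documented as a known
deviation rather than adjusted.

## Reconstruction

Annihilation: with hits (r₁, t₁), (r₂, t₂) and û = (r₂−r₁)/|r₂−r₁|, the
point is x = (r₁+r₂)/2 + û·c(t₁−t₂)/2 — the sign places the point nearer
the *earlier* hit — clamped to the chord; the annihilation time is
(t₁+t₂)/2 − |r₁−r₂|/(2c).  Emission time: t_p − |r_p − x|/c, exact under
zero positron range.  With all smearing disabled the chain reproduces
generated positions and lifetimes to machine precision (tested).

**Direct image**: a histogram of reconstructed annihilation points on a
5 mm grid.  **TOF-FBP**: list-mode backprojection of a 1-D Gaussian kernel
(σ = c·CRT/(2·2.3548), floored at one voxel) along each LOR on a
1.8×1.8×2.9 mm grid, followed by a regularised Fourier inverse of the
orientation-averaged backprojection blob e^(−r²/2σ²)/r² (Tikhonov parameter
3e−3 relative to the kernel peak; the apodised-ramp analogue in image
space).  The reference filter of the original TOF-FBP formulation is not
reproduced here; the deconvolution is a replaceable strategy behind the same
interface, and its output is validated through pattern properties (peak at
the source, near-CRT-independent PSF) rather than cell-by-cell numbers.

**PSF extraction** follows a point-source resolution analysis: the peak
region is windowed along x and z (12 cm default, excluding the ≥ 9-cm
distant neighbouring sources; wider when a source is imaged alone) and
marginalised over the full y extent, as in profiles of a coronal-view
image; each 1-D profile is fitted with a Gaussian plus constant offset
(FWHM = 2.3548σ), falling back to interpolated half-maximum width when the
peak occupies fewer than three voxels.  Slicing instead of marginalising
would blind the profile to displacements along obliquely oriented LORs and
reproduces neither the growth of the radial width with CRT nor its
magnitude.  With this estimator the direct-image radial FWHM at
(20, 0, 75) cm is ≈ 5 mm at CRT = 10 ps, ≈ 9 mm at 140 ps and ≈ 28 mm at
500 ps, and the TOF-FBP width stays at 3–5 mm throughout.  One deviation is
documented: the direct-image *axial* width at CRT = 500 ps comes out ≈ 14 mm
here, while the corresponding published table repeats the 140 ps value
(6.8 mm); no setting of this model reproduces that repetition, and the
axial column enters only the qualitative pattern checks.

## Lifetime imaging

Per voxel, the mean of the Δt spectrum — negative entries included, since
clipping would bias the estimate upward — is the default lifetime
estimator; it is unbiased under the chain's symmetric timing noise, with
standard error √(τ² + σ_eff²)/√N.  σ_eff is *measured* from the chain
(standard deviation of per-event reconstructed-minus-true lifetime), not
assumed: ≈ 8, 21, 55, 193 ps at CRT = 10, 50, 140, 500 ps, i.e. ≈ 0.39·CRT.
An exponential-convolved-with-Gaussian maximum-likelihood fit (Gaussian
width held at the known σ_eff) is available as a cross-check estimator and
agrees with the mean within statistical error.  Voxels below a count floor
(default 5) are masked, never reported as zero.

Because σ_eff ≪ τ, the resolution law is τ/√N to within half a percent for
every CRT ≤ 500 ps: at τ = 2 ns and N = 10⁴ the RMS is 20.0–20.1 ps.  Note
that the often-quoted "better than 20 ps" bound *equals* τ/√N at these
numbers — the procedure saturates it rather than beating it, and the
acceptance test allows the RMS estimator's own sampling noise
(≈ RMS/√(2·reps)) on top of the 20 ps figure.

Per-source accuracy is assessed by pooling events whose reconstructed
position falls within 1.5 cm of a source (three 5-mm voxels — a
counts-weighted peak neighbourhood; a 7.5 mm radius discards most of the
sample at CRT = 500 ps where the radial PSF is ≈ 3 cm) and comparing the
reconstructed mean lifetime with the mean of the *same events'* generated
lifetimes.  This image-to-image comparison isolates the reconstruction
bias, which is what a generated-vs-reconstructed figure shows; comparing
against the nominal τ instead adds the shared exponential sampling noise
τ/√n (≈ 20–40 ps at realistic per-source statistics) that no reconstruction
can remove.  The measured bias is ≤ ~5 ps across all six sources and all
four CRT settings, and is CRT-independent within errors.  Position-selection
does not bias the lifetime: along-LOR position errors are driven by
t₁ − t₂ while the annihilation-time error is driven by t₁ + t₂, which are
independent for i.i.d. Gaussian hit-time noise.

The mean-lifetime image is invariant under uniform event thinning (tested
at 50% thinning against per-voxel standard errors), the statistical basis
of the claim that lifetime images need no attenuation correction.

## Problem sizes

Default study sizes were chosen so that every statistical comparison has
the power it needs on a single CPU: 2–3·10⁶ decays per shared test sample
(≈ 10⁴ registered triples), 4·10⁵ decays for the efficiency measurement
(binomial SE ≈ 0.013 percentage points), 500 replicates for the RMS study,
and 4·10⁶ decays per source (2.4·10⁷ total, ≈ 2–4·10⁴ registered triples
per source) for the bias scan, giving per-source bias standard errors of
2–7 ps.  The acceptance script completes in a few minutes; the test suite
in well under a minute apart from the shared-fixture generation.

## Known limitations

- No positron range, acollinearity, pPs/direct-annihilation components,
  random or scattered coincidences, detector dead time, or in-patient
  attenuation: passing tests demonstrate internal consistency of the ideal
  chain, not performance on real data.
- Single Compton interaction per photon and gap-free annuli (see the
  efficiency discussion above).
- The lifetime image uses the arithmetic-mean estimator; multi-component
  spectra (pPs + direct + oPs) would require the fit-based estimator with a
  mixture model, which is out of scope here.
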