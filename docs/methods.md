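# Methods

This note documents the models implemented in `anemovis`, their
assumptions, the defaults the synthetic-data generators use, and the
numerical choices that were genuinely open.

## Spectra and ocular media

All spectral quantities live on a common evenly spaced wavelength grid,
by default 300–800 nm at 1 nm, which covers ocular-media transmission
measurements and every visual pigment considered; 1 nm resolves all the
λ_max comparisons made anywhere in the package.  Integrals are
trapezoidal throughout.  Spectrum files are two-column CSV/TSV
(wavelength in nm, value); negative measured values are rejected rather
than clipped so instrument artefacts surface instead of disappearing.

Lens transmission curves are normalized at 700 nm, where ocular media
are effectively transparent.  T50 — the wavelength at 50% of maximal
transmittance — is found by ordinary least squares on the contiguous run
of points with normalized values in [0.2, 0.8] on the rising limb,
solved at 0.5.  The window bounds are a design choice: the central limb
of a sigmoidal transmission curve is close to linear there, and the fit
is insensitive to the exact bounds for limb slopes of a few nm.  When
the limb carries fewer than two samples (a step-like curve) the first
sample at or above half-maximum is reported.  If the curve crosses 0.5
upward more than once (e.g. an absorption notch), the longest-wavelength
rising crossing is used and a warning issued.  T50 < 400 nm classifies
the lens as UV-transmitting.

## Visual pigments

Pigment absorbance uses the A1 (retinal) template of Govardovskii et
al. (2000): a log-inverse α-band plus a Gaussian β-band centred at
λ_mβ = 189 + 0.315·λ_max with width −40.5 + 0.195·λ_max.  All constants
sit in a `TemplateConstants` record so alternates (e.g. different β-band
parameterisations) can be configured.  The template is trusted for
λ_max in 330–620 nm, which covers a UV-to-red cone complement plus rods.

`fit_lambda_max` peak-normalizes a measured absorbance curve and
minimises the sum of squared residuals against the template over a
1 nm coarse scan refined to a 0.1 nm lattice; ties break toward shorter
wavelengths, and a best fit at the search boundary raises a warning
(flat or saturated inputs end up there).  With noise σ = 0.02 on a
peak-normalized curve sampled at 1 nm, recovery is within ±2 nm in
≳95% of replicates — comparable to the spread of single-cell
microspectrophotometric estimates.

Sequence-based λ_max estimation is additive: estimate = reference λ_max
plus the sum of shifts of matched (site, variant) substitution rules.
Variants at a rule site with no known effect contribute zero and are
reported, because undescribed tuning sites are a real phenomenon (RH2
estimates in damselfishes are known to depend on the reference species
used).  Site numbering follows the reference sequence's own coordinates.

Coexpression of two opsins in one cone is modelled as absorbance mixing
within a single outer segment: (1−f)·A₁ + f·A₂, renormalized to peak 1.
This matches the empirical single-λ_max readout of coexpressing cones
and makes the mixture a single effective pigment for the downstream
model.  Receptor sensitivity is the pointwise product of pigment
absorbance and lens transmission, unnormalized — quantum-catch *ratios*
absorb any scale.

## Receptor-noise-limited discrimination

Quantum catch is ∫R(λ)I(λ)S(λ)dλ for a reflective target under an
illuminant, or ∫L(λ)S(λ)dλ for a radiance viewed directly.  Catches are
computed in the energy units of the supplied spectra with no photon
conversion; because only log catch ratios enter the model, the unit
convention is immaterial as long as all spectra share it.  This is
stated prominently because mixing photon- and energy-unit spectra would
silently bias results.

Channel signals are Δf_i = ln(Q_target/Q_background), which builds in
von Kries adaptation: ΔS and ΔL are exactly invariant under global
illuminant rescaling.  Noise follows the standard abundance convention
ω_i = ν·√(n_ref/n_i) with the reference the most abundant channel.  The
modelled animal is a trichromat with one single cone per double-cone
pair (n_S:n_M:n_L = 1:2:2) and Weber fraction ν = 0.1, so
ω = (0.1√2, 0.1, 0.1).  The long-wavelength LWS opsin is excluded from
the modelled trichromat: its expression is ~1% of cones and its labelled
cells are rare and unpatterned, consistent with a negligible functional
role.  Luminance is the summed M+L (double-cone) catch with ω = 0.1,
the standard teleost achromatic-channel assumption; luminance noise has
not been measured separately, so the colour Weber fraction is reused.

The monochromatic sweep builds a single-pigment eye behind the lens for
each candidate λ_max and scores the *luminance* JND between the two
stimuli — a monochromat has no chromatic channel.  The coexpression
sweep varies the single cone's %SWS2B (mixing 370 nm SWS1 with 408 nm
SWS2B) with M/L fixed at RH2B 498 / RH2A 520 nm and scores the
trichromatic ΔS.  Sweep ties break toward the shortest wavelength /
smallest fraction.

## Opsin expression proportions

Expression is summarised as rod (RH1) vs cone fractions of total opsin
expression, per-gene fractions of total cone expression, and single-
vs double-cone gene sets normalized separately (SWS1+SWS2B in singles;
RH2B+RH2A+LWS in doubles — the partition established by in-situ
labelling).  Input counts are assumed length-normalized per transcript;
`normalize_by_length` divides raw counts by transcript length when
needed, since published proportions do not always state their
normalization.  Cohort summaries are arithmetic means and sample SDs of
per-individual proportions.  Regression tests of expression against sex
or size are deliberately out of scope; the tidy proportion table is the
input such a test would consume.

## Stereology and topographic maps

Counting data follow the optical-fractionator design for wholemounts:
frames of area a at the nodes of a systematic grid of cell area A, with
the thickness sampling fraction equal to 1 (the full depth is
inspected).  The total estimator is N̂ = ΣQ·(A/a).  The coefficient of
error is implemented as the relative standard error of the mean per-site
count, CE = (s/√n)/q̄ — the cited Scheaffer-type estimators are not
printed in the sources this emulates, and this form has the required
properties (0 for uniform counts, ∝ 1/√n) while being trivially
replaceable.

Topographic maps use Gaussian-kernel smoothing: each site contributes
its density (count/a) spread over a Gaussian kernel scaled by the grid
cell area it represents, and each kernel is renormalized by its mass
inside the retina outline.  The edge correction prevents rim
underestimation, and makes the area-weighted map mean equal the mean
site density up to raster discretisation (verified to within 5% in
tests).  Defaults tie the analysis to the sampling design: σ equals the
grid spacing √A and the raster step is σ/4.  Peaks are the masked
argmax, with ties resolved toward the mask centroid and then
lexicographically.  No shrinkage correction is applied (wholemount
protocols are treated as shrinkage-free); maps of two classes on the
same raster can be divided cellwise with a denominator floor for
cone:ganglion-cell convergence ratios.  Coordinates are millimetres
with +x temporal and +y dorsal, origin near the outline centroid —
the sources define orientation only by arrows, not numerically.

Smoothing attenuates sharp features: with σ = 0.3 mm the recovered peak
of the synthetic ganglion-cell surface reads ~6–8% below the generating
40,400 cells/mm², which propagates into a correspondingly conservative
SRP.  This is a property of kernel mapping itself, not of the
implementation.

In-situ channel fractions (RH2A/RH2B pairing in double cones, SWS2B
coexpression in single cones, LWS fraction) are pooled count-weighted
with Wilson binomial confidence intervals.  The coexpression region is
found by Nadaraya–Watson smoothing of per-site fractions (a fraction is
intensive, so a kernel-weighted average is the right smoother, not the
density kernel sum) and taking the largest connected component above a
threshold.  The default threshold is *half the smoothed peak* (an FWHM
region): an absolute threshold interacts badly with the attenuation of
small patches under smoothing and with the overall under-labelling known
to affect in-situ counts, while the relative rule recovers a constructed
0.5 mm-radius disc's centroid to < 0.1 mm and its area to ~10%.

The ideal cone mosaic is a periodic square lattice with one single cone
per unit cell and double cones at two edge midpoints, so every single
cone has exactly four equidistant double-cone nearest neighbours and the
double:single ratio is exactly 2 at every size.

## Acuity

SRP follows the peak ganglion-cell density chain: focal length =
2.55 × lens radius (Matthiessen's ratio, configurable), retinal
magnification f·tan 1°, linear cell density √D (square-lattice
assumption; hexagonal √(2D/√3) is a flag), SRP = magnification·√D/2.
Detection distance treats a target as distinguishable while it subtends
one full resolvable cycle, d = size/tan((1/SRP)°), and reports values
floored at the printed precision — the conservative convention that
reproduces quoted whole-metre ranges.  Both the one-full-cycle reading
and the floor convention are inferred from the published number chain
(26.4→26 m, 16.6→16 m, 1.65→1.6 m, 1.04→1 m); a half-cycle criterion
would double every distance.

## Synthetic data: what it emulates and what it does not

The generators produce every input with the statistical structure the
analyses assume.  Defaults are the study conditions:

* Ganglion-cell surface: baseline 12,000 + horizontal streak 12,000
  (Gaussian ridge, σ_y 0.8 mm) + temporal peak 16,400 (isotropic
  Gaussian, σ 0.7 mm at (1.8, 0) mm), peaking at 40,400 cells/mm².
  Cone surface = 2 × ganglion surface (mean convergence ratio 2:1);
  single = total/3, double = 2·total/3 per the mosaic.  Retina radius
  3.5 mm (≈38 mm², consistent with ~10⁶ ganglion cells at these
  densities).  Sites are a systematic grid with spacing √A (A =
  0.09 mm²) and a seed-dependent random common offset — systematic
  random sampling, which makes the fractionator unbiased over offsets;
  counts are Poisson with mean a·D (a = 0.0025 mm²).  Overdispersed
  counts are not modelled.
* Lens: logistic transmission, default T50 352 nm (a male lens, the one
  the visual modelling uses); 358 and 328 nm reproduce female and
  immature lenses.
* Reflectances: Gaussian/logistic composites with the qualitative
  measured shapes (UV-reflecting white stripe peaking ~520 nm; orange
  with a small 360–380 nm peak and a dominant long-λ plateau; anemone
  peaking ~600 nm); zooplankton and looming-predator targets are exactly
  flat 10% grey.  The light field is blue-green, peaking near 480 nm,
  positive over 320–700 nm, with horizontal radiance a scaled copy of
  horizontal irradiance.
* Expression: cone-gene simplex ~ Dirichlet(150 × means) with means
  (6.8, 0.7, 49.2, 42.0, 1.3)% for (SWS1, SWS2B, RH2B, RH2A, LWS); rod
  fraction ~ Beta with mean 0.503 and concentration 16 (SD ≈ 0.12).
  A single Dirichlet concentration cannot reproduce every printed
  per-gene SD simultaneously; 150 is a compromise chosen once (it makes
  RH2B/RH2A spreads slightly wide and SWS1 slightly tight).
* In-situ counts: all single cones SWS1⁺; within a temporal disc
  (centre (2.3, 0) mm, radius 0.5 mm) each single cone is SWS2B⁺ with
  probability 0.5, zero outside; double cones RH2A/RH2B-paired at rate
  0.995; LWS labels 0.5% of double cones.

Because the spectra are smooth idealisations and the count noise is
exactly Poisson/Binomial, passing tests demonstrate that the estimators
and models are correct and well-calibrated under their own assumptions —
not that they are robust to instrument baselines, retinal tears,
labelling dropout, or non-Poisson clustering in real material.  The
discrimination sweeps on synthetic reflectances reproduce directions of
change (e.g. which targets benefit from higher SWS2B coexpression), not
published curve values, which depend on unpublished measured spectra.

## Problem sizes

The default pipeline run uses a 3.5 mm-radius retina (~430 sites), a
10-individual cohort, 2 nm sweep steps and 2% coexpression steps, and
completes in a few seconds.  Verification runs use 200 fractionator
replicates, a 10⁴-individual cohort and 100-seed fit-recovery studies.

## Known limitations

* The CE formula is a generic relative SEM, not the exact published
  Scheaffer/Coimbra estimator (which is not printed in the sources).
* Tetrachromatic opponency, spatial/temporal vision, photon-unit
  conversion and radiative-transfer water optics are out of scope.
* Sequence-based λ_max estimation is strictly additive over known
  sites; epistasis and undescribed tuning sites are reported only as
  unmatched variants.
* The acuity chain deliberately does not chase the third digit of
  published SRP tables, which were computed from unrounded inputs:
  with the printed peak density (40,400 cells/mm²) and lens diameter
  (2.5 mm) the formula gives 5.59 cycles/deg against a printed 5.77
  (~3%).  Detection distances are computed from the printed SRPs.
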