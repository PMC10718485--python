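# Methods

This note documents the models implemented in `cartoptics`, the
assumptions and defaults behind them, what the synthetic-data
generators do and do not emulate, and the numerical choices made where
the design was genuinely open.

## Spectral conventions

All spectra live on the 400–1400 nm band. The default analysis grid is
1 nm — finer than both the 3 nm visible-band and 7 nm NIR-band
spectrometer resolutions it harmonizes — and dual-band series are
merged at a configurable boundary (default 950 nm) with a 50 nm linear
blend ramp; no merge rule is standard for this instrument pairing, so
the boundary and ramp width are explicit parameters. Wavelengths are
nominal instrument wavelengths; no vacuum/air refractive correction is
applied. Coefficients are in mm⁻¹ throughout.

## Extinction from collimated transmittance

For a thin section of thickness d (nominally 0.1 mm),

    mu_t = -ln((T_sample - T_dark) / (T_ref - T_dark)) / d.

The logarithm is natural: mu_t is the e-folding coefficient consumed
by exp(−mu_t·s) path statistics downstream. Wavelengths where the net
sample signal is non-positive are *masked*, not clipped to an epsilon —
clipping would fabricate a finite extinction where the measurement ran
out of dynamic range — and the masked fraction is reported per record.
Because cartilage absorbs weakly across this band, mu_s is taken equal
to mu_t by default; a caller-supplied absorption spectrum is
subtracted (floored at zero, with a warning) when available. Multiple-
scattering contamination of the collimated beam is not corrected: for
thin sections with mu_t ≤ 50 mm⁻¹ the multiply scattered contribution
to the on-axis signal is negligible. Fresnel losses at the glass
sandwich are assumed common to sample and reference paths and cancel
in the normalization.

## Power-law decomposition

Scattering spectra are decomposed as

    mu_s(lambda) = alpha [ c (lambda/lambda0)^-p + (1-c) (lambda/lambda0)^-b ],

p = 4 for Rayleigh scatterers, p = 3 for the collagen-fibril variant;
lambda0 = 500 nm, so alpha = mu_s(500 nm) under either model. Fitting
is unweighted least squares on the raw coefficient scale (the quality
metric of record is raw-scale RMSE), solved with a bounded
trust-region optimizer. Bounds are alpha ∈ (0, 10³] mm⁻¹, b ∈ [0, 4],
c ∈ [0, 1]; boundary values are physically meaningful (measured zone
spectra can have c = 0 exactly), which is why the optimizer is bounded
rather than reparameterized through a transform that would push the
bounds to infinity. Because (c, b) are weakly identifiable when c ≈ 0
or b approaches p, the fit multi-starts from 8 Latin-hypercube points
and keeps the best converged solution; parameters ending within 10⁻⁴
of a bound (relative to the box width) are flagged `at_bound`.

Outlier handling is declarative: fits with R² below a configurable
floor (default 0.90) or without convergence are flagged, never
deleted, and summaries exclude flagged fits. The floor is a stated
stand-in for an unspecified historical outlier rule and is exposed as
a parameter.

A fit requires ≥ 10 wavelengths spanning ≥ 300 nm; narrower spans
cannot separate the two mixture components. Fitting on the merged 1 nm
grid or a native instrument grid are both supported; tests use a 5 nm
grid, which at 2% multiplicative noise recovers alpha to a median
relative error below 5%, b below 10%, and c within ±0.05.

## Monte-Carlo transport and sphere inversion

The forward model is a photon-packet random walk in a homogeneous
finite cylinder (default radius 7.5 mm), pencil beam on axis at normal
incidence:

- step lengths s = −ln(u)/(mu_a + mu_s);
- implicit capture: fraction mu_a/(mu_a+mu_s) of the packet weight is
  deposited at each interaction;
- Henyey–Greenstein deflection sampled by the closed-form inverse CDF
  (mean cosine = g; default g = 0.9), uniform azimuth;
- unpolarized Fresnel reflection/transmission at the top and bottom
  faces (default n_sample = 1.358 against air), total internal
  reflection included; the deterministic specular reflection of the
  entrance beam is reported separately;
- Russian roulette below weight 10⁻⁴ with survival probability 0.1
  (unbiased reweighting) — standard photon-packet practice.

Packets crossing the lateral wall are tallied as side loss rather than
Fresnel-reflected; with the default aspect ratio (radius ≫ thickness)
side losses are ≲10⁻⁴ of launched energy, and reporting them
separately keeps the energy ledger exact: reflectance + transmittance
+ absorbed + side + specular + net roulette correction equals the
launched weight to < 10⁻⁶ per run, asserted every simulation. The
kernel is validated against an independent radiative-transfer oracle:
the Chandrasekhar H-function plane albedo of a semi-infinite
isotropically scattering half-space (albedo 0.9) is matched to within
1% (0.04% observed at 10⁶ packets). Glass cuvette walls are not
modeled; the surround is air. The kernel is compiled with numba when
available, with an identical pure-Python fallback.

The inverse estimator builds a lookup table of (Rd, Td) on a
log-spaced (mu_a, mu_s') grid — default 24×24 nodes over
mu_a ∈ [10⁻³, 1] mm⁻¹, mu_s' ∈ [0.1, 10] mm⁻¹, bracketing bulk-
cartilage values — and minimizes per wavelength the squared relative
(Rd, Td) residual against bilinear interpolation in log-property
space, coarse-scan seeded and Nelder–Mead polished. The table is
parameterized in mu_s' (the quantity of record); the simulator
converts through the similarity relation mu_s = mu_s'/(1−g) with the
configured g. Tables carry a fingerprint of the physical configuration
and refuse inversion under a mismatched geometry/n/g. Wavelengths
whose optimum lands on the table hull are flagged out-of-range, not
failed. Forward–inverse closure at bulk-regime properties
(mu_s' ≈ 2–3.5 mm⁻¹) recovers mu_s' within 5% and mu_a within 10% at
10⁴-photon nodes and 10⁵-photon measurements. This estimator is a
functional inverse-sphere workflow validated by closure, not a
replication of any particular instrument's inversion software.

## Anisotropy factors

The zone anisotropy spectrum is

    g_HG(lambda) = 1 - mu_s'_bulk(lambda) / mu_s_zone(lambda),

pairing the bulk-tissue reduced scattering of a location with each
zone's section-level scattering from the same location — the ratio is
read as the zone's normalized contribution to bulk transport. Since
mu_s' is estimated under the Henyey–Greenstein phase function, the
derived g is HG-referenced; the Graaff correction
g_mHG = g_HG(1−c) then discounts the Rayleigh-scattered share, using
the *zone's* fitted c (the correction quantifies how that zone's own
small-particle population depresses its effective anisotropy), not the
bulk c*. Two routes are computed: pointwise division of raw spectra
(masked wherever mu_s' ≥ mu_s would imply g ≤ 0) and division of
fitted power-law curves; the smooth route is the headline because it
is noise-free by construction. When the zone spectrum decays more
slowly than the bulk one (b_zone < b_bulk), g rises with wavelength —
the mechanism behind increasingly forward-directed NIR scattering.
Mixing a single-scattering mu_s with a multiply-scattered mu_s' in one
ratio is an interpretive assumption of the method, recorded here, not
resolved.

## Polarized-light orientation mapping

A birefringent section between crossed polarizers modulates intensity
as I(θ) = I₀ sin²(2(θ−φ)) sin²(δ/2) + offset, period 90°, extinguished
when the polarizer aligns with the fiber axis φ. From 21 frames
(θ = 0°…180°, 9° steps) each pixel gets an exact linear harmonic fit

    I(θ) ≈ s0 + s1 cos 4θ + s2 sin 4θ,

with φ = atan2(−s2, −s1)/4 (mod 90°), the sign convention fixed so
fitted-intensity minima fall at θ ≡ φ — verified by generator round
trip. Harmonic regression is used instead of brightest/darkest-frame
lookup because the 9° sampling would quantize φ to 4.5°; the fit is
continuous and exact for the assumed signal model. The parallelism
index is the Michelson contrast of the fitted curve, A/s0 with
A = √(s1²+s2²): 1 for a fully modulated offset-free signal, 0 for no
modulation. φ is invariant to gain; offsets lower only the parallelism
index.

Depth reduction takes per-row circular means of φ with period-90°
statistics (vector averaging of 4φ), weighted by the parallelism
index. The modulo-90° ambiguity is resolved only at the profile level
by a monotone-depth prior (isotonic regression of angle on depth),
never per pixel. Zone fractions follow from linear-interpolated 30°
and 60° crossings of the smoothed profile. The synthetic generator's
default logistic angle profile is calibrated to cross 30° at depth
fraction 0.08 and 60° at 0.29, i.e. 8/21/71% superficial/middle/deep
depth shares; the full reduction recovers these within ±2 percentage
points and the angle profile within 3° RMSE at 1% intensity noise. A
fixed 630 nm illumination is assumed; retardance dispersion is
ignored.

## Group statistics

Per-parameter comparisons run over four stratifications: zones pooled
over locations, zones within each location, locations pooled over
zones, and locations per zone. Branch selection requires every group
to pass a Kolmogorov–Smirnov normality test against a normal with the
group's estimated moments (a Lilliefors-corrected variant would be
stricter; the plain KS is the default, and the choice is isolated in
one function) and Levene's test for variance homogeneity, at
α = 0.05. The parametric branch is one-way ANOVA with Tukey HSD; the
nonparametric branch is Kruskal–Wallis with Dunn's rank-sum pairwise
z-tests (tie-corrected, Bonferroni-adjusted by default, Holm
available). Dunn's procedure is implemented in-package and pinned by a
hand-computed oracle. Post-hoc matrices are symmetric with a unit
diagonal. Groups with n < 3 are excluded with a warning; zero-variance
groups force the nonparametric branch. Samples are treated as
independent across strata (no joint-of-origin clustering), matching
the flat grouping of the source data.

## Synthetic data: what it does and does not emulate

The generators reproduce the *statistical structure* the analysis
stages consume: power-law zone spectra at literature-scale parameter
magnitudes with additive or multiplicative Gaussian noise; a weakly
absorbing mu_a with Gaussian bumps at 950 and 1150 nm mimicking water
bands; detector-count triplets built as the exact inverse of the
Beer–Lambert stage; sphere spectra from the package's own forward
transport model; and ideal-signal-model birefringence stacks. They do
not emulate vendor file formats, radiometric calibration drift,
speckle, instrument PSFs, section-thickness variability, rigorous
Mueller-matrix birefringence, or the cutting-order assignment of
physical sections to zones (synthetic sections are generated per zone
directly). Passing tests therefore demonstrate correctness of the
estimators under their stated models and noise levels — not robustness
to every instrumental artifact of real acquisitions.

Default noise levels are 2% multiplicative on scattering spectra and
1% of I₀ on polarized-light frames; both are parameters, chosen as
realistic mid-range values for these modalities.

## Problem sizes

Default test and example runs use a 5–20 nm analysis grid, 10⁴–10⁵
photon packets per simulation, 24×24 lookup-table nodes, and
192×48-pixel image stacks. These sizes were chosen so the documented
tolerances are met with comfortable margin while a full suite run
stays desk-scale; all are configurable upward for production use.

## Known limitations

- Isotropic transport model: scattering coefficients and phase
  function do not depend on propagation direction, although the zonal
  collagen architecture makes real cartilage weakly anisotropic.
- Fixed n = 1.358 and g = 0.9 for bulk inversion; spectral variation
  of either shifts recovered properties by a few percent.
- The lateral cylinder wall absorbs rather than Fresnel-reflects
  (negligible at default aspect ratio, visible for thick narrow
  samples).
- The g derivation inherits the HG phase-function assumption; it is
  not a goniometric measurement of the phase function.
- Lookup-table inversion accuracy is bounded by node noise
  (photons⁻¹ᐟ²) and bilinear interpolation error between log-spaced
  nodes.
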