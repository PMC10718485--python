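# cartoptics

Broadband scattering properties of articular cartilage zones.

Articular cartilage is layered: collagen fibers lie parallel to the
articular surface in the superficial zone (SZ), tilt through the middle
zone (MZ), and stand perpendicular in the deep zone (DZ). This
depth-wise architecture shapes how the tissue scatters light, which in
turn determines what diffuse optical diagnostics of early cartilage
degeneration can see. `cartoptics` is a Python library for quantifying
that relationship across the 400–1400 nm band, for researchers in
tissue optics and musculoskeletal photonics.

## What it computes

- **Extinction spectra of thin zone sections** from collimated
  transmittance via Beer–Lambert's law,
  μ<sub>t</sub>(λ) = −ln[(T−T<sub>dark</sub>)/(T<sub>ref</sub>−T<sub>dark</sub>)]/d;
  for weakly absorbing cartilage μ<sub>s</sub> ≈ μ<sub>t</sub>.
- **Rayleigh/Mie power-law decomposition** of scattering spectra,
  μ<sub>s</sub>(λ) = α[c(λ/λ₀)⁻⁴ + (1−c)(λ/λ₀)⁻ᵇ] with λ₀ = 500 nm
  (and the collagen-fibril λ⁻³ variant), by bounded multi-start least
  squares, with fit quality, outlier flagging, and zone/location
  summaries.
- **Monte-Carlo inversion of integrating-sphere measurements**: a
  photon-packet transport model in a finite cylinder
  (Henyey–Greenstein phase function, unpolarized Fresnel boundaries,
  implicit capture, Russian roulette) drives a lookup-table inversion
  recovering (μ<sub>a</sub>, μ<sub>s</sub>′) from diffuse reflectance
  and transmittance.
- **Spectral anisotropy factors** per zone from
  g<sub>HG</sub>(λ) = 1 − μ<sub>s</sub>′(λ)/μ<sub>s</sub>(λ) (bulk over
  zone), with the Graaff small-particle correction
  g<sub>mHG</sub> = g<sub>HG</sub>(1−c).
- **Collagen fiber orientation** from 21-frame crossed-polarizer image
  stacks by exact harmonic fitting of the sin²(2(θ−φ)) modulation,
  reduced to depth profiles and 30°/60°-thresholded zone fractions.
- **Group statistics**: four stratified zone/location comparisons of
  the fitted parameters (KS normality and Levene gatekeeping, ANOVA +
  Tukey or Kruskal–Wallis + Dunn post-hoc matrices).

A synthetic-data module generates every input with known ground truth
at literature-scale magnitudes, so the whole pipeline is testable end
to end without access to measurement hardware.

## Worked example

```sh
python examples/02_power_law_decomposition.py
```

```
alpha: fitted  22.73  true  22.86  (mm^-1, mu_s at 500 nm)
b    : fitted  1.338  true  1.350  (Mie size parameter)
c    : fitted  0.114  true  0.110  (Rayleigh fraction)
fit quality: R^2 = 99.89%  RMSE = 0.2302 mm^-1
```

A middle-zone-scale scattering spectrum with 2% multiplicative noise is
decomposed into its Rayleigh (c) and Mie (b) components: the scatterer
density α (the scattering coefficient at 500 nm), the Mie size exponent
b, and the Rayleigh contribution fraction c all return within a few
percent of the generating truth. The other scripts in `examples/` walk
through extinction (`01`), sphere inversion (`03`), anisotropy spectra
(`04`), collagen orientation mapping (`05`), and the full pipeline with
statistics (`06`).

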