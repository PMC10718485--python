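"""Synthetic measurement generators with known ground truth.

The pipeline's real inputs — thin-section transmittance triplets,
integrating-sphere spectra, crossed-polarizer image stacks — are produced
here from explicit forward models, so every analysis stage can be
exercised end-to-end against a known truth:

* power-law scattering spectra per cartilage zone at literature-scale
  magnitudes (:func:`gen_mus_spectrum`),
* a water-like absorption spectrum with the characteristic 950 and
  1150 nm peaks (:func:`gen_mua_spectrum`),
* detector-count triplets that invert through Beer–Lambert back to the
  input extinction (:func:`gen_transmittance_triplet`),
* sphere (Rd, Td) spectra via the forward Monte-Carlo model
  (:func:`gen_sphere_measurement`),
* 21-frame crossed-polarizer stacks with a depth-varying collagen angle
  profile transitioning from surface-parallel to perpendicular
  (:func:`gen_plm_stack`).

All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .montecarlo import SphereMeasurement, TransportConfig, simulate_rt
from .powerlaw import DEFAULT_LAMBDA0_NM, PowerLawFit, evaluate_power_law
from .spectra import SampleGeometry, Spectrum

__all__ = [
    "SyntheticScatterTruth",
    "SyntheticFiberProfile",
    "PLM_ANGLES_DEG",
    "gen_mus_spectrum",
    "gen_mua_spectrum",
    "gen_transmittance_triplet",
    "gen_sphere_measurement",
    "gen_plm_stack",
    "default_zone_truths",
]

#: The 21 polarizer orientation angles: 0°–180° in 9° steps.
PLM_ANGLES_DEG = 9.0 * np.arange(21)


@dataclass(frozen=True)
class SyntheticScatterTruth:
    """Ground-truth power-law parameters of a synthetic scattering spectrum."""

    alpha: float
    b: float
    c: float
    model_kind: str = "rayleigh4"
    lambda0: float = DEFAULT_LAMBDA0_NM

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")
        if not 0.0 <= self.c <= 1.0:
            raise ValueError("c must be in [0, 1]")
        if self.b < 0:
            raise ValueError("b must be >= 0")

    def as_fit(self) -> PowerLawFit:
        return PowerLawFit(
            model_kind=self.model_kind,
            alpha=self.alpha,
            b=self.b,
            c=self.c,
            lambda0=self.lambda0,
        )


def default_zone_truths() -> dict[str, SyntheticScatterTruth]:
    """Representative zone truths at literature-scale magnitudes.

    Means over anatomical locations of the published per-zone parameters:
    scatterer density rising with depth, Rayleigh fraction highest in the
    middle zone, and a bulk-tissue reduced-scattering entry.
    """
    return {
        "SZ": SyntheticScatterTruth(alpha=16.85, b=1.41, c=0.10),
        "MZ": SyntheticScatterTruth(alpha=22.86, b=1.35, c=0.11),
        "DZ": SyntheticScatterTruth(alpha=30.79, b=1.29, c=0.04),
        "BULK": SyntheticScatterTruth(alpha=2.60, b=2.54, c=0.05),
    }


def gen_mus_spectrum(
    truth: SyntheticScatterTruth,
    grid: np.ndarray,
    noise_sd: float = 0.0,
    seed: int = 0,
    multiplicative: bool = False,
) -> Spectrum:
    """Power-law scattering spectrum plus i.i.d. Gaussian noise.

    ``noise_sd`` is in mm^-1 for additive noise; with
    ``multiplicative=True`` it is a relative sd (e.g. 0.02 for 2% noise).
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    grid = np.asarray(grid, dtype=float)
    clean = evaluate_power_law(truth.as_fit(), grid)
    rng = np.random.default_rng(seed)
    if noise_sd > 0:
        noise = rng.normal(0.0, noise_sd, size=grid.size)
        vals = clean * (1.0 + noise) if multiplicative else clean + noise
    else:
        vals = clean
    return Spectrum(grid, np.maximum(vals, 0.0), "mm^-1")


def gen_mua_spectrum(
    grid: np.ndarray,
    baseline: float = 0.01,
    peak_950: float = 0.04,
    peak_1150: float = 0.08,
    width_nm: float = 35.0,
) -> Spectrum:
    """Weakly absorbing spectrum with water-like 950 / 1150 nm peaks.

    Two Gaussian bumps over a low flat baseline — the qualitative shape of
    hydrated-tissue absorption across 400–1400 nm, without importing an
    external water spectrum.  Units mm^-1.
    """
    grid = np.asarray(grid, dtype=float)
    vals = (
        baseline
        + peak_950 * np.exp(-0.5 * ((grid - 950.0) / width_nm) ** 2)
        + peak_1150 * np.exp(-0.5 * ((grid - 1150.0) / width_nm) ** 2)
    )
    return Spectrum(grid, vals, "mm^-1")


def gen_transmittance_triplet(
    mut: Spectrum,
    geometry: SampleGeometry,
    dark_level: float = 100.0,
    reference_level: float = 60_000.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[Spectrum, Spectrum, Spectrum]:
    """Detector-count (sample, dark, reference) triplet for a target mu_t.

    Constructed so the Beer–Lambert stage recovers ``mut`` exactly as
    noise goes to zero:

        sample = dark + (reference - dark) * exp(-mu_t * d) + noise

    Noise is additive Gaussian on the sample channel counts.
    """
    if np.any(mut.values < 0):
        raise ValueError("mut must be non-negative")
    if geometry.thickness <= 0:
        raise ValueError("geometry.thickness must be > 0")
    rng = np.random.default_rng(seed)
    wl = mut.wavelengths
    dark = Spectrum(wl, np.full(wl.size, float(dark_level)), "counts")
    reference = Spectrum(wl, np.full(wl.size, float(reference_level)), "counts")
    net = (reference_level - dark_level) * np.exp(-mut.values * geometry.thickness)
    sample_vals = dark_level + net
    if noise_sd > 0:
        sample_vals = sample_vals + rng.normal(0.0, noise_sd, size=wl.size)
    sample = Spectrum(wl, sample_vals, "counts")
    return sample, dark, reference


def gen_sphere_measurement(
    mua: Spectrum,
    musp: Spectrum,
    geometry: SampleGeometry,
    n: float = 1.358,
    g: float = 0.9,
    photons: int = 100_000,
    seed: int = 0,
) -> SphereMeasurement:
    """Integrating-sphere (Rd, Td) spectra via the forward Monte-Carlo model.

    One simulation per wavelength at ``mu_s = mu_s' / (1 - g)``; sampling
    noise scales as photons^-1/2.
    """
    if photons < 10_000:
        raise ValueError("photons must be >= 1e4 for usable sphere spectra")
    if not np.array_equal(mua.wavelengths, musp.wavelengths):
        raise ValueError("mua and musp must share a grid")
    rd = np.empty(len(mua))
    td = np.empty(len(mua))
    for k in range(len(mua)):
        cfg = TransportConfig(
            geometry=geometry,
            n_sample=n,
            g=g,
            photons=photons,
            seed=seed + 7919 * k,
        )
        res = simulate_rt(mua.values[k], musp.values[k] / (1.0 - g), cfg)
        rd[k] = res.rd
        td[k] = res.td
    wl = mua.wavelengths
    return SphereMeasurement(
        Rd=Spectrum(wl, np.clip(rd, 0.0, 1.0), "fraction"),
        Td=Spectrum(wl, np.clip(td, 0.0, 1.0), "fraction"),
        geometry=geometry,
    )


@dataclass(frozen=True)
class SyntheticFiberProfile:
    """Depth-varying collagen fiber angle, surface-parallel to perpendicular.

    ``angle_at(z)`` maps normalized depth (0 = articular surface, 1 = deep
    boundary) to the fiber angle in degrees.  The default logistic
    transition is calibrated so the angle crosses 30° at depth 0.08 and
    60° at depth 0.29, which yields superficial/middle/deep zone depth
    shares of 8% / 21% / 71% under the standard 30°/60° zone thresholds.
    """

    steepness: float = field(default=2.0 * np.log(2.0) / 0.21)
    midpoint: float = 0.185

    def angle_at(self, depth_fraction: np.ndarray | float) -> np.ndarray | float:
        z = np.asarray(depth_fraction, dtype=float)
        ang = 90.0 / (1.0 + np.exp(-self.steepness * (z - self.midpoint)))
        return float(ang) if np.isscalar(depth_fraction) else ang

    def zone_fractions_target(self) -> tuple[float, float, float]:
        """Depth fractions where the profile crosses 30° and 60°."""
        # invert the logistic: z = midpoint - ln(90/a - 1)/steepness
        z30 = self.midpoint - np.log(90.0 / 30.0 - 1.0) / self.steepness
        z60 = self.midpoint - np.log(90.0 / 60.0 - 1.0) / self.steepness
        return (float(z30), float(z60 - z30), float(1.0 - z60))


def gen_plm_stack(
    profile: SyntheticFiberProfile,
    image_shape: tuple[int, int] = (128, 64),
    retardance: float = np.pi / 2,
    i0: float = 1.0,
    offset: float = 0.05,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Crossed-polarizer image stack (21 frames) for a fiber-angle profile.

    Rows are depth (row 0 at the articular surface); every pixel of a row
    shares the profile angle at that depth.  Frame intensity follows the
    crossed-polars birefringence signal

        I(theta) = I0 * sin^2(2 (theta - phi)) * sin^2(retardance / 2)
                   + offset + noise

    which is extinguished (minimum) when the polarizer angle theta aligns
    with the fiber axis phi.  Returns an array of shape (21, rows, cols).
    """
    rows, cols = image_shape
    if rows < 4 or cols < 4:
        raise ValueError("image must be at least 4x4 pixels")
    depth = (np.arange(rows) + 0.5) / rows
    phi = np.asarray(profile.angle_at(depth))  # per-row angle, degrees
    theta = PLM_ANGLES_DEG[:, None, None]
    phi_grid = phi[None, :, None]
    amplitude = i0 * np.sin(retardance / 2.0) ** 2
    signal = amplitude * np.sin(np.radians(2.0 * (theta - phi_grid))) ** 2
    stack = np.broadcast_to(signal + offset, (21, rows, cols)).copy()
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        stack += rng.normal(0.0, noise_sd, size=stack.shape)
    return stack
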