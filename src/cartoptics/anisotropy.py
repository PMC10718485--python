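"""Spectral scattering anisotropy factors of cartilage zones.

The anisotropy factor is derived from the ratio of the bulk-tissue
reduced scattering coefficient to a zone's (unreduced) scattering
coefficient,

    g(lambda) = 1 - mu_s'(lambda) / mu_s(lambda),

a rearrangement of mu_s' = mu_s (1 - g) in which the bulk/zone ratio is
read as the zone's normalized contribution to bulk transport.  Because
the reduced coefficient comes from a Henyey–Greenstein-based inversion,
this g is an HG-referenced value (g_HG); the small-particle (Rayleigh)
component is accounted for afterwards by the Graaff correction

    g_mHG = g_HG * (1 - c),

with c the zone's fitted Rayleigh contribution fraction.

Two routes are provided: a raw route dividing measured spectra pointwise
(with masking where the ratio would imply g <= 0) and a smooth route
dividing fitted power-law curves, which is noise-free by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .powerlaw import PowerLawFit, evaluate_power_law
from .spectra import LocationLabel, Spectrum, ZoneLabel

__all__ = [
    "AnisotropySpectrum",
    "derive_g",
    "apply_rayleigh_correction",
    "smooth_power_law_g",
    "anisotropy_for_zone",
]


@dataclass(frozen=True)
class AnisotropySpectrum:
    """Paired g_HG and g_mHG spectra for one zone–location combination.

    ``mask`` flags wavelengths where mu_s' >= mu_s made g undefined
    (masked entries hold 0 in the stored spectra).
    """

    g_hg: Spectrum
    g_mhg: Spectrum
    c_used: float
    mask: np.ndarray
    zone: ZoneLabel | None = None
    location: LocationLabel | None = None


def derive_g(musp_bulk: Spectrum, mus_zone: Spectrum) -> tuple[Spectrum, np.ndarray]:
    """g(lambda) = 1 - mu_s'/mu_s from raw spectra, with masking.

    Both spectra must already share a grid (resample first).  Wavelengths
    where mu_s' >= mu_s (which would imply g <= 0) or mu_s <= 0 are
    masked; masked entries are stored as 0 and flagged in the returned
    boolean array.
    """
    if not np.array_equal(musp_bulk.wavelengths, mus_zone.wavelengths):
        raise ValueError("musp_bulk and mus_zone grids differ; resample first")
    mus = mus_zone.values
    musp = musp_bulk.values
    mask = (mus <= 0) | (musp >= mus)
    with np.errstate(divide="ignore", invalid="ignore"):
        g = 1.0 - musp / mus
    g = np.where(mask, 0.0, g)
    return Spectrum(musp_bulk.wavelengths, g, "g"), mask


def apply_rayleigh_correction(g_hg: Spectrum, c: float) -> Spectrum:
    """Graaff small-particle correction: g_mHG = g_HG * (1 - c)."""
    if not 0.0 <= c <= 1.0:
        raise ValueError(f"c must be in [0, 1], got {c}")
    return g_hg.with_values(g_hg.values * (1.0 - c))


def smooth_power_law_g(
    fit_bulk: PowerLawFit,
    fit_zone: PowerLawFit,
    grid: np.ndarray,
) -> tuple[Spectrum, np.ndarray]:
    """Noise-free g(lambda) from fitted power-law curves.

    Evaluates both fits on ``grid`` and forms 1 - bulk/zone.  Both fits
    must have converged and share the reference wavelength.  Wavelengths
    where the zone curve evaluates to <= 0 are masked.
    """
    if not (fit_bulk.converged and fit_zone.converged):
        raise ValueError("both fits must have converged")
    if fit_bulk.lambda0 != fit_zone.lambda0:
        raise ValueError("fits must share the reference wavelength lambda0")
    grid = np.asarray(grid, dtype=float)
    bulk = np.asarray(evaluate_power_law(fit_bulk, grid))
    zone = np.asarray(evaluate_power_law(fit_zone, grid))
    mask = zone <= 0
    with np.errstate(divide="ignore", invalid="ignore"):
        g = 1.0 - bulk / zone
    g = np.where(mask, 0.0, g)
    return Spectrum(grid, g, "g"), mask


def anisotropy_for_zone(
    fit_bulk: PowerLawFit,
    fit_zone: PowerLawFit,
    grid: np.ndarray,
    zone: ZoneLabel | None = None,
    location: LocationLabel | None = None,
) -> AnisotropySpectrum:
    """Headline smooth-route anisotropy with the zone's Rayleigh correction.

    The correction uses the zone's fitted small-particle fraction
    ``fit_zone.c`` (not the bulk one): the correction quantifies how the
    zone's own Rayleigh scatterers depress its effective anisotropy.
    """
    g_hg, mask = smooth_power_law_g(fit_bulk, fit_zone, grid)
    g_mhg = apply_rayleigh_correction(g_hg, fit_zone.c)
    return AnisotropySpectrum(
        g_hg=g_hg,
        g_mhg=g_mhg,
        c_used=fit_zone.c,
        mask=mask,
        zone=zone,
        location=location,
    )
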