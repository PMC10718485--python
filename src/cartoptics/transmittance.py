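"""Extinction spectra of thin cartilage sections from collimated transmittance.

A thin section (nominally 0.1 mm) is measured on-axis together with a dark
frame and an empty-path reference.  Beer–Lambert's law then gives the
extinction coefficient

    mu_t(lambda) = -ln[ (sample - dark) / (reference - dark) ] / d

in mm^-1 with d the section thickness in mm.  The logarithm is natural:
mu_t is an e-folding coefficient consumed downstream by exp(-mu_t * s)
path statistics.  For low-absorption cartilage mu_t is dominated by
scattering, so mu_s is taken equal to mu_t unless an absorption spectrum
is supplied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .spectra import LocationLabel, SampleGeometry, Spectrum, ZoneLabel

__all__ = [
    "TransmittanceRecord",
    "ExtinctionResult",
    "ExposureError",
    "compute_extinction",
    "extinction_to_mus",
]


class ExposureError(ValueError):
    """Reference does not exceed dark level somewhere in the band."""


@dataclass(frozen=True)
class TransmittanceRecord:
    """One collimated-transmittance acquisition triplet.

    All three spectra must share a wavelength grid (resample first); the
    reference must exceed the dark level everywhere analyzed.
    """

    sample: Spectrum
    dark: Spectrum
    reference: Spectrum
    geometry: SampleGeometry
    zone: ZoneLabel | None = None
    location: LocationLabel | None = None

    def __post_init__(self) -> None:
        for other, name in ((self.dark, "dark"), (self.reference, "reference")):
            if not np.array_equal(self.sample.wavelengths, other.wavelengths):
                raise ValueError(f"{name} grid differs from sample grid; resample first")


@dataclass(frozen=True)
class ExtinctionResult:
    """Extinction spectrum plus the mask of unusable wavelengths.

    ``mut`` carries the extinction coefficient (mm^-1); entries where the
    net sample counts were non-positive hold NaN and are flagged True in
    ``masked``.  ``masked_fraction`` summarizes how much of the band was
    lost.
    """

    mut: Spectrum
    masked: np.ndarray

    @property
    def masked_fraction(self) -> float:
        return float(self.masked.mean())

    @property
    def values_masked(self) -> np.ndarray:
        """Extinction values with masked wavelengths as NaN."""
        return np.where(self.masked, np.nan, self.mut.values)


def compute_extinction(rec: TransmittanceRecord) -> ExtinctionResult:
    """Beer–Lambert extinction from a transmittance triplet.

    Wavelengths where ``sample - dark <= 0`` (transmitted signal below the
    noise floor) are masked rather than clipped to a small epsilon, so
    the spectrum stays honest about where the measurement ran out of
    dynamic range.

    Raises
    ------
    ExposureError
        If ``reference - dark <= 0`` anywhere (saturated dark or missing
        reference exposure).
    """
    d = rec.geometry.thickness
    net_sample = rec.sample.values - rec.dark.values
    net_ref = rec.reference.values - rec.dark.values
    if np.any(net_ref <= 0):
        bad = rec.sample.wavelengths[net_ref <= 0]
        raise ExposureError(
            f"reference - dark <= 0 at {bad.size} wavelengths "
            f"(first at {bad[0]:.0f} nm); re-expose reference"
        )
    masked = net_sample <= 0
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = net_sample / net_ref
        mut = -np.log(ratio) / d
    mut[masked] = np.nan
    if masked.any():
        warnings.warn(
            f"{int(masked.sum())}/{masked.size} wavelengths masked "
            "(non-positive net sample counts)",
            stacklevel=2,
        )
    # Spectrum requires finite values: masked entries are stored as 0 and
    # surfaced as NaN through ExtinctionResult.values_masked.
    safe = np.where(masked, 0.0, mut)
    return ExtinctionResult(
        mut=Spectrum(rec.sample.wavelengths, safe, "mm^-1"),
        masked=masked,
    )


def extinction_to_mus(mut: Spectrum, mua: Spectrum | None = None) -> Spectrum:
    """Scattering coefficient from extinction.

    Cartilage absorbs weakly across 400–1400 nm, so by default
    ``mu_s = mu_t`` (the extinction is attributed entirely to scattering).
    If an absorption spectrum is supplied on the same grid,
    ``mu_s = mu_t - mu_a`` floored at zero; flooring is reported via a
    warning because it signals mu_a exceeding the measured extinction.
    """
    if mua is None:
        return Spectrum(mut.wavelengths, mut.values.copy(), "mm^-1")
    if not np.array_equal(mut.wavelengths, mua.wavelengths):
        raise ValueError("mua grid differs from mut grid; resample first")
    mus = mut.values - mua.values
    n_floor = int(np.sum(mus < 0))
    if n_floor:
        warnings.warn(
            f"mu_a exceeded mu_t at {n_floor} wavelengths; floored mu_s at 0",
            stacklevel=2,
        )
        mus = np.maximum(mus, 0.0)
    return Spectrum(mut.wavelengths, mus, "mm^-1")
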