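"""Shared spectral domain types, grid harmonization, and tabular I/O.

Every stage of the cartilage-optics pipeline passes wavelength-indexed
series around: extinction coefficients in mm^-1, dimensionless
transmittance ratios, anisotropy factors.  The :class:`Spectrum` container
enforces the conventions they all rely on — strictly increasing
wavelengths, finite values, and an analysis band of 400–1400 nm — and the
module functions handle resampling between instrument grids and stitching
the visible-band and NIR-band spectrometer outputs into one series.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BAND_NM",
    "DEFAULT_GRID_NM",
    "Spectrum",
    "ZoneLabel",
    "LocationLabel",
    "SampleGeometry",
    "BandError",
    "SpectrumParseError",
    "read_spectrum",
    "write_spectrum",
    "resample_to_grid",
    "stitch_bands",
    "common_grid",
]

#: Analysis band in nm; measurements outside it are clipped away.
BAND_NM = (400.0, 1400.0)

#: Default common analysis grid spacing (nm), finer than both the 3 nm
#: visible-band and 7 nm NIR-band instrument resolutions.
DEFAULT_GRID_NM = 1.0


class BandError(ValueError):
    """No data remains inside the analysis band."""


class SpectrumParseError(ValueError):
    """A tabular spectrum file could not be parsed."""


class ZoneLabel(str, enum.Enum):
    """Depth-wise cartilage zone: superficial, middle, deep, or bulk tissue."""

    SZ = "SZ"
    MZ = "MZ"
    DZ = "DZ"
    BULK = "BULK"


class LocationLabel(str, enum.Enum):
    """Anatomical origin within the knee joint.

    Lateral/medial femur (FL/FM), patella (PL/PM), and tibial plateau
    (TL/TM).
    """

    FL = "FL"
    FM = "FM"
    PL = "PL"
    PM = "PM"
    TL = "TL"
    TM = "TM"


@dataclass(frozen=True)
class SampleGeometry:
    """Cylindrical sample geometry.

    Parameters
    ----------
    thickness : float
        Axial thickness in mm.  Thin zone sections are nominally 0.1 mm;
        bulk plugs are on the order of 1–2 mm.
    radius : float
        Lateral radius in mm.
    """

    thickness: float
    radius: float = 7.5

    def __post_init__(self) -> None:
        if not (self.thickness > 0):
            raise ValueError(f"thickness must be > 0, got {self.thickness}")
        if not (self.radius > 0):
            raise ValueError(f"radius must be > 0, got {self.radius}")


@dataclass(frozen=True)
class Spectrum:
    """A wavelength-indexed series on the 400–1400 nm analysis band.

    Wavelengths are strictly increasing and values finite.  ``units_tag``
    is a free-form label (``"mm^-1"``, ``"counts"``, ``"fraction"``, …)
    carried along for provenance; no unit arithmetic is performed.
    """

    wavelengths: np.ndarray
    values: np.ndarray
    units_tag: str = ""

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "values", vals)
        if wl.ndim != 1 or vals.ndim != 1 or wl.shape != vals.shape:
            raise ValueError("wavelengths and values must be 1-D and equal length")
        if wl.size == 0:
            raise BandError("empty spectrum")
        if np.any(np.diff(wl) <= 0):
            raise ValueError("wavelengths must be strictly increasing (no duplicates)")
        if not np.all(np.isfinite(wl)) or not np.all(np.isfinite(vals)):
            raise ValueError("wavelengths and values must be finite")

    def __len__(self) -> int:
        return int(self.wavelengths.size)

    def clip_band(self, band: tuple[float, float] = BAND_NM) -> "Spectrum":
        """Restrict to ``band`` (inclusive); raise :class:`BandError` if empty."""
        lo, hi = band
        keep = (self.wavelengths >= lo) & (self.wavelengths <= hi)
        if not keep.any():
            raise BandError(
                f"no wavelengths inside [{lo}, {hi}] nm "
                f"(input covers {self.wavelengths[0]}–{self.wavelengths[-1]} nm)"
            )
        return Spectrum(self.wavelengths[keep], self.values[keep], self.units_tag)

    def with_values(self, values: np.ndarray, units_tag: str | None = None) -> "Spectrum":
        """Same grid, new values."""
        return Spectrum(
            self.wavelengths,
            values,
            self.units_tag if units_tag is None else units_tag,
        )

    def interp(self, wavelengths_nm: np.ndarray | float) -> np.ndarray | float:
        """Linear interpolation at ``wavelengths_nm`` (no extrapolation)."""
        q = np.asarray(wavelengths_nm, dtype=float)
        if np.any(q < self.wavelengths[0]) or np.any(q > self.wavelengths[-1]):
            raise ValueError(
                "requested wavelengths outside spectrum support "
                f"[{self.wavelengths[0]}, {self.wavelengths[-1]}] nm"
            )
        out = np.interp(q, self.wavelengths, self.values)
        return float(out) if np.isscalar(wavelengths_nm) else out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"wavelength_nm": self.wavelengths, "value": self.values}
        )


def read_spectrum(
    path: str | Path,
    dialect: str = "csv",
    band: tuple[float, float] | None = BAND_NM,
) -> Spectrum:
    """Read a two-column tabular spectrum (``wavelength_nm,value``).

    ``dialect`` is ``"csv"`` or ``"tsv"``.  A header row is optional and
    ``#`` comment lines are ignored.  Rows are sorted by wavelength and
    clipped to ``band`` (pass ``None`` to skip clipping).

    Raises
    ------
    SpectrumParseError
        On a malformed row (the message names the offending line).
    BandError
        If nothing remains inside the band.
    """
    path = Path(path)
    sep = {"csv": ",", "tsv": "\t"}.get(dialect)
    if sep is None:
        raise ValueError(f"unknown dialect {dialect!r}; expected 'csv' or 'tsv'")
    wl: list[float] = []
    vals: list[float] = []
    with path.open("r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = [p.strip() for p in line.split(sep)]
            if len(parts) < 2:
                raise SpectrumParseError(f"{path}:{lineno}: expected 2 columns, got {len(parts)}")
            try:
                w, v = float(parts[0]), float(parts[1])
            except ValueError:
                if lineno == 1:  # optional header
                    continue
                raise SpectrumParseError(
                    f"{path}:{lineno}: non-numeric row {line!r}"
                ) from None
            wl.append(w)
            vals.append(v)
    if not wl:
        raise SpectrumParseError(f"{path}: no data rows")
    order = np.argsort(wl, kind="stable")
    spec = Spectrum(np.asarray(wl)[order], np.asarray(vals)[order])
    return spec.clip_band(band) if band is not None else spec


def write_spectrum(spec: Spectrum, path: str | Path, value_name: str = "value") -> None:
    """Write ``wavelength_nm,<value_name>`` CSV."""
    df = pd.DataFrame({"wavelength_nm": spec.wavelengths, value_name: spec.values})
    df.to_csv(path, index=False)


def resample_to_grid(spec: Spectrum, grid: Sequence[float] | np.ndarray) -> Spectrum:
    """Linearly interpolate onto ``grid`` (must lie inside the spectrum's support).

    Values at grid points that coincide with original sample points are
    preserved exactly.  Extrapolation is refused.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or grid.size == 0:
        raise ValueError("grid must be a non-empty 1-D array")
    if grid[0] < spec.wavelengths[0] or grid[-1] > spec.wavelengths[-1]:
        raise ValueError(
            f"grid [{grid[0]}, {grid[-1]}] nm extends beyond spectrum support "
            f"[{spec.wavelengths[0]}, {spec.wavelengths[-1]}] nm"
        )
    vals = np.interp(grid, spec.wavelengths, spec.values)
    return Spectrum(grid, vals, spec.units_tag)


def common_grid(
    lo: float = BAND_NM[0],
    hi: float = BAND_NM[1],
    step_nm: float = DEFAULT_GRID_NM,
) -> np.ndarray:
    """The default 1 nm analysis grid, inclusive of both band edges."""
    n = int(round((hi - lo) / step_nm))
    return lo + step_nm * np.arange(n + 1)


def stitch_bands(
    vis: Spectrum,
    nir: Spectrum,
    boundary_nm: float = 950.0,
    overlap_nm: float = 50.0,
    grid_step_nm: float = DEFAULT_GRID_NM,
) -> Spectrum:
    """Merge visible-band and NIR-band spectra into one series.

    The dual-spectrometer setup produces a visible series covering below
    ``boundary_nm`` and an NIR series covering above it.  Inside the
    overlap window ``[boundary - overlap/2, boundary + overlap/2]`` the two
    are blended with a weight ramping linearly from pure-vis at the window
    start to pure-NIR at the window end; outside the window the output
    equals whichever input covers it.

    Raises a coverage error if there is a gap between the two bands.
    """
    if vis.wavelengths[0] > boundary_nm:
        raise ValueError("vis spectrum does not cover below the boundary")
    if nir.wavelengths[-1] < boundary_nm:
        raise ValueError("nir spectrum does not cover above the boundary")
    if vis.wavelengths[-1] < nir.wavelengths[0]:
        raise ValueError(
            f"coverage gap between vis (ends {vis.wavelengths[-1]} nm) and "
            f"nir (starts {nir.wavelengths[0]} nm)"
        )

    lo = vis.wavelengths[0]
    hi = nir.wavelengths[-1]
    grid = np.arange(lo, hi + 0.5 * grid_step_nm, grid_step_nm)

    half = overlap_nm / 2.0
    win_lo = max(boundary_nm - half, nir.wavelengths[0])
    win_hi = min(boundary_nm + half, vis.wavelengths[-1])
    if win_hi < win_lo:  # bands touch but do not overlap: hard switch
        win_lo = win_hi = boundary_nm

    out = np.empty_like(grid)
    vis_only = grid <= win_lo
    nir_only = grid >= win_hi
    blend = ~(vis_only | nir_only)

    out[vis_only] = np.interp(grid[vis_only], vis.wavelengths, vis.values)
    out[nir_only] = np.interp(grid[nir_only], nir.wavelengths, nir.values)
    if blend.any():
        t = (grid[blend] - win_lo) / (win_hi - win_lo)  # 0 → vis, 1 → nir
        v = np.interp(grid[blend], vis.wavelengths, vis.values)
        n = np.interp(grid[blend], nir.wavelengths, nir.values)
        out[blend] = (1.0 - t) * v + t * n

    tag = vis.units_tag or nir.units_tag
    return Spectrum(grid, out, tag)
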