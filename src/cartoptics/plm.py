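"""Collagen fiber orientation from crossed-polarizer image stacks.

A birefringent tissue section between crossed polarizers modulates the
transmitted intensity as sin^2(2(theta - phi)) where theta is the
polarizer orientation and phi the local fiber azimuth: the signal is
periodic in 90° and extinguished when the polarizer aligns with the
fiber axis.  From a 21-frame stack (theta = 0°..180° in 9° steps) the
per-pixel modulation is recovered by an exact linear harmonic fit

    I(theta) ~ s0 + s1 cos(4 theta) + s2 sin(4 theta)

whose coefficients are Stokes-parameter estimates of the modulation.
The fiber azimuth follows from the phase, and the Michelson contrast of
the fitted curve, A / s0 with A = sqrt(s1^2 + s2^2), is the parallelism
index — a [0, 1] measure of local fiber alignment.

Depth reduction averages azimuths per depth row with period-90° circular
statistics, and the 30°/60° thresholds on the (isotonically smoothed)
depth profile yield the superficial/middle/deep zone depth fractions.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.isotonic import IsotonicRegression

from .synthetic import PLM_ANGLES_DEG

__all__ = [
    "PLMStack",
    "OrientationMap",
    "DepthProfile",
    "fit_pixel_harmonics",
    "depth_profile",
    "zone_fractions",
    "analyze_stack",
    "read_plm_stack",
    "write_plm_stack",
]


@dataclass(frozen=True)
class PLMStack:
    """21 grayscale frames at polarizer angles 0°, 9°, …, 180°.

    ``frames`` has shape (21, rows, cols); rows run from the articular
    surface (row 0) downward unless ``surface_at_top`` is False.
    """

    frames: np.ndarray
    angles_deg: np.ndarray = None  # type: ignore[assignment]
    pixel_size_um: float = 3.5
    surface_at_top: bool = True

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames, dtype=float)
        object.__setattr__(self, "frames", frames)
        if self.angles_deg is None:
            object.__setattr__(self, "angles_deg", PLM_ANGLES_DEG.copy())
        angles = np.asarray(self.angles_deg, dtype=float)
        object.__setattr__(self, "angles_deg", angles)
        if frames.ndim != 3 or frames.shape[0] != 21:
            raise ValueError(f"expected 21 frames, got shape {frames.shape}")
        if angles.shape != (21,) or not np.allclose(np.diff(angles), 9.0):
            raise ValueError("angles must be 0..180 in strict 9 degree steps")

    @property
    def oriented_frames(self) -> np.ndarray:
        """Frames with row 0 at the articular surface."""
        return self.frames if self.surface_at_top else self.frames[:, ::-1, :]


@dataclass(frozen=True)
class OrientationMap:
    """Per-pixel fiber azimuth and parallelism index.

    ``phi_deg`` is the fiber angle in [0, 90) degrees relative to the
    articular surface (defined modulo 90° — the crossed-polars signal
    cannot distinguish phi from phi + 90°); ``pi_index`` the Michelson
    contrast of the fitted modulation; ``s0, s1, s2`` the harmonic
    coefficients.  Pixels without modulation have ``valid`` False and
    undefined phi.
    """

    phi_deg: np.ndarray
    pi_index: np.ndarray
    s0: np.ndarray
    s1: np.ndarray
    s2: np.ndarray
    valid: np.ndarray


@dataclass(frozen=True)
class DepthProfile:
    """Depth-resolved mean fiber angle and derived zone geometry."""

    depth_fraction: np.ndarray
    mean_angle_deg: np.ndarray
    zone_bounds: tuple[float, float]
    zone_fractions: tuple[float, float, float]


def fit_pixel_harmonics(stack: PLMStack) -> OrientationMap:
    """Least-squares harmonic fit of the crossed-polars modulation per pixel.

    The fit is exact for the assumed signal model, so — unlike a discrete
    brightest/darkest-frame lookup, which quantizes the azimuth to half
    the 9° angular step — the recovered phi is continuous.  The azimuth is
    chosen so that fitted-intensity minima (extinction) occur at
    theta = phi (mod 90°).
    """
    frames = stack.oriented_frames
    theta = np.radians(stack.angles_deg)
    design = np.column_stack(
        [np.ones_like(theta), np.cos(4.0 * theta), np.sin(4.0 * theta)]
    )
    flat = frames.reshape(21, -1)
    coef, *_ = np.linalg.lstsq(design, flat, rcond=None)
    rows, cols = frames.shape[1:]
    s0 = coef[0].reshape(rows, cols)
    s1 = coef[1].reshape(rows, cols)
    s2 = coef[2].reshape(rows, cols)
    amplitude = np.hypot(s1, s2)
    valid = (s0 > 0) & (amplitude > 1e-12 * np.maximum(s0, 1e-300))
    with np.errstate(divide="ignore", invalid="ignore"):
        pi_index = np.where(s0 > 0, np.clip(amplitude / np.where(s0 > 0, s0, 1.0), 0.0, 1.0), 0.0)
    # extinction at theta = phi requires the cos(4(theta-phi)) coefficient
    # to be negative there: I = s0 + A cos(4 theta - psi) with minimum at
    # 4 phi = psi + pi, i.e. phi = atan2(-s2, -s1) / 4 (mod 90°).
    phi = np.degrees(np.arctan2(-s2, -s1)) / 4.0
    phi = np.mod(phi, 90.0)
    phi = np.where(valid, phi, np.nan)
    return OrientationMap(
        phi_deg=phi, pi_index=pi_index, s0=s0, s1=s1, s2=s2, valid=valid
    )


def _circular_mean_90(phi_deg: np.ndarray, weights: np.ndarray | None = None) -> float:
    """Weighted circular mean of angles with period 90° (via 4*phi vectors)."""
    a = np.radians(4.0 * phi_deg)
    if weights is None:
        weights = np.ones_like(a)
    c = float(np.sum(weights * np.cos(a)))
    s = float(np.sum(weights * np.sin(a)))
    if c == 0.0 and s == 0.0:
        return np.nan
    return float(np.mod(np.degrees(np.arctan2(s, c)) / 4.0, 90.0))


def depth_profile(omap: OrientationMap, n_bins: int = 64) -> tuple[np.ndarray, np.ndarray]:
    """Depth-binned circular-mean fiber angle, weighted by parallelism.

    Pixels are grouped into ``n_bins`` bins along the depth (row) axis;
    each bin's angle is the period-90° circular mean of its valid pixels,
    weighted by the parallelism index.  Empty bins are linearly
    interpolated from their neighbours.  Returns (depth_fraction,
    mean_angle_deg), depth normalized to [0, 1].
    """
    rows = omap.phi_deg.shape[0]
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    edges = np.linspace(0, rows, n_bins + 1).astype(int)
    depth = (edges[:-1] + edges[1:]) / (2.0 * rows)
    angles = np.full(n_bins, np.nan)
    for i in range(n_bins):
        sl = slice(edges[i], max(edges[i + 1], edges[i] + 1))
        phi = omap.phi_deg[sl]
        w = omap.pi_index[sl]
        ok = omap.valid[sl] & np.isfinite(phi)
        if ok.any():
            angles[i] = _circular_mean_90(phi[ok], w[ok])
    nan = np.isnan(angles)
    if nan.all():
        raise ValueError("no valid pixels in any depth bin")
    if nan.any():
        angles[nan] = np.interp(depth[nan], depth[~nan], angles[~nan])
    return depth, angles


def zone_fractions(
    depth_fraction: np.ndarray,
    mean_angle_deg: np.ndarray,
    thresholds: tuple[float, float] = (30.0, 60.0),
) -> tuple[tuple[float, float, float], tuple[float, float]]:
    """Zone depth fractions from the 30°/60° angular thresholds.

    The raw profile is first isotonically smoothed (the fiber angle is
    monotone non-decreasing with depth in intact cartilage; this also
    resolves the modulo-90° ambiguity at the profile level), then each
    threshold crossing is located by linear interpolation of the smoothed
    profile.  Returns ``((sz, mz, dz), (sz_end, mz_end))`` with the
    fractions summing to 1.
    """
    t1, t2 = thresholds
    if not 0 < t1 < t2 < 90:
        raise ValueError("thresholds must satisfy 0 < t1 < t2 < 90")
    depth = np.asarray(depth_fraction, dtype=float)
    ang = IsotonicRegression(increasing=True).fit_transform(depth, np.asarray(mean_angle_deg, dtype=float))

    def crossing(level: float) -> float:
        above = ang >= level
        if not above.any():
            return 1.0
        i = int(np.argmax(above))
        if i == 0:
            return 0.0
        # linear interpolation between the bracketing bins
        a0, a1 = ang[i - 1], ang[i]
        d0, d1 = depth[i - 1], depth[i]
        if a1 == a0:
            return float(d1)
        return float(d0 + (level - a0) * (d1 - d0) / (a1 - a0))

    sz_end = crossing(t1)
    mz_end = max(crossing(t2), sz_end)
    fractions = (sz_end, mz_end - sz_end, 1.0 - mz_end)
    return fractions, (sz_end, mz_end)


def analyze_stack(stack: PLMStack, n_bins: int = 64) -> DepthProfile:
    """Full reduction: harmonic fit, depth profile, zone fractions."""
    omap = fit_pixel_harmonics(stack)
    depth, ang = depth_profile(omap, n_bins=n_bins)
    fracs, bounds = zone_fractions(depth, ang)
    return DepthProfile(
        depth_fraction=depth,
        mean_angle_deg=ang,
        zone_bounds=bounds,
        zone_fractions=fracs,
    )


def write_plm_stack(frames: np.ndarray, path: str | Path) -> None:
    """Write a 21-frame stack as a multipage TIFF (float32)."""
    import tifffile

    tifffile.imwrite(Path(path), np.asarray(frames, dtype=np.float32))


def read_plm_stack(path: str | Path, **kwargs) -> PLMStack:
    """Read a 21-page TIFF into a :class:`PLMStack`."""
    import tifffile

    frames = tifffile.imread(Path(path))
    return PLMStack(frames=frames, **kwargs)
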