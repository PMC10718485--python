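"""Monte-Carlo photon transport in a cylindrical tissue sample.

Forward model for integrating-sphere measurements: photon packets are
launched as a pencil beam on the cylinder axis and tracked through a
homogeneous turbid medium with

* exponential free-path sampling, step ``s = -ln(u) / (mu_a + mu_s)``,
* implicit capture (a fraction ``mu_a / (mu_a + mu_s)`` of the packet
  weight is absorbed at every interaction),
* Henyey–Greenstein angular deflection with anisotropy ``g`` and uniform
  azimuth,
* unpolarized Fresnel reflection/transmission at the top and bottom faces
  (refractive-index step sample/surround), specular entrance reflection
  handled deterministically,
* Russian-roulette termination of low-weight packets (unbiased
  reweighting).

Packets crossing the lateral cylinder wall are tallied as side loss.
Energy bookkeeping is exact per run: diffuse reflectance + transmittance
+ absorbed + side loss + specular + net roulette correction equals the
launched weight to floating-point precision.

An inverse estimator recovers (mu_a, mu_s') per wavelength from measured
(Rd, Td) pairs through a precomputed lookup table over a log-spaced
property grid, mirroring the standard inverse integrating-sphere
workflow.  The table is parameterized in the reduced scattering
coefficient mu_s' = mu_s (1 - g); the simulator converts via the
similarity relation with the configured g.
"""

from __future__ import annotations

import hashlib
import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.interpolate import RegularGridInterpolator
from scipy.optimize import minimize

from .spectra import LocationLabel, SampleGeometry, Spectrum

try:  # pragma: no cover - exercised implicitly
    from numba import njit as _njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def _njit(*args, **kwargs):
        def wrap(fn):
            return fn

        if args and callable(args[0]):
            return args[0]
        return wrap


__all__ = [
    "TransportConfig",
    "SphereMeasurement",
    "RTResult",
    "LookupTable",
    "OpticalPropertyEstimate",
    "sample_hg_cosine",
    "specular_reflectance",
    "simulate_rt",
    "build_lookup_table",
    "invert_sphere",
]


@dataclass(frozen=True)
class TransportConfig:
    """Fixed conditions of a transport simulation.

    Defaults are the standard bulk-cartilage assumptions: refractive index
    1.358, anisotropy 0.9, air surround.
    """

    geometry: SampleGeometry
    n_sample: float = 1.358
    n_surround: float = 1.0
    g: float = 0.9
    photons: int = 10_000
    seed: int = 0
    roulette_threshold: float = 1e-4
    roulette_survival: float = 0.1

    def __post_init__(self) -> None:
        if not (0.0 <= self.g < 1.0):
            raise ValueError(f"g must be in [0, 1), got {self.g}")
        if self.n_sample < 1.0 or self.n_surround < 1.0:
            raise ValueError("refractive indices must be >= 1")
        if self.photons < 1_000:
            raise ValueError(f"photons must be >= 1000, got {self.photons}")
        if not (0.0 < self.roulette_survival <= 1.0):
            raise ValueError("roulette_survival must be in (0, 1]")

    def fingerprint(self) -> str:
        """Hash of the physical configuration (photons and seed excluded)."""
        payload = json.dumps(
            {
                "thickness": self.geometry.thickness,
                "radius": self.geometry.radius,
                "n_sample": self.n_sample,
                "n_surround": self.n_surround,
                "g": self.g,
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass(frozen=True)
class SphereMeasurement:
    """Paired diffuse reflectance / total transmittance spectra."""

    Rd: Spectrum
    Td: Spectrum
    geometry: SampleGeometry
    location: LocationLabel | None = None

    def __post_init__(self) -> None:
        if not np.array_equal(self.Rd.wavelengths, self.Td.wavelengths):
            raise ValueError("Rd and Td must share a wavelength grid")
        if np.any(self.Rd.values < 0) or np.any(self.Td.values < 0):
            raise ValueError("Rd and Td must be non-negative")
        if np.any(self.Rd.values + self.Td.values > 1.0 + 1e-9):
            raise ValueError("Rd + Td must not exceed 1 (energy conservation)")


@dataclass(frozen=True)
class RTResult:
    """Energy fractions from one forward simulation (per launched photon)."""

    rd: float
    td: float
    absorbed: float
    side_loss: float
    specular: float
    roulette_net: float
    photons: int

    @property
    def balance_deficit(self) -> float:
        """|1 - sum of all tallies| — exact bookkeeping check."""
        total = (
            self.rd
            + self.td
            + self.absorbed
            + self.side_loss
            + self.specular
            + self.roulette_net
        )
        return abs(1.0 - total)

    def se(self, fraction: float) -> float:
        """Binomial-style standard error of a tallied fraction."""
        p = min(max(fraction, 1.0 / self.photons), 1.0 - 1.0 / self.photons)
        return math.sqrt(p * (1.0 - p) / self.photons)


def sample_hg_cosine(g: float, u) -> np.ndarray | float:
    """Inverse-CDF sample of the Henyey–Greenstein deflection cosine.

    For ``g == 0`` the distribution is isotropic (``2u - 1``); otherwise

        cos(theta) = (1 + g^2 - ((1 - g^2) / (1 - g + 2 g u))^2) / (2 g)

    The mean of the distribution equals ``g``.
    """
    u_arr = np.asarray(u, dtype=float)
    if np.any((u_arr < 0) | (u_arr > 1)):
        raise ValueError("u must be in [0, 1]")
    if abs(g) < 1e-9:
        out = 2.0 * u_arr - 1.0
    else:
        frac = (1.0 - g * g) / (1.0 - g + 2.0 * g * u_arr)
        out = (1.0 + g * g - frac * frac) / (2.0 * g)
        out = np.clip(out, -1.0, 1.0)
    return float(out) if np.isscalar(u) else out


def specular_reflectance(n_from: float, n_to: float) -> float:
    """Normal-incidence Fresnel reflectance between two indices."""
    return ((n_to - n_from) / (n_to + n_from)) ** 2


@_njit(cache=True)
def _fresnel_unpolarized(cosi: float, m: float) -> float:
    """Unpolarized Fresnel reflectance, incidence from the medium with
    relative index m = n_inside / n_outside."""
    if m == 1.0:
        return 0.0
    sini = math.sqrt(max(0.0, 1.0 - cosi * cosi))
    sint = m * sini
    if sint >= 1.0:
        return 1.0  # total internal reflection
    cost = math.sqrt(1.0 - sint * sint)
    rs = (m * cosi - cost) / (m * cosi + cost)
    rp = (m * cost - cosi) / (m * cost + cosi)
    return 0.5 * (rs * rs + rp * rp)


@_njit(cache=True)
def _transport_kernel(
    mua: float,
    mus: float,
    d: float,
    radius: float,
    m: float,  # n_sample / n_surround
    g: float,
    n_photons: int,
    seed: int,
    w0: float,
    r_thresh: float,
    r_surv: float,
):
    np.random.seed(seed)
    rd = 0.0
    td = 0.0
    absorbed = 0.0
    side = 0.0
    roulette_net = 0.0
    mut = mua + mus
    r2max = radius * radius

    for _ in range(n_photons):
        x = 0.0
        y = 0.0
        z = 0.0
        ux = 0.0
        uy = 0.0
        uz = 1.0
        w = w0
        alive = True

        while alive:
            if mut > 0.0:
                s = -math.log(np.random.random()) / mut
            else:
                s = 1.0e12

            # propagate, handling top/bottom faces until the step is spent
            while True:
                if uz > 1e-12:
                    db = (d - z) / uz
                    exit_top = False
                elif uz < -1e-12:
                    db = -z / uz
                    exit_top = True
                else:
                    db = 1.0e12
                    exit_top = False

                if db < s:
                    x += ux * db
                    y += uy * db
                    z = 0.0 if exit_top else d
                    s -= db
                    if x * x + y * y > r2max:
                        side += w
                        alive = False
                        break
                    cosi = abs(uz)
                    refl = _fresnel_unpolarized(cosi, m)
                    if np.random.random() < refl:
                        uz = -uz
                        continue
                    if exit_top:
                        rd += w
                    else:
                        td += w
                    alive = False
                    break
                else:
                    x += ux * s
                    y += uy * s
                    z += uz * s
                    if x * x + y * y > r2max:
                        side += w
                        alive = False
                    break

            if not alive:
                break

            # implicit capture
            if mut > 0.0:
                absorbed += w * (mua / mut)
                w *= mus / mut
                if w <= 0.0:
                    break

            # Henyey-Greenstein deflection, uniform azimuth
            u1 = np.random.random()
            if g < 1e-9:
                cost = 2.0 * u1 - 1.0
            else:
                frac = (1.0 - g * g) / (1.0 - g + 2.0 * g * u1)
                cost = (1.0 + g * g - frac * frac) / (2.0 * g)
                if cost > 1.0:
                    cost = 1.0
                elif cost < -1.0:
                    cost = -1.0
            sint = math.sqrt(1.0 - cost * cost)
            phi = 2.0 * math.pi * np.random.random()
            cosp = math.cos(phi)
            sinp = math.sin(phi)
            if abs(uz) > 0.99999:
                ux = sint * cosp
                uy = sint * sinp
                uz = cost if uz > 0.0 else -cost
            else:
                tmp = math.sqrt(1.0 - uz * uz)
                uxn = sint * (ux * uz * cosp - uy * sinp) / tmp + ux * cost
                uyn = sint * (uy * uz * cosp + ux * sinp) / tmp + uy * cost
                uzn = -sint * cosp * tmp + uz * cost
                norm = math.sqrt(uxn * uxn + uyn * uyn + uzn * uzn)
                ux = uxn / norm
                uy = uyn / norm
                uz = uzn / norm

            # Russian roulette
            if w < r_thresh:
                if np.random.random() < r_surv:
                    gain = w * (1.0 / r_surv - 1.0)
                    roulette_net -= gain
                    w += gain
                else:
                    roulette_net += w
                    alive = False

    n = float(n_photons)
    return rd / n, td / n, absorbed / n, side / n, roulette_net / n


def simulate_rt(mua: float, mus: float, config: TransportConfig) -> RTResult:
    """Forward-simulate diffuse reflectance and transmittance.

    Parameters are the absorption and (unreduced) scattering coefficients
    in mm^-1.  Returns per-launched-photon energy fractions; the specular
    entrance reflection at normal incidence is deterministic and reported
    separately.
    """
    if mua < 0 or mus < 0:
        raise ValueError("mua and mus must be non-negative")
    m = config.n_sample / config.n_surround
    r_sp = specular_reflectance(config.n_surround, config.n_sample)
    w0 = 1.0 - r_sp
    rd, td, ab, side, rnet = _transport_kernel(
        float(mua),
        float(mus),
        float(config.geometry.thickness),
        float(config.geometry.radius),
        float(m),
        float(config.g),
        int(config.photons),
        int(config.seed) % (2**31),
        float(w0),
        float(config.roulette_threshold),
        float(config.roulette_survival),
    )
    result = RTResult(
        rd=rd,
        td=td,
        absorbed=ab,
        side_loss=side,
        specular=r_sp,
        roulette_net=rnet,
        photons=config.photons,
    )
    if result.balance_deficit > 1e-6:
        warnings.warn(
            f"energy bookkeeping deficit {result.balance_deficit:.2e} exceeds 1e-6",
            stacklevel=2,
        )
    return result


@dataclass(frozen=True)
class LookupTable:
    """Forward-model tables Rd/Td over a log-spaced (mu_a, mu_s') grid."""

    mua_grid: np.ndarray
    musp_grid: np.ndarray
    Rd_table: np.ndarray
    Td_table: np.ndarray
    config_fingerprint: str

    def __post_init__(self) -> None:
        shape = (len(self.mua_grid), len(self.musp_grid))
        if self.Rd_table.shape != shape or self.Td_table.shape != shape:
            raise ValueError("table shapes must match grid lengths")
        for tab in (self.Rd_table, self.Td_table):
            if np.any(tab < 0) or np.any(tab > 1):
                raise ValueError("table values must lie in [0, 1]")

    def save(self, path: str | Path) -> None:
        payload = {
            "mua_grid": self.mua_grid.tolist(),
            "musp_grid": self.musp_grid.tolist(),
            "Rd_table": self.Rd_table.tolist(),
            "Td_table": self.Td_table.tolist(),
            "config_fingerprint": self.config_fingerprint,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "LookupTable":
        payload = json.loads(Path(path).read_text())
        return cls(
            mua_grid=np.asarray(payload["mua_grid"]),
            musp_grid=np.asarray(payload["musp_grid"]),
            Rd_table=np.asarray(payload["Rd_table"]),
            Td_table=np.asarray(payload["Td_table"]),
            config_fingerprint=payload["config_fingerprint"],
        )


def build_lookup_table(
    config: TransportConfig,
    mua_range: tuple[float, float] = (1e-3, 1.0),
    musp_range: tuple[float, float] = (0.1, 10.0),
    nodes: tuple[int, int] = (24, 24),
) -> LookupTable:
    """Forward-simulate Rd/Td on a log-spaced optical-property grid.

    Each node runs one simulation at ``mu_s = mu_s' / (1 - g)``.
    Monotonicity spot checks (Rd increasing in mu_s' at fixed mu_a; Td
    decreasing in mu_a at fixed mu_s') are logged as warnings when the
    Monte-Carlo noise at the configured photon count violates them
    grossly.
    """
    if mua_range[0] <= 0 or musp_range[0] <= 0:
        raise ValueError("ranges must be positive (log-spaced grid)")
    mua_grid = np.geomspace(*mua_range, nodes[0])
    musp_grid = np.geomspace(*musp_range, nodes[1])
    Rd = np.empty((nodes[0], nodes[1]))
    Td = np.empty_like(Rd)
    one_minus_g = 1.0 - config.g
    for i, mua in enumerate(mua_grid):
        for j, musp in enumerate(musp_grid):
            cfg = TransportConfig(
                geometry=config.geometry,
                n_sample=config.n_sample,
                n_surround=config.n_surround,
                g=config.g,
                photons=config.photons,
                seed=config.seed + 977 * i + 13 * j,
                roulette_threshold=config.roulette_threshold,
                roulette_survival=config.roulette_survival,
            )
            res = simulate_rt(mua, musp / one_minus_g, cfg)
            Rd[i, j] = res.rd
            Td[i, j] = res.td
    # monotonicity spot-checks at the grid corners of the mid row/column
    mid = nodes[0] // 2
    if Rd[mid, -1] < Rd[mid, 0]:
        warnings.warn("LUT spot-check: Rd not increasing in mu_s'", stacklevel=2)
    mid_j = nodes[1] // 2
    if Td[-1, mid_j] > Td[0, mid_j]:
        warnings.warn("LUT spot-check: Td not decreasing in mu_a", stacklevel=2)
    return LookupTable(
        mua_grid=mua_grid,
        musp_grid=musp_grid,
        Rd_table=np.clip(Rd, 0.0, 1.0),
        Td_table=np.clip(Td, 0.0, 1.0),
        config_fingerprint=config.fingerprint(),
    )


@dataclass(frozen=True)
class OpticalPropertyEstimate:
    """Per-wavelength (mu_a, mu_s') recovered from sphere measurements."""

    mua: Spectrum
    musp: Spectrum
    residual: np.ndarray
    out_of_range: np.ndarray


def invert_sphere(
    meas: SphereMeasurement,
    lut: LookupTable,
    config: TransportConfig,
) -> OpticalPropertyEstimate:
    """Recover (mu_a, mu_s') per wavelength from (Rd, Td).

    Minimizes the squared relative residual of the measured (Rd, Td)
    against bilinear interpolation of the lookup table in
    (log mu_a, log mu_s') space: a coarse scan over a refined mesh seeds a
    Nelder–Mead polish, both confined to the table's hull.  Wavelengths
    whose optimum sits on the hull boundary are flagged out-of-range
    rather than failing.
    """
    if lut.config_fingerprint != config.fingerprint():
        raise ValueError(
            "lookup table fingerprint does not match transport config "
            "(geometry / n / g differ)"
        )
    la = np.log(lut.mua_grid)
    ls = np.log(lut.musp_grid)
    interp_rd = RegularGridInterpolator((la, ls), lut.Rd_table, bounds_error=True)
    interp_td = RegularGridInterpolator((la, ls), lut.Td_table, bounds_error=True)

    # refined scan mesh in log space
    fa = np.linspace(la[0], la[-1], 96)
    fs = np.linspace(ls[0], ls[-1], 96)
    mesh = np.array(np.meshgrid(fa, fs, indexing="ij")).reshape(2, -1).T
    rd_mesh = interp_rd(mesh)
    td_mesh = interp_td(mesh)

    n_wl = len(meas.Rd)
    mua_out = np.empty(n_wl)
    musp_out = np.empty(n_wl)
    resid_out = np.empty(n_wl)
    oor = np.zeros(n_wl, dtype=bool)
    eps = 1e-6

    for k in range(n_wl):
        rd_m = meas.Rd.values[k]
        td_m = meas.Td.values[k]
        wr = 1.0 / max(rd_m, eps) ** 2
        wt = 1.0 / max(td_m, eps) ** 2
        obj_mesh = wr * (rd_mesh - rd_m) ** 2 + wt * (td_mesh - td_m) ** 2
        x0 = mesh[np.argmin(obj_mesh)]

        def objective(xy):
            a = np.clip(xy[0], la[0], la[-1])
            s = np.clip(xy[1], ls[0], ls[-1])
            pt = np.array([[a, s]])
            return float(
                wr * (interp_rd(pt)[0] - rd_m) ** 2
                + wt * (interp_td(pt)[0] - td_m) ** 2
            )

        sol = minimize(objective, x0, method="Nelder-Mead", options={"xatol": 1e-4, "fatol": 1e-10})
        a_opt = float(np.clip(sol.x[0], la[0], la[-1]))
        s_opt = float(np.clip(sol.x[1], ls[0], ls[-1]))
        mua_out[k] = math.exp(a_opt)
        musp_out[k] = math.exp(s_opt)
        resid_out[k] = sol.fun
        edge_tol = 1e-3
        if (
            a_opt - la[0] < edge_tol
            or la[-1] - a_opt < edge_tol
            or s_opt - ls[0] < edge_tol
            or ls[-1] - s_opt < edge_tol
        ):
            oor[k] = True

    wl = meas.Rd.wavelengths
    return OpticalPropertyEstimate(
        mua=Spectrum(wl, mua_out, "mm^-1"),
        musp=Spectrum(wl, musp_out, "mm^-1"),
        residual=resid_out,
        out_of_range=oor,
    )
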