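"""Published reference values for bovine articular cartilage scattering.

Literature-reported means and standard deviations of the Mie–Rayleigh
power-law parameters of bovine knee cartilage, per depth zone (SZ/MZ/DZ
from thin-section collimated transmittance; BULK from integrating-sphere
reduced scattering) and anatomical location.  Units: ``alpha`` in mm^-1
(the scattering coefficient at the 500 nm reference wavelength), ``b``
dimensionless (Mie scatterer size parameter), ``c`` a fraction in [0, 1]
(Rayleigh contribution).

These values serve two roles: they seed the synthetic-data generators at
realistic magnitudes, and they are the inputs for the worked-example
zone-mean aggregations.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "LOCATIONS",
    "zone_parameter_table",
    "zone_means",
]

LOCATIONS = ["FL", "FM", "PL", "PM", "TL", "TM"]

# (parameter, zone) -> per-location (mean, sd), location order as in LOCATIONS.
_ZONE_PARAMS: dict[tuple[str, str], list[tuple[float, float]]] = {
    ("alpha", "SZ"): [(22.5, 7.99), (18.23, 4.70), (17.84, 0.0), (12.75, 1.63), (21.7, 3.86), (8.08, 0.0)],
    ("alpha", "MZ"): [(33.25, 30.64), (22.60, 9.36), (25.02, 0.0), (11.95, 2.29), (30.23, 9.41), (14.08, 7.38)],
    ("alpha", "DZ"): [(34.83, 8.66), (34.94, 11.02), (20.05, 0.0), (19.64, 3.56), (45.44, 9.82), (29.86, 8.03)],
    ("alpha", "BULK"): [(2.53, 0.16), (2.06, 0.4), (3.0, 0.0), (2.34, 0.3), (3.45, 0.62), (2.23, 0.13)],
    ("b", "SZ"): [(1.27, 0.31), (1.68, 0.2), (2.14, 0.0), (1.22, 0.27), (1.58, 0.14), (0.55, 0.0)],
    ("b", "MZ"): [(0.85, 0.63), (1.30, 0.47), (1.75, 0.0), (1.69, 0.05), (1.49, 0.31), (1.02, 0.11)],
    ("b", "DZ"): [(1.07, 0.29), (1.22, 0.45), (1.61, 0.0), (1.74, 0.30), (1.12, 0.17), (0.98, 0.03)],
    ("b", "BULK"): [(2.56, 0.18), (2.53, 0.18), (2.68, 0.0), (2.56, 0.37), (2.52, 0.03), (2.41, 0.27)],
    ("c", "SZ"): [(0.05, 0.07), (0.10, 0.03), (0.06, 0.0), (0.27, 0.19), (0.0, 0.0), (0.12, 0.0)],
    ("c", "MZ"): [(0.07, 0.1), (0.16, 0.1), (0.05, 0.0), (0.14, 0.14), (0.0, 0.0), (0.22, 0.06)],
    ("c", "DZ"): [(0.02, 0.04), (0.04, 0.08), (0.08, 0.0), (0.0, 0.0), (0.02, 0.03), (0.07, 0.03)],
    ("c", "BULK"): [(0.05, 0.06), (0.08, 0.13), (0.0, 0.0), (0.17, 0.17), (0.0, 0.0), (0.0, 0.0)],
}


def zone_parameter_table() -> pd.DataFrame:
    """Long-format table: parameter, zone, location, mean, sd."""
    rows = []
    for (param, zone), entries in _ZONE_PARAMS.items():
        for loc, (mean, sd) in zip(LOCATIONS, entries):
            rows.append(
                {"parameter": param, "zone": zone, "location": loc, "mean": mean, "sd": sd}
            )
    return pd.DataFrame(rows)


def zone_means(parameter: str, zone: str) -> float:
    """Unweighted mean of the per-location published means for one zone.

    E.g. ``zone_means("b", "SZ")`` averages the six per-location Mie
    size-parameter means of the superficial zone.
    """
    try:
        entries = _ZONE_PARAMS[(parameter, zone)]
    except KeyError:
        raise KeyError(f"no published entry for parameter={parameter!r} zone={zone!r}") from None
    return float(sum(m for m, _ in entries) / len(entries))
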