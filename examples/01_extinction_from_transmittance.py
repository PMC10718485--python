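"""Beer-Lambert extinction of a thin cartilage section.

Builds a synthetic collimated-transmittance triplet (sample, dark,
reference counts) for a 100 um deep-zone section with a known scattering
spectrum, then recovers the extinction coefficient mu_t(lambda).
"""

import numpy as np

from cartoptics import SampleGeometry, TransmittanceRecord, compute_extinction
from cartoptics.synthetic import (
    SyntheticScatterTruth,
    gen_mus_spectrum,
    gen_transmittance_triplet,
)

grid = np.arange(400.0, 1401.0, 10.0)
truth = SyntheticScatterTruth(alpha=30.79, b=1.29, c=0.04)  # deep-zone scale
mus = gen_mus_spectrum(truth, grid)
geometry = SampleGeometry(thickness=0.1)  # 100 um section

sample, dark, reference = gen_transmittance_triplet(mus, geometry, noise_sd=20.0, seed=1)
record = TransmittanceRecord(sample=sample, dark=dark, reference=reference, geometry=geometry)
result = compute_extinction(record)

for wl in (500.0, 700.0, 1000.0, 1300.0):
    i = np.argmin(np.abs(grid - wl))
    print(f"lambda = {wl:6.0f} nm   mu_t = {result.mut.values[i]:6.2f} mm^-1   "
          f"true mu_s = {mus.values[i]:6.2f} mm^-1")
print(f"masked fraction: {result.masked_fraction:.3f}")
# mu_t tracks the true mu_s because cartilage absorption is negligible:
# at 500 nm the deep zone extinguishes ~30 mm^-1, decaying as a power law.
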