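"""Rayleigh/Mie power-law decomposition of a scattering spectrum.

Fits mu_s(lambda) = alpha [c (lambda/500)^-4 + (1-c) (lambda/500)^-b]
to a noisy synthetic middle-zone spectrum and prints the recovered
parameters against the truth.
"""

import numpy as np

from cartoptics import fit_power_law
from cartoptics.synthetic import SyntheticScatterTruth, gen_mus_spectrum

grid = np.arange(400.0, 1401.0, 5.0)
truth = SyntheticScatterTruth(alpha=22.86, b=1.35, c=0.11)  # middle-zone scale
spec = gen_mus_spectrum(truth, grid, noise_sd=0.02, seed=7, multiplicative=True)

fit = fit_power_law(spec, "rayleigh4", seed=7)
print(f"alpha: fitted {fit.alpha:6.2f}  true {truth.alpha:6.2f}  (mm^-1, mu_s at 500 nm)")
print(f"b    : fitted {fit.b:6.3f}  true {truth.b:6.3f}  (Mie size parameter)")
print(f"c    : fitted {fit.c:6.3f}  true {truth.c:6.3f}  (Rayleigh fraction)")
print(f"fit quality: R^2 = {100 * fit.r2:.2f}%  RMSE = {fit.rmse:.4f} mm^-1")
# At 2% noise the three parameters come back within a few percent; c is
# the softest because the lambda^-4 term only dominates below ~500 nm.
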