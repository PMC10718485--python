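"""Full synthetic pipeline run: sections to statistics.

Runs every stage on a reduced problem size and prints the zone summary
and the zone-wise post-hoc comparison for the scatterer-density
parameter alpha.
"""

import tempfile
from pathlib import Path

from cartoptics import PipelineConfig, run_pipeline

config = PipelineConfig(
    seed=1,
    grid_step_nm=20.0,
    samples_per_group=3,
    sphere_wavelengths_nm=(600.0, 1000.0),
    lut_nodes=(8, 8),
    lut_photons=3_000,
)
out = Path(tempfile.mkdtemp(prefix="cartoptics_"))
result = run_pipeline(config, out)

print("zone summary (alpha = mu_s at 500 nm, mm^-1):")
print(result.zone_summary[["zone", "n", "alpha_mean", "alpha_sd", "b_mean", "c_mean"]])
print()
for res in result.stats_results:
    if res.test_id == 1 and res.parameter == "alpha" and not res.skipped:
        print(f"zones post-hoc ({res.branch} branch), adjusted p-values:")
        print(res.posthoc.round(4))
print(f"\nartifacts in {out}")
# alpha rises with depth (SZ < MZ < DZ) and the deep zone separates from
# the superficial zone in the post-hoc matrix, mirroring the depth-wise
# scatterer-density gradient the pipeline is built to quantify.
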