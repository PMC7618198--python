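"""Dynamic vs static distortion correction on a rigid-motion series.

Head rotation changes the B0 field; a static field map (acquired once,
here: the pose-0 ground truth, rigidly re-registered) cannot follow
those changes, while per-readout rEPI field mapping can.  Temporal
standard deviation and tSNR of the corrected series quantify this.
Runs a few minutes at this size.
"""

import json

from repimap.pipeline import RunConfig, run_motion_demo
from repimap.recon import ReconConfig

cfg = RunConfig(
    n=48, n_coils=6, R=1, noise_sigma=0.02,
    field_kind="mixed", field_amplitude_hz=60,
    n_volumes=16, block_len=4,
    recon=ReconConfig(n_iterations=10, n_inner=10),
    seed=5,
)
metrics = run_motion_demo(cfg)
print("masked mean temporal SD per processing:")
print(json.dumps(metrics["mean_temporal_sd"], indent=1))
print("masked mean tSNR per processing:")
print(json.dumps(metrics["mean_tsnr"], indent=1))
print(f"voxelwise tSNR ratio dynamic/static: "
      f"{metrics['tsnr_ratio_dynamic_over_static']:.3f}")
print("(uncorrected > static > dynamic temporal SD reproduces the value "
      "of per-volume field mapping under motion)")
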