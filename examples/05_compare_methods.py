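"""Three-way method comparison on a motion-corrupted phantom.

Runs the full pipeline three ways — nearest-neighbour baseline,
velocity-constrained Kalman tracking, and vc-Kalman plus motion
compensation — on the same tissue-dominant phantom with respiration-like
motion, and tabulates CNR and velocity nRMSE for each.

Takes ~30 s on one CPU.
"""

from vckulm import generate_phantom, regions_from_vessel_mask
from vckulm.pipeline import compare_methods
from vckulm.studies import motion_study_config, motion_study_pipeline

stack, truth = generate_phantom(motion_study_config(seed=11))
vessel_region, noise_region = regions_from_vessel_mask(truth.vessel_mask)

table = compare_methods(stack, motion_study_pipeline(),
                        vessel_region=vessel_region,
                        noise_region=noise_region)
cols = ["method", "cnr", "nrmse", "n_tracks", "mean_trace_length",
        "mean_flow_speed"]
print(table[cols].round(3).to_string(index=False))
# Expected pattern: CNR rises and nRMSE falls from the baseline through
# vc-Kalman to vc-Kalman + motion compensation — prediction and the VD
# constraint remove bad links, and compensation removes the motion smear
# and its velocity bias.
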