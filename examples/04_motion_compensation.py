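"""Block-NCC tissue-motion estimation with DP-guided search.

Applies a known sinusoidal motion to a textured scene with bright static
landmarks, estimates per-frame displacement fields against the middle
reference frame, and verifies that compensated landmark detections return
to their rest positions. Also reports the equivalence of the seeded
hill-climb search with an exhaustive sweep.
"""

import numpy as np
from scipy import ndimage

from vckulm import (FrameStack, LocalizationConfig, MotionConfig,
                    compensate_detections, dp_search_vs_exhaustive,
                    estimate_displacement_field, localize_frame)

rng = np.random.default_rng(4)
scene = ndimage.gaussian_filter(rng.normal(size=(96, 96)), 1.5) + 2.0
landmarks = [(rng.uniform(20, 76), rng.uniform(20, 76)) for _ in range(6)]
yy, xx = np.mgrid[0:96, 0:96].astype(float)
for (x, y) in landmarks:
    scene += 30.0 * np.exp(-((xx - x) ** 2 + (yy - y) ** 2) / (2 * 1.2**2))

n = 20
t = np.arange(n)
shifts = list(zip(2.0 * np.sin(2 * np.pi * t / 16),
                  1.0 * np.sin(2 * np.pi * t / 16 + 0.6)))
frames = np.stack([ndimage.shift(scene, (dy, dx), order=1, mode="nearest")
                   for (dx, dy) in shifts])
stack = FrameStack(frames=frames, frame_rate=440.0)

config = MotionConfig(block_size=32, block_stride=16, search_range=4)
fields = estimate_displacement_field(stack, config, mode="dp")
err = [np.hypot(f.dx_grid.mean() - (dx - shifts[n // 2][0]),
                f.dy_grid.mean() - (dy - shifts[n // 2][1]))
       for f, (dx, dy) in zip(fields, shifts)]
print(f"field error vs applied motion: mean {np.mean(err):.3f} px")

report = dp_search_vs_exhaustive(stack, config)
print(f"DP-guided vs exhaustive search: "
      f"{100 * report['agreement_fraction']:.1f}% of "
      f"{report['n_informative_blocks']} blocks agree")

dets = []
for k in range(n):
    dets.extend(localize_frame(stack.frames[k],
                               LocalizationConfig(min_peak_intensity=10.0),
                               frame_index=k))
aligned = compensate_detections(dets, fields)
ref_dx, ref_dy = shifts[n // 2]
residuals = [min(np.hypot(d.x - (x + ref_dx), d.y - (y + ref_dy))
                 for (x, y) in landmarks) for d in aligned]
print(f"landmark residual after compensation: "
      f"{np.sqrt(np.mean(np.square(residuals))):.3f} px RMS "
      f"(motion amplitude was 2 px)")
# Sub-0.1 px residuals mean trajectories assembled from compensated
# detections are no longer smeared by respiration-scale tissue motion.
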