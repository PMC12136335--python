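"""SVD clutter filtering and subpixel bubble localization.

Generates a clutter-heavy phantom, removes the tissue signal by zeroing
the leading singular components of the Casorati matrix, sets the noise
floor from a bubble-free control run, and localizes bubbles to subpixel
precision with the three-sample cosine fit. Prints the localization error
against the generator's ground truth.
"""

import numpy as np

from vckulm import (LocalizationConfig, PhantomConfig, SVDConfig, VesselSpec,
                    estimate_noise_threshold, generate_phantom, localize_stack,
                    svd_filter)

vessel = VesselSpec(centerline=[(48.0, 2.0), (48.0, 94.0)], radius=1.5,
                    flow_speed=1.0)
base = dict(grid_shape=(96, 96), n_frames=100, frame_rate=440.0,
            psf_sigma=1.2, clutter_amplitude=8.0, clutter_rank=2,
            noise_sigma=0.3)

# control acquisition without bubbles fixes the noise floor
control, _ = generate_phantom(PhantomConfig(vessels=[], bubble_rate=0.0,
                                            seed=2, **base))
svd = SVDConfig(n_tissue_components=2)
floor = estimate_noise_threshold(control, svd, percentile=0.99)
print(f"noise floor (99th pct of bubble-free residual): {floor:.3f}")

stack, truth = generate_phantom(PhantomConfig(vessels=[vessel],
                                              bubble_rate=0.05, seed=3, **base))
filtered = svd_filter(stack, SVDConfig(n_tissue_components=2,
                                       noise_threshold=floor))
# peak threshold well above the noise floor: the floor keeps residual
# noise out of the image, the peak threshold keeps noise bumps riding on
# bubble tails from being reported as bubbles
detections = localize_stack(filtered,
                            LocalizationConfig(min_peak_intensity=4 * floor))

by_frame = {}
for tr in truth.true_tracks:
    for (f, x, y, _) in tr.points:
        by_frame.setdefault(f, []).append((x, y))
errors = []
for d in detections:
    cands = by_frame.get(d.frame, [])
    if cands:
        e = min(np.hypot(d.x - x, d.y - y) for (x, y) in cands)
        if e < 1.0:
            errors.append(e)
print(f"detections: {len(detections)}, "
      f"matched to an isolated bubble within 1 px: {len(errors)}")
print(f"localization error: mean {np.mean(errors):.3f} px, "
      f"p95 {np.quantile(errors, 0.95):.3f} px")
# Subpixel errors well below 0.2 px are what make super-resolution maps
# sharper than the diffraction-limited PSF (sigma 1.2 px here). The
# remaining detections are mostly merged responses of bubble pairs
# travelling closer than the PSF width — overlapping bubbles are not
# demixed, only localized as one peak between them.
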