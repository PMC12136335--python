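# vckulm — velocity-constrained Kalman tracking for ultrasound localization microscopy

Ultrasound localization microscopy (ULM) reconstructs microvascular maps far
below the diffraction limit by localizing intravascular microbubbles in
thousands of ultrafast B-mode frames, linking them into trajectories, and
accumulating the trajectories into super-resolved density and velocity
images. The hard parts are everything between the raw movie and the map:
tissue clutter dwarfs the bubble echoes, bubbles cross and disappear,
respiration shifts the whole scene by several pixels, and a lower frame rate
stretches the inter-frame displacements until naive nearest-neighbour
matching falls apart.

`vckulm` is a tested Python implementation of a velocity-constrained Kalman
(vc-Kalman) ULM pipeline for researchers working on ULM algorithms and
their validation:

1. **SVD clutter filtering** — zero the leading singular components of the
   Casorati matrix (pixels × frames) per temporal chunk, then apply a noise
   floor estimated from a bubble-free control acquisition.
2. **Cosine-fit subpixel localization** — refine each intensity peak from
   its two axial neighbours with the exact inverse of
   `I(u) = A·cos(α(u − ξ))`:
   `α = arccos((I(−1)+I(1))/(2I(0)))`,
   `β = arctan((I(−1)−I(1))/(2I(0)·sin α))`, `ξ = −β/α`.
3. **Multidimensional Kalman tracking** — state `S = [x, y, I, dx, dy]`
   (position, brightness, velocity), constant-velocity prediction, gated
   minimum-cost linear assignment whose cost blends normalized distance with
   brightness mismatch, statistical-velocity seeding for young tracks, and
   coasting across single-frame dropouts.
4. **Velocity-difference (VD) rejection** — a trajectory with step vectors
   `vᵢ` is kept only if `VD = Σ|vᵢ| / |Σ vᵢ| ≤ 2`, i.e. the summed step
   lengths may not deviate from the net displacement by more than 100%.
5. **Motion compensation** — per-frame block displacement fields against the
   middle reference frame by normalized cross-correlation
   `R_nc = Σ S_r S_d / √(Σ S_r² · Σ S_d²)`, with prefix-sum (integral-image)
   energy terms, a continuity-seeded 3×3 hill-climb instead of an exhaustive
   sweep, and 3-point parabolic subpixel refinement
   `ξ = (R(−1) − R(1)) / (2(R(−1) − 2R(0) + R(1)))`.
6. **Rendering and metrics** — super-resolved density and signed-velocity
   maps, contrast-to-noise ratio `CNR = (E_V − E_N)/σ_N`, and per-pixel
   velocity `nRMSE = √(Σ|Vᵢ − V̄|²/N)/|V̄|`.

A synthetic flow-phantom generator (`vckulm.phantom`) produces movies with
exact ground truth — bubble tracks, clutter/bubble/noise layers, applied
motion — so every stage has an oracle.

## Worked example

`examples/03_track_and_reject.py` builds a dense 500-frame phantom
(8 vessels, flows 1.5–3.6 px/frame, clutter and noise), runs SVD filtering,
localization, both trackers and the VD filter, and scores against ground
truth:

```
8536 detections over 500 frames (197 true bubbles)
vc-Kalman: 183 tracks, VD rejected 0 (worst VD = 1.01)
vc-Kalman + VD       precision 0.969 recall 0.870 F1 0.917
nearest-neighbour    precision 0.963 recall 0.827 F1 0.890
```

The F1 scores are link-level identity scores: a link (two consecutive
points of an estimated track) counts as correct when both points belong to
the same true bubble. Prediction plus the brightness term recovers links
the nearest-neighbour baseline misses.

`examples/05_compare_methods.py` runs the three method variants on a
motion-corrupted, tissue-dominant phantom:

```
      method     cnr  nrmse  n_tracks  mean_trace_length  mean_flow_speed
 baseline_nn   1.612  0.787       335             35.388          979.165
   vc_kalman   1.702  0.165       244             50.373         1027.376
vc_kalman_mc 154.370  0.049       245             50.069         1019.157
```

CNR rises and velocity nRMSE falls from the baseline through vc-Kalman to
vc-Kalman with motion compensation: prediction and the VD constraint remove
bad links, and compensation removes the motion smear (here 1.5/3 px
sinusoidal motion) together with its velocity bias. Speeds are in px/s
(flow 1.5–3.1 px/frame at 440 Hz).

The other examples cover phantom generation (`01`), clutter filtering and
subpixel localization accuracy (`02`), and displacement-field estimation
with static landmarks (`04`). A thin CLI exposes the same pipeline from the
shell:

```bash
vckulm simulate --config phantom.yaml --out data/
vckulm run --config pipeline.yaml --input data/stack.tif --out results/
vckulm compare --config pipeline.yaml --input data/stack.tif --out table.csv
vckulm framerate-sweep --config pipeline.yaml --input data/stack.tif --out sweep.csv
```

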