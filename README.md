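# hierbg

Hierarchical block/pixel background modeling for moving-object detection in
underwater video.

Underwater footage is hard on classic background subtraction: artificial
lighting drifts across the sequence, the water itself makes parts of the
background oscillate (ripple, drifting particles), and absorption leaves
objects at low contrast against the scene. `hierbg` implements a two-stage
("hierarchical") background model that addresses those failure modes, along
with the classic per-pixel Gaussian baseline, the standard
completeness/false-alarm evaluation criteria, and a seeded synthetic-scene
generator with exact ground truth for end-to-end testing.

## The model

**Coarse stage (subblocks).** Each frame is tiled into nonoverlapping
M × N subblocks (default 8 × 8). A subblock is summarized by a
block-truncation-coding (BTC) intensity feature: threshold the block at its
mean μ, threshold each side again at its side mean (μ_h, μ_l), and collect
the four conditional means

```
v = (μ_ht, μ_hb, μ_lt, μ_lb),      μ_lb ≤ μ_lt ≤ μ ≤ μ_hb ≤ μ_ht.
```

Every subblock keeps K weighted feature vectors {(v_k, ω_k)}, Σω_k = 1,
maintained with mixture-style selective updates: on a match the weights
move by ω ← (1 − α_ω)ω + α_ω·M_k and the matched feature tracks the input
at rate α_b; on no match the weakest vector is replaced at weight α_ω. The
highest-weight vectors whose cumulative weight first exceeds T represent
the background (their count is B_i); matching one of them labels the block
background, anything else labels it object. Matching uses Euclidean
distance in feature space against an adaptive threshold

```
T_D = T_D_base · (α + S),
```

where S ∈ [0, 1] is the cosine similarity between the block's
mean-absolute-deviation profile and that of a running background exemplar
patch — S is invariant to adding a constant to either block, so a globally
brighter version of the remembered background still matches.

**Fine stage (pixels).** Only inside the rough object region, each pixel is
described by a moderated local binary pattern: the signs of
`g_p − g_c + β` over P neighbors sampled on a circle of radius R (default
P = 16, R = 2, β = 3; bilinear interpolation off-grid). The offset β makes
near-flat underwater regions stable, and the code is exactly invariant to
additive illumination change. Each pixel keeps a FIFO of its last K
background patterns; a pixel whose current pattern is within the distance
threshold of any remembered pattern is background (and refreshes the FIFO),
anything else is object. The refined mask is therefore always a subset of
the rough mask.

**Evaluation.** Detection quality is scored per frame by

```
C_good  = |Ω_in ∩ Ω_o| / |Ω_o|        (completeness)
C_false = |Ω_in ∩ Ω_b| / |Ω_b|        (false-alarm ratio)
```

with Ω_in the detected region, Ω_o the true object and Ω_b the true
background. The reference detector is the classic single-Gaussian-per-pixel
running background model (λ·σ test, selective exponential update).

## Worked example

```python
import hierbg

scene = hierbg.generate_scene(hierbg.standard_suite()["close_degraded"])
results = hierbg.detect_sequence(scene.frames)
report = hierbg.evaluate([r.refined_mask for r in results[10:]], scene.truth[10:])
baseline = hierbg.gaussian_baseline_detect(scene.frames)
base_report = hierbg.evaluate(baseline[10:], scene.truth[10:])
print(f"hierarchical: C_good = {report.mean_c_good:.4f}, C_false = {report.mean_c_false:.4f}")
print(f"gaussian:     C_good = {base_report.mean_c_good:.4f}, C_false = {base_report.mean_c_false:.4f}")
```

prints

```
hierarchical: C_good = 0.9299, C_false = 0.0385
gaussian:     C_good = 0.8836, C_false = 0.2253
```

The scene is a 96 × 96, 60-frame sequence with a low-contrast textured
disk (diameter ≈ a quarter of the frame) moving over a textured seabed,
degraded by a global illumination ramp, a rippling background region and
sensor noise; frames 1–10 are treated as burn-in. The hierarchical
detector covers 93 % of the true object while flagging under 4 % of the
background; the Gaussian baseline both misses more of the object (the
parts whose intensity matches the background) and false-alarms heavily on
the ripple region.

The same workflow is available from the shell:

```sh
hierbg synth --scene close_degraded --out scene/
hierbg detect --input scene/frames --output detected/
hierbg baseline --input scene/frames --output base/
hierbg evaluate --detected detected/ --truth scene/truth --report report.json
```

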