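# Methods

This note documents the detector's model and update rules, the defaults
and how they were chosen, what the synthetic scenes emulate (and what they
do not), and the numerical conventions that matter for reproducibility.

## Detection model

### Coarse stage: weighted BTC feature models per subblock

Frames are grayscale intensity arrays on the 8-bit scale, held as floats;
color input is reduced by BT.601 luma (0.299 R + 0.587 G + 0.114 B). Each
frame is tiled into nonoverlapping M × N subblocks after edge-replicated
padding to the next multiple of the block size (edge replication avoids
fake high-contrast block features at the borders; the padding is recorded
and masks are cropped back to frame size).

The BTC feature of a block partitions its pixels twice: pixels ≥ the block
mean μ form the high side (side mean μ_h), the rest the low side (μ_l);
each side splits again at its own mean, and the feature is the 4-vector of
conditional means v = (μ_ht, μ_hb, μ_lt, μ_lb). Ties go upward (≥ at every
threshold). Degenerate cases collapse explicitly: an all-equal block gives
four copies of μ; a side whose pixels are all equal gives two copies of
the side mean. With these rules no partition can be empty, so no epsilon
fudging is needed anywhere.

Each subblock keeps K entries (v_k, ω_k) with Σω_k = 1, sorted by weight
(descending; ties broken by most recent match). B_i is the smallest b ≥ 1
whose cumulative weight strictly exceeds T; the first B_i entries
represent background. Per frame:

1. Compute the block's feature v and its similarity S to the exemplar
   patch (below); the effective match threshold is T_D = T_D_base·(α + S),
   recomputed fresh every frame — it is a per-evaluation scaling, never a
   self-compounding recurrence.
2. Entries within distance T_D are candidates; the closest one matches
   (ties prefer the heavier entry). Matching an entry ranked ≤ B_i labels
   the block background, a deeper match labels it object.
3. On a match, all weights get ω ← (1 − α_ω)ω + α_ω·M_k (M_k = 1 for the
   matched entry) and are renormalized. The matched feature and the
   exemplar track the input at rate α_b *only when the label is
   background* — the coarse stage trusts its background decisions and
   deliberately does not learn object appearance into background state.
4. On no match the minimum-weight entry is replaced by (v, α_ω) and
   weights renormalize; the label is object.

The K − 1 initialization slots start as zero-weight placeholders and are
explicitly excluded from matching: a uniformly dark block would otherwise
"match" the zero vector. Placeholders are only targets for replacement.

The exemplar patch is a running average (rate α_b) of the block's
appearance over background-labeled frames, initialized from frame 1. It
exists because the model stores only 4-vectors, while S is defined over
pixel deviation profiles: S = |U_A·U_B| / (‖U_A‖‖U_B‖) with
U_X = |x_i − μ_X| in raster order. S is invariant to adding a constant to
either block, so illumination drift does not depress it; two constant
blocks define S = 1, a constant against a varied block S = 0.

### Fine stage: moderated LBP texture models per pixel

Within the rough object region only, each pixel's texture is the P-bit
pattern of signs s(g_p − g_c + β), neighbors sampled counterclockwise from
east on a circle of radius R (bit p has weight 2^p). Off-grid positions
are bilinearly interpolated; outside-frame positions read an
edge-replicated extension; the canonical P = 8, R = 1 configuration uses
the classical 3 × 3 integer neighborhood. The moderation offset β (default
3, in intensity units) makes ties and tiny deficits count as "not darker",
which stabilizes codes in near-flat regions; with β = 0, P = 8, R = 1 the
operator reduces to the classical LBP. Because the code depends only on
intensity differences, it is exactly invariant to additive illumination
change.

Every pixel keeps a FIFO of its last K background patterns (newest first).
A pixel is background iff some stored pattern is within Euclidean bit
distance T_D of the current one (the distance is √Hamming; the default
T_D = 1.2 accepts at most one differing bit); background pixels push the
current pattern into the FIFO, object pixels never touch their model. All
pixel histories are initialized from the first frame's patterns, so an
arriving object is compared against remembered *background* texture rather
than against itself; a pixel that somehow acquires its model only in the
current frame (possible through the scalar API) carries no temporal
evidence and classifies as object. Pixel models persist when their block
returns to background, so re-entry is warm; memory is bounded by
frame size × K.

The pipeline runs all block decisions before any pixel processing, paints
object blocks into the rough mask at block resolution, refines only inside
it, and crops padding. Frame 1 initializes all state and emits an
all-background result, so output length equals input length. The detector
contains no randomness: identical input and configuration give
bit-identical masks. No morphological post-processing is applied by
default; a binary-opening cleanup flag exists for practical use but is off
everywhere in the tests.

### Gaussian baseline and evaluation

The reference detector keeps one Gaussian per pixel: foreground iff
|x − m| > λ·σ, with mean and variance updated by exponential moving
averages (rate 0.05) on background-classified pixels only and σ floored at
2 intensity levels (λ = 2.5). Detection quality uses
C_good = |Ω_in ∩ Ω_o|/|Ω_o| and C_false = |Ω_in ∩ Ω_b|/|Ω_b| per frame;
sequence scores are arithmetic means, with frames whose true object region
is empty excluded from the C_good mean (C_good is undefined there) but
kept in the C_false mean.

## Parameter defaults and calibration

| parameter | default | units | notes |
|---|---|---|---|
| M × N | 8 × 8 | px | localizes objects; standard BTC block size |
| K (block) | 3 | — | appearance diversity per block; memory-light |
| T | 0.7 | — | conventional background-portion threshold |
| α | 0.75 | — | midpoint of the sensible 0.7–0.8 band |
| T_D_base | 20 | intensity | calibrated, see below |
| α_b | 0.05 | — | feature/exemplar tracking rate |
| α_ω | 0.02 | — | weight rate; sets the absorption horizon |
| P, R | 16, 2 | —, px | texture neighborhood, see below |
| β | 3 | intensity | moderation offset |
| K (pixel) | 3 | — | texture history depth |
| T_D (pixel) | 1.2 | bits^1/2 | background iff ≤ 1 differing bit |

T_D_base was calibrated on the synthetic fixtures by measuring the
distance-to-model distribution of pure-background blocks on the degraded
static scene (worst case ≈ 31 at S ≈ 0.9, i.e. comfortably below the
effective threshold 20·(0.75 + 0.9) = 33) against object-covered blocks of
the degraded moving-object scenes (typically ≥ 25 at half coverage, with S
also lower and the threshold correspondingly tighter). Larger bases
(40–70 effective) silently accept half-covered low-contrast object blocks
as background.

α_ω controls how fast a persistent new appearance is absorbed into the
background: the incumbent weight decays as (1 − α_ω)^n while another
appearance occupies the block, so absorption occurs after roughly
ln(T)/ln(1 − α_ω) occupied frames. At 0.05 that is ~7 frames — shorter
than the time a slow object needs to cross one block, which turns object
interiors into background mid-transit. The default 0.02 puts the horizon
at ~18 frames, longer than per-block dwell for objects moving around
1 px/frame, while genuine scene changes still absorb in under a second of
video. The closed-form absorption frame is property-tested.

P = 16, R = 2 for the texture stage: with 8-bit codes, the patterns of two
unrelated smooth textures collide within small Hamming distance far too
often for per-pixel matching (both concentrate on "contiguous arc"
patterns), which carves holes into detected objects. Sixteen samples at
radius 2 double the code length and widen the sampled annulus, and the
measured object/background collision rate drops enough to matter; the
classical P = 8, R = 1 configuration remains available and tested. The
pixel threshold accepts ≤ 1 differing bit of 16; allowing 2+ bits measurably
erodes completeness (object patterns start matching remembered background)
while stricter exact matching inflates false alarms under sensor noise.

## Synthetic scenes

The generator renders: a static background plate (unit-variance smoothed
noise, default sd 12 around mean 100, smoothing radius 3 px); an optional
global illumination ramp (additive, default 0 → +12 over 60 frames — about
0.2 intensity/frame, chosen so that a correctly tracking EMA background
model can follow it); an optional "unstable background" region — a
traveling sinusoidal intensity wave (amplitude 8, period 8 frames,
wavelength 96 px) confined to a rectangle, emulating water ripple; moving
textured objects composited over the plate with exact truth masks; and
per-frame Gaussian sensor noise (sd 2 in the degraded variants). All
randomness flows through one seeded generator; scenes are bit-reproducible.

Objects are deliberately *low-contrast in mean but strong in fine texture*
(default offset +20 over a ±50 fine-scale texture, smoothing radius 1 px):
that is the regime underwater imaging produces, and it is what separates
the two detectors — an intensity-only per-pixel model misses the object
parts whose brightness matches the background, while block statistics and
texture still carry signal. Object texture translates rigidly with the
object (integer-rounded shifts). The standard suite fixes four families
(static; one close disk of diameter ~¼ frame; one distant disk of diameter
5 px; two objects) in clean and degraded variants at fixed seeds, 96 × 96
× 60 frames — large enough for a 12 × 12 block grid and burn-in, small
enough for seconds-scale tests.

What the scenes do **not** emulate: scattering/attenuation light
transport, caustics, shape deformation (fish undulation), occlusions,
compression artifacts, or camera motion. Passing on these scenes shows the
model does what it is designed to do under drift, ripple, noise and low
contrast; it does not certify performance on arbitrary real footage.

## Numerical conventions and degenerate inputs

- Intensities are float64 on [0, 255] throughout; quantization only on
  file output (masks as 0/255 PNG).
- Tie-breaks: pixels equal to a BTC threshold go to the upper set; equal
  match distances prefer the heavier entry; equal weights sort by most
  recent match; equal minimum weights replace the stalest entry.
- S is clipped to 1 against floating-point overshoot; both-constant blocks
  give S = 1, one constant block gives S = 0.
- Weight renormalization keeps Σω = 1 to ~1e-16 per step; the conservation
  property is asserted at 1e-9 over 60-frame runs.
- C_good raises on an empty true object region rather than returning a
  sentinel; the sequence evaluator records NaN for that frame and excludes
  it from the C_good mean.
- The absorption test pins α_ω = 0.05, T = 0.7 explicitly, independent of
  the defaults.

## Known limitations

- Block-stage labels are block-resolution; a thin object smaller than the
  texture-stage threshold inside an unflagged block is invisible.
- The fine stage never updates object-classified pixels, so a pixel whose
  background truly changed while inside a flagged block re-learns it only
  after its block returns to background and is flagged again later.
- The texture model is per-pixel pattern matching, not a histogram model:
  it is sensitive to pattern-collision statistics, which is why the code
  length matters (see calibration).
- Multiplicative illumination change is only approximately tolerated (the
  LBP invariance is exact for additive shifts only).
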