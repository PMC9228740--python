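# Methods

This note records the models, the tunable parameters and the design
decisions behind `bloomspec`, including the points where the procedure was
genuinely open and a choice had to be made.

## Radiometry and data model

Scenes are five co-registered bands — blue (B1), green (B2), red (B3),
red edge (B4), near-infrared (B5) — held as reflectance fractions in [0, 1].
Sensor exports vary: already-calibrated reflectance is passed through, raw
digital numbers are divided by an explicit `dn_scale` (e.g. 65535), and
integer data without a scale are min–max normalized; all paths are monotone
and clipped to [0, 1], which keeps every normalized-difference index inside
its [−1, 1] contract. Pixel coordinates are 0-based, row-major, origin
top-left. Channel order of multiband files is overridable (`band_order`)
because export order differs between tools.

## Preprocessing

**Adaptive median filter** (two-stage, textbook form): per pixel the window
grows from 3×3 until the window median is strictly between the window
extremes or the maximum window (default 7×7) is reached; the centre pixel is
kept iff it is itself strictly between the extremes, else replaced by the
median. Filtering is applied to every band independently — the index is a
band ratio, so a single repaired band would still leave a corrupted ratio.
Borders use edge-inclusive reflection. The filter is idempotent away from
borders on impulse-corrupted smooth images; at borders the padding
duplicates edge values, so ties with window extremes can recur — the
property tests therefore check idempotence on the interior.

**Light mask**: a pixel is masked when its mean visible-band (B1–B3)
reflectance exceeds an absolute threshold if configured, otherwise the
0.995 quantile of that mean. The default quantile targets small glint spots
without eating legitimately bright classes. Masked pixels are *not*
inpainted; they are folded into the validity mask and become the ignore
class in training losses, metrics and grading denominators.

## The signed-root index

The working feature is sgn(x)·√|x| applied to the blue/NIR normalized
difference x = (ρ_B5 − ρ_B1)/(ρ_B5 + ρ_B1). The square-root stretch is the
whole point: it is odd and monotone (so no ordering or sign information is
lost) and |out| ≥ |in| on [−1, 1], which widens small class gaps near zero —
exactly where early-stage blooms sit. Zero-denominator pixels get a sentinel
and are excluded from statistics and flagged ignore downstream.

Band-pair selection scores each of the 10 unordered pairs by the *minimum*
over class pairs of |mean gap| / pooled standard deviation of the pair's
index. Taking the worst case rather than an average means the winning pair
is the one under which no two classes collapse; ties prefer pairs containing
B5, then the lower band number. With two perfectly constant classes the
pooled deviation is zero and a nonzero gap scores infinity, which is the
correct limiting behaviour for noise-free fixtures.

## Segmentation model

The stem ("feature-enhancement module") is structural: a 7×7 stride-4
padding-3 convolution — with stride 4 and padding 3, the 7×7 kernel is the
unique small odd kernel mapping a 768-pixel side to exactly 192 — followed
by one 4×4 and two 3×3 stride-1 same-padded convolutions, closed by a
residual unit (main path 3×3 → ReLU → 1×1, identity side path, combined by
pixel summation). Channel widths default to 32 → 64. The five convolutions
partition as stem + three mid layers + the residual unit's 3×3, with the
1×1 projection supplying the deepest features; a learned projection on the
side path is added only if channel widths mismatch (they do not with the
defaults).

The encoder is a deliberately small pre-norm transformer: patch side 4 on
the quarter-resolution features, embedding width 64, 4 heads, 2 layers,
ReLU MLP of ratio 2. The decoder is a linear per-token head producing a
4×4 patch of class scores at stem resolution, bilinearly upsampled (×4,
align-corners) to input resolution. A 1×1 full-resolution convolution of
the input is summed onto the upsampled scores ("detail fusion"): the
stride-4 stem discards sub-patch boundary detail, and transferring shallow
features forward is the cheapest way to restore per-pixel boundary
decisions without growing the encoder.

All layers — im2col convolution, layer norm, multi-head attention, bilinear
resize — are NumPy with hand-derived backward passes, each verified against
central finite differences in the test suite. Training is Adam (lr 1e-3,
batch 8) on softmax cross-entropy with ignore-class exclusion; 60 epochs by
default. Thirty epochs already classify class interiors correctly but leave
boundary pixels — the last thing the loss sharpens — noticeably under-fit,
so the default schedule is doubled; at desk scale this costs ~80 s on one
CPU core. Every random draw (init, shuffling) flows from one integer seed;
identical seeds give bit-identical loss histories and weights.

Training pairs index images with label rasters at the model's input size;
scene diversity comes from the generator itself rather than crop/scale
augmentation (the augmentation path in `to_model_input` exists for larger
rasters, and is deterministic given a seed). Prediction runs the full
chain — preprocess → index → resize to model input → forward → optional
region correction → argmax — and returns labels at scene resolution with
light-masked pixels restored as ignore. Whether region correction runs at
inference is a caller choice; both modes are exposed.

## Region correction

Class activation maps are projections M_c = W_c·f clipped at zero and
max-normalized per class *at construction*. The affinity graph connects all
pixel pairs within Euclidean radius r (default 5 px); weights are either
binary same-class indicators from a label raster (pairs touching ignore are
dropped) or feature similarities exp(−β·‖f₁−f₂‖) with β ≥ 1 (default 2)
penalizing weak similarity. Refinement iterates M ← T M (default t = 8)
with T the row-normalized, self-loop-augmented affinity matrix. T is
row-stochastic by construction (asserted), so each step is a convex
neighbourhood average: activations stay in [0, 1], within-class noise is
smoothed, and on a connected component the t → ∞ limit is the
stationary-weighted (degree-proportional) mean — spatially uniform, as the
3-pixel-chain closed form in the tests shows (limit 2/7 for a one-hot map
on a uniform chain with self-loops).

Two deliberate choices here. First, the output is *not* re-max-normalized
per class after diffusion: a class absent from the scene has a pure-noise
map that diffuses to a small constant, and dividing it by its own maximum
would inflate it into winning argmaxes (observed to cut bloom IoU from 0.70
to 0.13 at t = 8 on blob fixtures). Second, total class mass is conserved
only on degree-regular graphs, where the row-stochastic operator happens to
be doubly stochastic; on irregular graphs neighbourhood averaging trades
mass conservation for the uniform-limit behaviour, and the property test is
stated on regular graphs accordingly. At inference the refinement stack is
built from softmax probabilities (already a [0, 1] activation) rather than
max-normalized logits, for the same reason. Label synthesis takes the
argmax over the scored classes and sends pixels whose best activation falls
below a background threshold (default 0.2) to ignore.

## Metrics and grading

Binary confusion counts (positive class vs. rest, ignore excluded from
either raster) feed PA = (TP+TN)/total and IoU = TP/(TP+FP+FN); a K-class
pixel accuracy (exact label match over evaluated pixels) is provided
besides, since whole-scene scoring is the common reporting convention. The
pollution proportion is P = A₁/A × 100 with A all evaluated (non-ignore)
pixels by default; a `water_only` mode restricts A to water + bloom pixels
for surveys where bank area should not dilute the proportion — which
definition applies is a survey-design question, so both are exposed. The
severity scale is implemented exactly as printed: I iff P = 0, II iff
0 < P < 10, III iff 10 ≤ P < 30, IV iff 30 ≤ P < 60, V iff 60 ≤ P ≤ 100 —
a total function on [0, 100] (property-tested including every boundary).
The misjudgment of an estimated proportion is reported as the absolute
difference in percentage points.

## Synthetic scenes: what they emulate, and what they don't

The generator emulates the *structure* of low-altitude river imagery:
wavy vegetated banks (12 % of width per side), irregular flocculent bloom
blobs (top-k water pixels of a smoothed Gaussian random field, so the
configured bloom fraction of total pixels is hit exactly up to rounding,
and shapes are blobby, never geometric), optional boat rectangles, glint
disks that override all bands to near saturation, elliptical shadows that
dim all bands multiplicatively (ratio indices are invariant to that, which
is precisely why index-based detection survives shadow), 2 %
salt-and-pepper impulses and σ = 0.01 Gaussian noise. Class band priors are
chosen to reproduce the qualitative reflectance ordering of real scenes —
blooms NIR-bright/blue-dark, water the reverse, bank vegetation tracking
blooms closely in the red edge but not in blue/NIR (which is why the
(B1, B5) pair wins selection), boats bright across the visible — at
defaults that keep the blue/NIR index gap between bloom and water above
four pooled standard deviations. The weak-signal `low_contrast` preset
compresses bloom reflectance toward water and makes the red band nearly
uninformative, so a red/NIR NDVI confuses bloom with bank while the
blue/NIR signed-root index still separates them.

Every scene is a pure function of its seed, via independent child streams
per component (layout, radiometry, shadows, glint, noise), so toggling one
component never perturbs the others' draws.

What the generator does *not* model: radiative transfer, sun–sensor
geometry, atmospheric effects, mixed pixels at bloom edges (class
boundaries are hard), spatially correlated within-class texture, or real
bloom morphology. Passing the synthetic end-to-end tests therefore shows
that the pipeline recovers blooms whose spectral separability and noise
match the configured priors — it does not certify accuracy on real rivers,
where radiometry, class overlap and annotation noise are harsher.

## Problem sizes and numerical choices

The test suite trains the desk-scale model (input 96×96, 32 scenes, 60
epochs) once per session and evaluates 8 held-out scenes; the weak-signal
comparison trains two 16-scene models for 20 epochs each. These sizes were
chosen so a full run finishes in a couple of minutes on one CPU core while
leaving clear margins over the recovery thresholds (pooled bloom IoU ≈ 0.87
against a 0.7 bar; pooled multi-class PA ≈ 0.93 against 0.9). Float64 is
used throughout the network for clean gradient checks. Degenerate inputs
fail loudly: empty rasters, all-ignore labels, single-class band-pair
selection, zero evaluated pixels and out-of-range proportions all raise
typed errors rather than returning silent defaults; an all-masked scene
returns an all-ignore raster with a logged warning.

## Known limitations

- The transformer's positional embedding fixes the token count, so one
  trained model serves one input size; other scene sizes are resized to it.
- The NumPy training loop is single-core and desk-scale by design; it is
  not a path to training on real survey datasets.
- Affinity graphs are dense within the radius; memory grows as
  O(H·W·r²), fine at desk scale but a constraint for full-survey mosaics.
- The grading boundaries are exact per the printed scale; proportions
  estimated near a boundary (e.g. P ≈ 30) can flip levels under small
  estimation error — an inherent property of hard thresholds, surfaced in
  the reported proportion-error statistic instead.
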