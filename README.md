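# bloomspec

Detection and severity grading of cyanobacterial blooms in five-band
multispectral imagery from low-altitude UAV surveys.

Cyanobacterial blooms are dense surface accumulations of cyanobacteria in
eutrophic rivers and lakes. Spectrally they behave like vegetation — bright
in the near-infrared, dark in the blue and red — but on real water surfaces
the signal is confounded by specular glint, shadows, floating litter and
boats, and early-stage blooms are weak. `bloomspec` implements a full
detection pipeline for this setting:

1. **Preprocessing** — per-band two-stage adaptive median filtering against
   impulse noise, and a brightness ("light") mask that removes specular glint
   pixels from all downstream analysis.
2. **Signed-root vegetation index.** The classic NDVI is the normalized
   difference of near-infrared and red reflectance,
   NDVI = (ρ_B5 − ρ_B3)/(ρ_B5 + ρ_B3). `bloomspec`'s primary feature is the
   signed-root index on the blue/NIR pair,

       NDVI_sqrt = sgn(x) · √|x|,   x = (ρ_B5 − ρ_B1)/(ρ_B5 + ρ_B1),

   which is odd, strictly monotone and satisfies |out| ≥ |in| on [−1, 1], so
   weak bloom signals near zero are stretched apart from water. A band-pair
   selection report ranks all C(5,2) = 10 normalized-difference pairs by a
   worst-case Fisher separability score across classes.
3. **Segmentation.** A feature-enhancement stem (7×7 stride-4 padding-3
   convolution, then 4×4 and two 3×3 convolutions and a residual unit whose
   3×3→ReLU→1×1 main path is pixel-summed with its identity side path — a
   768×768 input maps to a 192×192 feature grid) feeds a small multi-head
   attention transformer encoder; a linear token decoder plus bilinear
   upsampling (with a 1×1 full-resolution detail-fusion skip) produces
   per-pixel class scores. Forward, backward and Adam are implemented in
   NumPy; training is bit-reproducible from a single seed.
4. **Region correction.** Per-class activation maps M_c(x,y) = W_c·f(x,y) are
   diffused along a radius-limited pixel-affinity graph (binary same-class
   labels, or exp(−β‖f₁−f₂‖) feature similarities) by iterating a
   row-stochastic random-walk transition, recovering object morphology at
   class boundaries before labels are synthesized.
5. **Grading.** Pixel accuracy PA = (TP+TN)/total and IoU = TP/(TP+FP+FN)
   evaluate the segmentation; the pollution proportion P = A₁/A × 100 (bloom
   pixels over evaluated pixels) maps onto the five-level severity scale
   used in Chinese algal-bloom monitoring practice: I (P = 0),
   II (0 < P < 10), III (10 ≤ P < 30), IV (30 ≤ P < 60), V (60 ≤ P ≤ 100).

Because real bloom surveys are rarely redistributable, the package ships a
deterministic synthetic-scene generator (`bloomspec.synthscene`) producing
five-band river scenes with ground truth: wavy bank margins, irregular bloom
blobs, boats, glint disks, shadows and sensor noise, under presets mirroring
regular / reflection / shadow survey scenarios plus a weak-signal
(`low_contrast`) variant.

## Worked example

```bash
bloomspec simulate --preset regular --n 8 --seed 7 --out scenes
bloomspec simulate --preset regular --n 2 --seed 1007 --out test_scenes
bloomspec train --data scenes --seed 3 --out model.npz
bloomspec predict --model model.npz --scene test_scenes/scene_000.tif --out pred.png
bloomspec evaluate --pred pred.png --truth test_scenes/labels_000.png
```

prints (last command):

```json
{
  "IoU_bloom": 0.7233354880413704,
  "P": 27.996509979278002,
  "PA": 0.9066419456865525,
  "PA_multiclass": 0.8537463191187697,
  "bloom_pixels": 2567,
  "evaluated_pixels": 9169,
  "level": "III"
}
```

Read this as: of the 9 169 pixels not masked out as glint, 2 567 were
predicted as bloom (P ≈ 28.0 %, severity level III); against the ground
truth the bloom class reaches IoU 0.72 and binary pixel accuracy 0.91.
(The 8-scene training set here keeps the example fast; the test suite's
32-scene run reaches bloom IoU ≈ 0.87 and multi-class PA ≈ 0.93 on held-out
scenes.) Grading a proportion directly:

```bash
$ bloomspec grade --p 48.7
{"P": 48.7, "level": "IV"}
```

The same functionality is available as a library:

```python
import bloomspec as bs

scene, truth = bs.generate_scene(bs.SceneConfig(seed=7))
index = bs.ndvi_sqrt(bs.preprocess_scene(scene))
report = bs.pollution_report(truth)   # P and severity level from labels
```

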