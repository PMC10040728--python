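# fidgetkit

Privacy-preserving video analysis for infant movement research.

Clinical assessment of infant spontaneous movements (Prechtl's General
Movements Assessment, GMA) works from short video snippets in which the
infant's face is fully visible — a serious obstacle to sharing data
between labs. `fidgetkit` implements a pseudonymization-plus-analysis
stack for this setting:

- **Face blurring driven by pose keypoints.** Per frame, the blur-mask
  center is the mean of the head keypoints (eyes + nose + ears
  horizontally, eyes + nose vertically, leaving the mouth visible for
  behavioural assessment), gated on mean eye/nose reliability > 0.35
  with carry-forward, smoothed by an exponential moving average
  (a = 0.5), and applied as a 150×68 px elliptic region filled with a
  normalized 25×25 box blur plus ~5% uniform noise to hinder
  reconstruction.
- **Fidgety-movement (FM) classification from skeleton time series.**
  5-s snippets (250 frames at 50 fps, 25 keypoints) become 250×42
  (with head keypoints) or 250×32 (without) matrices of interpolated,
  min-max-normalized coordinates, classified FM+ / FM- by a shallow
  network: one temporal convolution (64 filters, length 7), one or two
  fully connected layers (200, 100), batch norm and 10% dropout,
  sigmoid output; trained with Adam, binary cross-entropy, batch 32,
  validation-stop early stopping and best-of-restarts selection;
  evaluated by stratified 5-fold cross-validation with t-based 95% CIs
  and two-sample t-tests between feature conditions. The scientific
  point is the ablation: whether removing head keypoints (which the
  blur degrades) significantly changes classification accuracy.
- **Rater-agreement analytics.** Percent agreement and Cohen's kappa
  κ = (p_o − p_e)/(1 − p_e) with Fleiss–Cohen–Everitt 95% CIs, after
  excluding snippets labeled "not assessable" by either rater; inter-
  and intra-rater workflows.
- **Synthetic data.** Real infant videos are not shareable, so a
  generator produces everything the pipeline needs: FM+/FM- keypoint
  trajectories whose class signal lives only in wrist/ankle channels,
  detection dropout and reliability scores, renderable frames with a
  face proxy, and rater label pairs at a controlled target kappa.

See `docs/methods.md` for the models, parameter defaults and design
choices in detail.

## Worked example

```python
import numpy as np
from fidgetkit import (
    BlurSpec, KeypointFeaturizer, NetworkSpec, TrainConfig,
    blur_video, compare_conditions, cross_validate,
    gen_dataset, render_frames,
)

# synthetic study: 200 FM+ and 200 FM- snippets
seqs, y = gen_dataset(200, 200, seed=7)

# blur a rendered snippet (pixels outside the ellipse stay untouched)
frames = render_frames(seqs[0])
small = seqs[0].copy()
small.data[:, :, :2] *= 0.25          # renderer canvas is 480x270
summary = blur_video(frames, small, BlurSpec(mask_w=37, mask_h=17, kernel=9),
                     seed=1)
print(summary["n_frames"], summary["n_carried_forward"])

# head-keypoint ablation (about 8 minutes on one CPU core)
cfg = TrainConfig(restarts=3, max_epochs=60, patience=8)
res = {}
for with_head in (True, False):
    X = KeypointFeaturizer(with_head=with_head).fit_transform(seqs)
    res[with_head] = cross_validate(X, y, NetworkSpec(), cfg, k=5, seed=7,
                                    with_head=with_head)
    print(f"with_head={with_head}: mean {res[with_head].mean:.2f}% "
          f"(95% CI +/-{res[with_head].ci95:.2f})")
cmp = compare_conditions(res[True], res[False])
print(f"t = {cmp['t']:.3f}, p = {cmp['p']:.3f}, "
      f"significant: {cmp['significant']}")
```

Output of this exact script:

```
250 0
with_head=True: mean 73.00% (95% CI +/-11.38)
with_head=False: mean 81.00% (95% CI +/-10.02)
t = -1.464, p = 0.181, significant: False
```

Line 1: all 250 frames were blurred and no frame needed its mask
center carried forward (the reliability gate passed everywhere). The
next lines are the head-keypoint ablation: both feature conditions
classify far above chance, and the two-sample t-test over the fold
accuracies finds no significant difference between them (p = 0.181) —
removing the head channels does not significantly change accuracy,
because the class signal sits in the limbs. That is the desk-scale
analogue of the negative result that justifies face blurring: the
blurred region's keypoints are dispensable for FM classification. (The
absolute accuracy level reflects the deliberately subtle synthetic
burst signal; see `docs/methods.md`.)

Agreement statistics from published-style joint counts:

```python
from fidgetkit import inter_rater
from fidgetkit.synthetic import tables_from_counts

a, b = tables_from_counts(956, 828, 13, 13)   # 1810 assessable pairs
r = inter_rater(a, b)
print(r.n_compared, round(r.percent_agreement, 1), round(r.kappa, 2))
# 1810 98.6 0.97
```

## Command line

```bash
fidgetkit simulate --n-pos 20 --n-neg 20 --seed 1 --out data/ --render
fidgetkit blur --video data/snippet_0000 --keypoints data/snippet_0000.csv \
               --out blurred/ --seed 1
fidgetkit features --keypoints data/snippet_0000.csv --no-head --out f.csv
fidgetkit train --data data/ --with-head --folds 5 --seed 1 --out cv.json
fidgetkit compare cv_with.json cv_without.json
fidgetkit agreement --a rater_a.csv --b rater_b.csv
fidgetkit demo --seed 1 --out demo/
```

Keypoint input is either a directory of one-JSON-per-frame files
(`people[i].pose_keypoints_2d`, 75 floats per person in the standard
25-point layout) or a flat CSV (`snippet_id, frame, x_1, y_1, r_1, ...,
r_25`). Video I/O uses numbered-PNG frame directories.

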