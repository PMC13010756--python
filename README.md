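# gazedecode

Data-driven comparison of gaze allocation across experimental conditions.

Eye-tracking studies traditionally compare conditions by counting fixations
inside hand-drawn regions of interest (ROIs). That approach is fragile: the
ROI margin is a subjective choice, and nudging it by a fraction of a degree
of visual angle can flip the significance of an effect. `gazedecode`
implements a decoding alternative for researchers analysing fixation data
on natural images:

1. **Per-stimulus condition decoding.** For each image, single fixations
   are rendered into Gaussian-smoothed density maps (σ = 1 dva) and a CNN
   is trained to classify the experimental condition from one map at a
   time. Training and validation maps are sampled from *different trials*
   (one held-out repetition per participant × condition), so the decoder
   must learn condition-diagnostic spatial structure rather than the
   idiosyncrasies of individual trials.
2. **Inference against an empirical chance level.** The decoder's
   validation accuracy `acc` is compared with the accuracy of an identical
   pipeline trained after shuffling condition labels at the trial level
   (the empirical chance level `acc₀`). A bootstrap over the validation
   predictions (1000 draws with replacement, 100 replicates) yields a
   confidence interval at the Bonferroni-corrected level
   `1 − α/m` (α = 0.05, m = 10 images → 99.5%, the 0.0025/0.9975
   quantiles); the condition is decodable iff the CI's lower bound exceeds
   `acc₀`.
3. **Classification images.** Averaging the decoder's input maps grouped
   by its *predicted* label and subtracting the two class means gives a
   signed map of where condition-diagnostic fixation density sits —
   reverse correlation for gaze.
4. **The classical baseline.** Elliptical ROIs with morphological margin
   variation (erosion/dilation by a 0.78 dva disc), per-participant
   fixation proportions, two-way repeated-measures ANOVAs with partial
   η² = SS_effect / (SS_effect + SS_error), and the noncentral-F
   sample-size computation for one-group within-subject designs.
5. **A synthetic gaze simulator.** Fixations drawn from a Gaussian-mixture
   saliency scene with a planted, tunable condition effect (a fraction
   `delta` of mixture weight moved from the central salient locus toward
   the off-centre "sound source"), so the whole pipeline is testable with
   known ground truth and no external recordings.

The CNN machinery (convolution, pooling, dense layers, SGD with momentum)
is implemented on numpy, sized for desk-scale problems: the `small`
architecture (two conv blocks + one hidden dense layer, 64×64 input)
trains in ~2 minutes on one CPU. The canonical 5-conv + 3-dense `alexnet`
family at 227×227 is available for study-scale runs.

## Worked example

Simulate a two-condition dataset with a strong planted effect and run the
full per-image analysis:

```python
import gazedecode as gd
from gazedecode.pipeline import RunConfig, run_pipeline

cfg = RunConfig.from_dict({
    "seed": 5,
    "render": {"output_size_px": [32, 32]},
    "architecture": {"family": "small", "input_size_px": [32, 32]},
    "sample": {"n_train": 600, "n_val": 200},
    "training": {"max_epochs": 2},
    "bootstrap": {"resample_size": 200, "n_replicates": 50},
    "simulation": {"effect": {"delta": 0.5},
                   "sim": {"n_participants": 4, "n_reps": 3, "seed": 21}},
})
rec = run_pipeline(cfg, "runs/demo")[0]
print(f"accuracy {rec['observed_accuracy']:.3f}  "
      f"chance {rec['empirical_chance']:.3f}  "
      f"CI [{rec['ci'][0]:.3f}, {rec['ci'][1]:.3f}]  "
      f"significant: {rec['significant_above_chance']}")
```

prints

```
accuracy 0.645  chance 0.385  CI [0.571, 0.729]  significant: True
```

The decoder classifies held-out single fixations at 64.5% and the
Bonferroni-corrected bootstrap CI excludes the label-shuffled chance
level, so the planted condition difference is detected. (At this tiny
demonstration scale — 4 participants, 3 repetitions — the single-run
chance estimate is itself noisy, here 38.5%; see `docs/methods.md` on the
variance of the chance level.) `runs/demo/img1_difference.png` shows the classification image:
red where the "sound" condition has more diagnostic fixation density (the
planted target locus), blue where it has less (the central locus).

The same pipeline is scriptable from a shell via the `gazedecode` CLI
(`simulate`, `render`, `split`, `train`, `chance`, `infer`, `classim`,
`roi`, `power`, `run`), each accepting `--config FILE --seed N --out DIR`.

For the ROI side:

```python
spec = gd.PowerSpec()          # eta² = 0.14, alpha = .05, power = .8, m = 4
gd.required_sample_size(spec)  # -> 6 participants
```

## Layout

- `src/gazedecode/geometry.py`, `data.py` — screen geometry, dva
  conversion, fixation tables and validation
- `src/gazedecode/render.py` — fixation-map rendering and heatmaps
- `src/gazedecode/sampling.py` — trial-held-out splits, map sampling,
  online augmentation
- `src/gazedecode/nn.py`, `decoder.py` — CNN layers and the per-image
  condition decoder
- `src/gazedecode/inference.py` — empirical chance, bootstrap CIs,
  significance decisions, classification images
- `src/gazedecode/roi.py` — ellipse ROIs, morphology, proportions,
  RM-ANOVA, power analysis
- `src/gazedecode/simulate.py` — the synthetic gaze generator
- `src/gazedecode/pipeline.py`, `cli.py` — orchestration and the CLI

See `docs/methods.md` for the modelling assumptions, parameter defaults,
and numerical choices.
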