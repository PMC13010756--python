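# Methods

## The decoding model

For each stimulus image the package asks: do single fixations carry
information about the experimental condition? The unit of analysis is a
*single-fixation density map*: the fixation is marked as a unit impulse at
its pixel in a zero matrix at native image resolution, convolved with an
isotropic Gaussian of σ = 1 degree of visual angle (dva), and resized to
the decoder's input size with bilinear interpolation. The 1 dva bandwidth
approximates foveal extent plus tracker calibration error (≤ 0.5 dva).
Because the pre-smoothed map is a sum of impulses, the implementation
stamps a truncated, renormalised Gaussian kernel at each fixation pixel —
numerically identical to filtering the full raster and much faster.
Kernels are truncated at 4σ per axis and renormalised to unit sum; the
truncation radius is a config field. Pre-resize maps are unit-sum
(density) normalised; decoder inputs are additionally peak-scaled to 1
after the resize so single- and multi-fixation maps share dynamic range.
Fixation duration does not weight the impulse by default (each fixation
counts once); a duration-weighted mode exists.

A CNN is trained per image to classify the condition from one map at a
time. Two families:

* `alexnet` — the canonical five-convolution + three-dense layout at
  227×227, final layer resized to the number of conditions, single-channel
  maps replicated across the three input channels. Study-scale.
* `small` — two convolution blocks (8 and 16 channels) plus one hidden
  dense layer (64 units) at 64×64 (configurable). This is an explicit
  desk-scale surrogate so the full pipeline runs on one CPU in minutes; it
  is not a model from the literature.

Optimisation: SGD with momentum 0.9, mini-batch 32, at most 8 epochs,
initial learning rate 6×10⁻⁴ dropped ×0.1 every 4 epochs, L2 weight decay
10⁻⁴, training data reshuffled each epoch, validation accuracy monitored
every 50 iterations. Loss is 2-class softmax cross-entropy (the canonical
choice; unstated in descriptions of this protocol). Weights use seeded
fan-in-scaled (He) initialisation. Everything is float32 numpy and exactly
reproducible given the seeds: there are no nondeterministic kernels, so
strict determinism is the only mode.

**Checkpoint rule.** Training returns the *final-iteration* network by
default (`checkpoint: "final"`); `"best"` (highest validation accuracy,
earliest on ties) is available. The default matters for inference:
selecting the best of ~40 noisy validation checkpoints inflates accuracy
under the null — we measured a +2–3 pp upward bias of the label-shuffle
chance level with `"best"` — whereas published chance levels obtained with
this protocol scatter symmetrically around 0.5, consistent with
final-network semantics (also the MATLAB `trainNetwork` default that
protocol descriptions of this kind implicitly use).

## Anti-leakage splitting and sampling

Fixations close in time are close in space, so maps sampled from the same
trial into both train and validation sides would leak. The split holds out
one repetition per (participant, condition) cell (configurable), chosen
uniformly; all of a trial's fixations stay on one side. Maps are then
generated by drawing fixations uniformly *with replacement* from the
side's pooled fixations, one condition pool per map, with labels
alternating so class counts are balanced to within one. Balance is
enforced deliberately: imbalanced sampling would bias the chance level,
and the shuffle-label chance estimate covers any residual bias either
way. Validation fixations are also drawn with replacement (mirroring
training; the alternative is not materially different at these pool
sizes). Default corpus sizes are 180,000 training and 60,000 validation
maps per image; desk-scale analyses use 8,000/2,000 or less.
Single-fixation renders are memoised per fixation pixel, so stream length
is decoupled from rendering cost.

Online augmentation (rotation ±20°, translation ±10 px, per-axis scale
0.8–1.2, horizontal flip p = 0.5) is applied in the fixed order
scale → rotate → translate → flip about the map centre, bilinear, with
vacated pixels zero-filled. The order and the zero-fill are
implementation choices (only the set of transforms is prescribed);
augmentation never changes a label and never produces negative values.

## Inference

*Empirical chance.* The pipeline is re-run after permuting condition
labels across the image's trials (trial level: each trial's fixations move
together; the label multiset and the split structure are preserved), and
the retrained decoder's validation accuracy is the chance level. Default
is a single shuffled run, matching the protocol this package implements;
`n_runs > 1` averaging is exposed because the single-run estimate is
noisy (see Limitations).

*Bootstrap.* The trained decoder's validation predictions are resampled
with replacement (1000 per replicate, 100 replicates) and accuracy
recorded per replicate. Quantiles are linear-interpolation order
statistics at the Bonferroni-corrected positions α/2m and 1 − α/2m
(α = 0.05, m = 10 → 0.0025/0.9975, a 99.5% CI). With 100 replicates these
positions are effectively the sample minimum and maximum; `n_replicates`
is configurable upward for smoother intervals.

*Decision.* Significant iff the CI's lower bound exceeds the empirical
chance level. CIs entirely below chance are flagged `below_chance` and
never reported significant.

*Classification images.* Validation input maps are averaged grouped by the
decoder's *predicted* label; the signed difference of class means (first
condition minus second) localises condition-diagnostic density. Averaging
by true label is available for contrast. Rendering uses a diverging
palette symmetric about zero.

## ROI baseline

ROIs are rotated ellipses rasterised by testing pixel centres against the
ellipse inequality. Margin variants erode or dilate the mask with a
discrete Euclidean disc of radius 0.78 dva (rounded to whole pixels; the
isotropic radius uses the mean of the per-axis px/dva). Eroding by
0.78 dva shrinks the full major-axis extent by ≈ 1.6 dva — the radius acts
at both ends; descriptions of this operation sometimes phrase the 1.6 as
"smaller at each peripheral point", which is geometrically consistent only
for the full-extent reading, the one implemented here. The "larger" ROI is
symmetric dilation by the same disc.

The dependent variable is the per-(participant, image, condition)
proportion of in-image fixations inside the ROI, pooled over repetitions;
cells with no in-image fixations are missing, not zero. The two-way
fully-within-subject ANOVA tests each effect against its effect-by-subject
interaction, reports uncorrected central-F p values (with a two-level
condition factor sphericity is moot for the effect of interest) and
partial η² = SS_effect/(SS_effect + SS_error). The implementation is a
direct sums-of-squares decomposition, cross-checked in the tests against
both an explicit design-matrix projection oracle (1e-8 relative) and
`pingouin.rm_anova`.

*Power.* For a one-group repeated-measures design with m measurements,
power is computed from the noncentral F distribution with
df₁ = (m−1)ε, df₂ = (n−1)(m−1)ε and noncentrality
λ = f²·n·m·ε/(1−ρ)^k, where f² = η²/(1−η²), ρ is the assumed correlation
among measures and ε the nonsphericity correction. The exponent k encodes
the effect-size convention: k = 1 for the classic G*Power-style f, and
k = 2 (default) when the entered η² is SPSS-style partial η², which
already absorbs the within-subject error reduction. The SPSS-style
default reproduces the sample size n = 6 for η² = 0.14, α = 0.05,
power 0.8, m = 4, ρ = 0.5; the classic convention gives n = 10 for the
same inputs (the well-known discrepancy between the two conventions).

## Synthetic gaze generator

Fixation locations are drawn from a 2D Gaussian-mixture saliency scene:
by default a central face-like component (weight 0.60, σ = 10% of the
image's short side), an off-centre "sound source" target (0.25, σ = 8%)
and a diffuse background (0.15, σ = 30%), on a 320×240 image at
~20 px/dva. The sound condition moves a fraction `delta` of the central
component's weight to the target and may displace the central mean —
emulating sound-induced disengagement from central salient regions.
Per trial: a truncated-Poisson (mean 9, ≥ 1) fixation count for a
2-second presentation, a per-participant Gaussian offset (σ = 5 px), the
first fixation seeded at a lateral border with probability 0.5 (the
pre-trial fixation cross sits left or right of the image), coordinates
clipped to the raster, log-normal durations (median 250 ms — schema
filler; nothing consumes them by default). Defaults are 7 participants ×
5 repetitions per condition — the scale of the free-viewing study this
emulates. Because the mixture is known, the blurred density difference
between conditions is available in closed form (blurring a Gaussian
mixture adds the kernel covariance to each component), which scores
classification-image recovery exactly.

What the generator does *not* emulate: scanpath dynamics (saccade
amplitudes, inhibition of return), image-driven saliency structure beyond
two loci, inter-participant strategy differences beyond a translation,
and temporal order effects beyond the first-fixation bias. Passing tests
therefore certify the pipeline's statistical machinery and its behaviour
under a known spatial effect — not performance on real images.

## Numerical choices and degenerate inputs

Pixel coordinates are 0-based, origin top-left, half-open bounds; the dva
conversion uses a symmetric tan(1°) convention (eccentricity-dependent
magnification across a desktop display is < 1% and ignored). Physical
screen size is a user input; a helper derives it from a diagonal assuming
square pixels. Fixations outside the raster are retained in the dataset,
flagged, and excluded from rendering and ROI counts. Resize is plain
bilinear without aspect-ratio preservation (matching the blanket
output-size prescription); nearest-neighbour is available. Prediction
ties go to the first class. Empty map inputs, single-class training
streams, empty condition pools, eroded-to-empty ROIs and unbalanced ANOVA
tables raise typed errors rather than degrading silently. Per-stage seeds
derive from blake2s(global seed, stage, image), so adding images never
perturbs existing images' randomness.

Desk-scale problem sizes used by the test suite and the acceptance
script: the chance-calibration run uses 8,000/2,000 maps at 64×64
(~2–3 min on one CPU); the null-calibration sweep uses 1,500/500 maps at
32×32 per seed. These sizes were chosen so a complete verification run
stays in the minutes range while keeping every statistical property
measurable.

## Known limitations

* **The chance level is noisy at study-scale data volumes.** With one
  held-out repetition per cell, a 7-participant two-condition design
  yields 14 validation trials (~126 unique fixations) per image. Maps
  resample that small pool, so validation accuracy — true-label and
  shuffled alike — carries ~4–5 pp of trial-level dependence noise
  regardless of how many maps are drawn. Published chance levels obtained
  with this protocol scatter over a comparable range (roughly 0.41–0.55).
* **Consequently the significance test is anticalibrated at that scale.**
  The bootstrap resamples maps as if independent, so the 99.5% CI
  half-width (~4 pp at 500–2,000 maps) is of the same order as the
  dependence noise it ignores; under a null simulation the pipeline
  declared significance in 8/20 runs instead of ~1/200. The package
  implements the published procedure faithfully and therefore inherits
  this; remedies (many more validation trials, multi-run chance
  averaging via `n_runs`, a trial-blocked bootstrap) change the
  procedure and are left to the user. Single-image decisions at small
  trial counts should be read as exploratory.
* The ROI baseline reproduces, by design, the margin fragility it is
  meant to illustrate; its ANOVA p values are uncorrected for sphericity
  on the 10-level image factor (Greenhouse–Geisser is not applied).
* The `small` architecture is a surrogate: absolute accuracies are not
  comparable to study-scale AlexNet runs, though the inferential logic is
  identical.
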