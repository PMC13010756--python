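"""Statistical inference on decoding accuracy, and classification images.

The inferential logic per image:

1. *Empirical chance*: retrain the decoder after shuffling condition labels
   at the trial level (all fixations of a trial keep one common, shuffled
   label, and the trial-held-out split structure is preserved). The
   resulting validation accuracy is the pipeline's null reference — around
   50% for two balanced conditions, but noticeably noisy, which is why it
   is estimated empirically rather than assumed to be exactly 0.5.
2. *Bootstrap CI*: resample the trained decoder's validation predictions
   with replacement (1000 per replicate, 100 replicates) and take the
   quantiles implied by a Bonferroni correction over the image family
   (0.05/10 two-sided -> 0.0025 and 0.9975, a 99.5% CI).
3. *Decision*: the image decodes significantly above chance iff the CI's
   lower bound exceeds the empirical chance level. CIs entirely below
   chance are flagged, never reported as significant.
4. *Classification images*: average the decoder's input maps grouped by
   its *predicted* label; the signed difference of the two class means
   shows where condition-diagnostic fixation density sits.

Note on quantiles: with 100 replicates the 0.0025/0.9975 order statistics
are effectively the sample minimum and maximum; ``n_replicates`` is
configurable upward for smoother interval estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .data import GazeDataset
from .decoder import (ArchitectureSpec, TrainConfig, build_decoder,
                      collect_stream, evaluate_accuracy, train_decoder)
from .render import FixationMap, RenderConfig
from .sampling import SampleSpec, sample_maps


class DegenerateClassificationError(ValueError):
    """Every map was predicted as the same class."""


@dataclass(frozen=True)
class BootstrapConfig:
    resample_size: int = 1000
    n_replicates: int = 100
    familywise_alpha: float = 0.05
    n_comparisons: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.resample_size < 1 or self.n_replicates < 2:
            raise ValueError("resample_size >= 1 and n_replicates >= 2 required")
        if not (0 < self.familywise_alpha < 1):
            raise ValueError("familywise_alpha must lie in (0, 1)")
        if self.n_comparisons < 1:
            raise ValueError("n_comparisons must be >= 1")


@dataclass
class ChanceResult:
    """Validation accuracies of label-shuffled retraining runs."""

    image_id: str
    run_accuracies: list[float]

    @property
    def chance(self) -> float:
        return float(np.mean(self.run_accuracies))


@dataclass
class BootstrapResult:
    replicates: np.ndarray
    ci_lower: float
    ci_upper: float
    quantiles: tuple[float, float]
    ci_level: float


@dataclass
class SignificanceResult:
    image_id: str
    observed_accuracy: float
    empirical_chance: float
    ci_lower: float
    ci_upper: float
    significant_above_chance: bool
    below_chance: bool
    bootstrap_draws: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.ci_lower > self.ci_upper:
            raise ValueError("ci_lower must not exceed ci_upper")


@dataclass
class ClassificationImage:
    """Per-class mean input maps and their signed difference (A - B)."""

    class_labels: list[str]
    class_means: dict[str, np.ndarray]
    difference: np.ndarray
    n_per_class: dict[str, int]


def bonferroni_quantiles(
    familywise_alpha: float, n_comparisons: int
) -> tuple[float, float, float]:
    """Two-sided bootstrap quantiles under a Bonferroni correction.

    Returns ``(lower_q, upper_q, ci_level)`` where the per-comparison alpha
    is ``familywise_alpha / n_comparisons``; e.g. (0.05, 10) ->
    (0.0025, 0.9975, 0.995).
    """
    if not (0 < familywise_alpha < 1):
        raise ValueError("familywise_alpha must lie in (0, 1)")
    if n_comparisons < 1:
        raise ValueError("n_comparisons must be >= 1")
    alpha = familywise_alpha / n_comparisons
    return alpha / 2.0, 1.0 - alpha / 2.0, 1.0 - alpha


def bootstrap_accuracy(
    predictions: np.ndarray,
    true_labels: np.ndarray,
    config: BootstrapConfig,
) -> BootstrapResult:
    """Bootstrap the accuracy of fixed predictions on held-out data.

    Each replicate draws ``resample_size`` prediction/label pairs with
    replacement and records their accuracy; quantiles use linear
    interpolation between order statistics.
    """
    predictions = np.asarray(predictions)
    true_labels = np.asarray(true_labels)
    if predictions.size == 0 or predictions.shape != true_labels.shape:
        raise ValueError("predictions and labels must be equal-length, non-empty")
    rng = np.random.default_rng(config.seed)
    correct = (predictions == true_labels).astype(np.float64)
    idx = rng.integers(0, len(correct),
                       size=(config.n_replicates, config.resample_size))
    replicates = correct[idx].mean(axis=1)
    lo_q, hi_q, level = bonferroni_quantiles(
        config.familywise_alpha, config.n_comparisons)
    lo, hi = np.quantile(replicates, [lo_q, hi_q], method="linear")
    return BootstrapResult(replicates, float(lo), float(hi), (lo_q, hi_q),
                           level)


def decide_significance(
    image_id: str,
    observed_accuracy: float,
    empirical_chance: float,
    ci: tuple[float, float],
    bootstrap_draws: np.ndarray | None = None,
) -> SignificanceResult:
    """Apply the decision rule: significant iff the CI's lower bound
    exceeds the empirical chance level. A CI entirely below chance is
    flagged ``below_chance`` and is never significant."""
    for v in (observed_accuracy, empirical_chance, *ci):
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"proportions must lie in [0, 1], got {v}")
    lo, hi = ci
    return SignificanceResult(
        image_id=image_id,
        observed_accuracy=observed_accuracy,
        empirical_chance=empirical_chance,
        ci_lower=lo,
        ci_upper=hi,
        significant_above_chance=bool(lo > empirical_chance),
        below_chance=bool(hi < empirical_chance),
        bootstrap_draws=bootstrap_draws,
    )


def shuffle_trial_labels(
    trials: Sequence[tuple], rng: np.random.Generator
) -> dict[tuple, str]:
    """Permute condition labels across trials (trial-level shuffle):
    the multiset of labels is preserved, and every fixation of a trial
    carries that trial's single shuffled label."""
    trials = sorted(trials)
    labels = [t[2] for t in trials]
    perm = rng.permutation(len(labels))
    return {t: labels[p] for t, p in zip(trials, perm)}


def empirical_chance(
    dataset: GazeDataset,
    image_id: str,
    split: tuple[Sequence[tuple], Sequence[tuple]],
    render_config: RenderConfig,
    sample_spec: SampleSpec,
    arch_spec: ArchitectureSpec,
    train_config: TrainConfig,
    n_runs: int = 1,
    seed: int = 0,
) -> ChanceResult:
    """Estimate the empirical chance level by label-shuffled retraining.

    For each run: shuffle condition labels at the trial level over the
    image's trials (train and validation together, keeping the split
    fixed), rebuild the map streams, train a fresh decoder, and record its
    validation accuracy. The mean across runs is the chance level.
    """
    train_trials, val_trials = split
    rng = np.random.default_rng(seed)
    accs: list[float] = []
    for run in range(n_runs):
        label_map = shuffle_trial_labels(
            list(train_trials) + list(val_trials), rng)
        run_seed = int(rng.integers(2**31))
        tr_stream = sample_maps(
            dataset, image_id, train_trials, render_config,
            SampleSpec(sample_spec.n_train, sample_spec.n_val,
                       sample_spec.fixations_per_map, seed=run_seed),
            n=sample_spec.n_train, label_map=label_map)
        va_stream = sample_maps(
            dataset, image_id, val_trials, render_config,
            SampleSpec(sample_spec.n_train, sample_spec.n_val,
                       sample_spec.fixations_per_map, seed=run_seed + 1),
            n=sample_spec.n_val, label_map=label_map)
        tx, ty, labels = collect_stream(tr_stream, arch_spec)
        vx, vy, _ = collect_stream(va_stream, arch_spec)
        dec = build_decoder(arch_spec, seed=run_seed + 2)
        train_decoder(dec, tx, ty, vx, vy, train_config,
                      class_labels=labels)
        accs.append(evaluate_accuracy(dec, vx, vy))
    return ChanceResult(image_id=image_id, run_accuracies=accs)


def classification_images(
    maps: Sequence[FixationMap] | np.ndarray,
    predicted_labels: Sequence[str],
    class_order: Sequence[str] | None = None,
) -> ClassificationImage:
    """Reverse correlation: average input maps grouped by predicted label.

    ``difference`` is the first class's mean minus the second's (class
    order defaults to the sorted label set). Raises
    :class:`DegenerateClassificationError` if a class received no maps.
    """
    arr = (maps if isinstance(maps, np.ndarray)
           else np.stack([m.values for m in maps]))
    predicted = np.asarray(predicted_labels)
    labels = list(class_order) if class_order else sorted(set(predicted))
    if len(labels) != 2:
        raise ValueError(f"need exactly two classes, got {labels!r}")
    means: dict[str, np.ndarray] = {}
    counts: dict[str, int] = {}
    for lab in labels:
        sel = predicted == lab
        counts[lab] = int(sel.sum())
        if counts[lab] == 0:
            raise DegenerateClassificationError(
                f"no maps predicted as class {lab!r}"
            )
        means[lab] = arr[sel].mean(axis=0)
    return ClassificationImage(
        class_labels=labels,
        class_means=means,
        difference=means[labels[0]] - means[labels[1]],
        n_per_class=counts,
    )


def save_difference_png(ci: ClassificationImage, path) -> None:
    """Render the signed difference map with a diverging palette (blue =
    fewer diagnostic fixations for the first class, red = more), intensity
    proportional to |difference|, symmetric about zero."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    vmax = float(np.abs(ci.difference).max()) or 1.0
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.imshow(ci.difference, cmap="RdBu_r", vmin=-vmax, vmax=vmax)
    ax.set_axis_off()
    ax.set_title(f"{ci.class_labels[0]} - {ci.class_labels[1]}", fontsize=9)
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
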