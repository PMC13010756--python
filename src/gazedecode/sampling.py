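"""Trial-held-out splitting, map sampling, and online augmentation.

The anti-overfitting core of the decoding pipeline: training and validation
maps must come from *different trials*, because fixations close in time are
also close in space, so a same-trial split would leak spatial structure and
inflate decoding accuracy. One repetition per (participant, condition) cell
is held out for validation; maps are then generated by sampling fixations
with replacement from each side's pool, balanced across conditions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np
from scipy import ndimage

from .data import GazeDataset
from .render import FixationMap, RenderConfig, render_map


class DesignError(ValueError):
    """A design cell cannot support the requested split."""


class SamplingError(ValueError):
    """A condition pool is empty or otherwise unusable for sampling."""


@dataclass(frozen=True)
class SplitSpec:
    """Held-out-repetition split specification."""

    heldout_reps_per_cell: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.heldout_reps_per_cell < 1:
            raise ValueError("heldout_reps_per_cell must be >= 1")


@dataclass(frozen=True)
class SampleSpec:
    """How many labelled maps to draw, and how.

    Defaults mirror the study-scale corpus: 180,000 training and 60,000
    validation single-fixation maps per image, balanced across the two
    conditions, fixations drawn uniformly with replacement.
    """

    n_train: int = 180_000
    n_val: int = 60_000
    fixations_per_map: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_train, self.n_val, self.fixations_per_map) < 1:
            raise ValueError("sample counts must be >= 1")


@dataclass(frozen=True)
class AugmentationSpec:
    """Online augmentation ranges (applied scale -> rotate -> translate ->
    flip, all about the map centre; vacated pixels are zero-filled)."""

    rotation_deg: float = 20.0
    translation_px: float = 10.0
    scale_xy: tuple[float, float] = (0.8, 1.2)
    horizontal_flip_prob: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rotation_deg < 0 or self.translation_px < 0:
            raise ValueError("augmentation ranges must be non-negative")
        if not (0 <= self.horizontal_flip_prob <= 1):
            raise ValueError("flip probability must lie in [0, 1]")
        if self.scale_xy[0] > self.scale_xy[1]:
            raise ValueError("scale range must be well-ordered")


def split_by_trial(
    dataset: GazeDataset, image_id: str, spec: SplitSpec
) -> tuple[list[tuple], list[tuple]]:
    """Partition an image's trials into (train, validation) keys.

    Exactly ``spec.heldout_reps_per_cell`` repetitions per
    (participant, condition) cell go to validation, chosen uniformly at
    random; all remaining trials train. Raises :class:`DesignError` naming
    the first cell with too few repetitions.
    """
    rng = np.random.default_rng(spec.seed)
    keys = dataset.trial_keys(image_id)
    if not keys:
        raise DesignError(f"no trials for image {image_id!r}")
    cells: dict[tuple, list[tuple]] = {}
    for key in keys:
        cells.setdefault((key[0], key[2]), []).append(key)
    train: list[tuple] = []
    val: list[tuple] = []
    for cell in sorted(cells):
        trials = sorted(cells[cell])
        if len(trials) <= spec.heldout_reps_per_cell:
            raise DesignError(
                f"cell (participant={cell[0]!r}, condition={cell[1]!r}) of "
                f"image {image_id!r} has {len(trials)} repetitions; "
                f"needs > {spec.heldout_reps_per_cell}"
            )
        held = rng.choice(len(trials), size=spec.heldout_reps_per_cell,
                          replace=False)
        held_set = set(held.tolist())
        for i, t in enumerate(trials):
            (val if i in held_set else train).append(t)
    return sorted(train), sorted(val)


def write_split_manifest(path, train, val, spec: SplitSpec) -> None:
    """Persist a split as JSON for exact reproducibility."""
    with open(path, "w") as fh:
        json.dump(
            {
                "spec": {"heldout_reps_per_cell": spec.heldout_reps_per_cell,
                         "seed": spec.seed},
                "train": [list(k) for k in train],
                "validation": [list(k) for k in val],
            },
            fh,
            indent=1,
        )


def condition_pools(
    dataset: GazeDataset,
    trials: Sequence[tuple],
    label_map: Mapping[tuple, str] | None = None,
) -> dict[str, np.ndarray]:
    """Per-condition (n, 2) arrays of in-image fixation coordinates pooled
    over the given trials. ``label_map`` overrides trial labels (used for
    trial-level label shuffling: all of a trial's fixations move together)."""
    pools: dict[str, list[np.ndarray]] = {}
    for key in trials:
        label = label_map[key] if label_map is not None else key[2]
        fx = dataset.trial_fixations(key)
        if len(fx):
            pools.setdefault(label, []).append(fx[["x", "y"]].to_numpy(float))
    return {
        lab: np.concatenate(chunks, axis=0) for lab, chunks in
        sorted(pools.items())
    }


def sample_maps(
    dataset: GazeDataset,
    image_id: str,
    trials: Sequence[tuple],
    render_config: RenderConfig,
    spec: SampleSpec,
    n: int | None = None,
    label_map: Mapping[tuple, str] | None = None,
) -> Iterator[FixationMap]:
    """Lazily yield ``n`` labelled fixation maps (default ``spec.n_train``).

    Each map renders ``spec.fixations_per_map`` fixations drawn uniformly
    with replacement from one condition's pooled trial fixations; labels
    alternate between the two conditions so counts are balanced to within 1.
    Single-fixation renders are memoised per fixation pixel, which keeps
    large streams cheap (the pool has far fewer distinct fixations than the
    stream has maps).
    """
    n = spec.n_train if n is None else n
    frame = dataset.frames[image_id]
    pools = condition_pools(dataset, trials, label_map)
    labels = sorted(pools)
    if len(labels) < 2:
        raise SamplingError(
            f"need fixations from two conditions, got {labels!r}"
        )
    for lab in labels:
        if len(pools[lab]) == 0:
            raise SamplingError(f"condition {lab!r} has no fixations")
    rng = np.random.default_rng(spec.seed)
    cache: dict[tuple, np.ndarray] = {}

    def one(i: int) -> FixationMap:
        label = labels[i % len(labels)]
        pool = pools[label]
        idx = rng.integers(0, len(pool), size=spec.fixations_per_map)
        pts = pool[idx]
        if spec.fixations_per_map == 1:
            key = (label, int(round(pts[0, 0])), int(round(pts[0, 1])))
            if key not in cache:
                cache[key] = render_map(
                    pts, frame, dataset.geometry, render_config
                ).values
            values = cache[key]
            return FixationMap(values, label=label,
                               provenance={"image": image_id, "i": i})
        return render_map(pts, frame, dataset.geometry, render_config,
                          label=label, provenance={"image": image_id, "i": i})

    return (one(i) for i in range(n))


def _affine_matrix(spec_params: dict, shape: tuple[int, int]) -> np.ndarray:
    """Inverse (output -> input) homogeneous transform about the map centre
    for scale -> rotate -> translate -> flip, in (y, x) coordinate order."""
    sx, sy = spec_params["scale"]
    theta = np.deg2rad(spec_params["rotation"])
    tx, ty = spec_params["translation"]
    flip = spec_params["flip"]
    h, w = shape
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0

    def mat(a):
        return np.asarray(a, dtype=float)

    scale = mat([[sy, 0, 0], [0, sx, 0], [0, 0, 1]])
    rot = mat([[np.cos(theta), -np.sin(theta), 0],
               [np.sin(theta), np.cos(theta), 0], [0, 0, 1]])
    trans = mat([[1, 0, ty], [0, 1, tx], [0, 0, 1]])
    flipm = mat([[1, 0, 0], [0, -1 if flip else 1, 0], [0, 0, 1]])
    centre = mat([[1, 0, cy], [0, 1, cx], [0, 0, 1]])
    uncentre = mat([[1, 0, -cy], [0, 1, -cx], [0, 0, 1]])
    forward = centre @ flipm @ trans @ rot @ scale @ uncentre
    return np.linalg.inv(forward)


def augment(
    fmap: FixationMap,
    spec: AugmentationSpec,
    rng: np.random.Generator,
) -> FixationMap:
    """Random affine augmentation of one map; label/provenance preserved.

    Draws rotation, translation, per-axis scale and flip from ``rng`` and
    applies them about the map centre with bilinear interpolation,
    zero-filling vacated pixels. With all ranges zero and flip probability
    zero the output equals the input exactly.
    """
    params = {
        "rotation": rng.uniform(-spec.rotation_deg, spec.rotation_deg),
        "translation": (
            rng.uniform(-spec.translation_px, spec.translation_px),
            rng.uniform(-spec.translation_px, spec.translation_px),
        ),
        "scale": (
            rng.uniform(*spec.scale_xy),
            rng.uniform(*spec.scale_xy),
        ),
        "flip": bool(rng.random() < spec.horizontal_flip_prob),
    }
    return apply_augmentation(fmap, params)


def apply_augmentation(fmap: FixationMap, params: dict) -> FixationMap:
    """Deterministically apply a drawn augmentation parameter set."""
    identity = (
        params["rotation"] == 0
        and params["translation"] == (0.0, 0.0)
        and params["scale"] == (1.0, 1.0)
    )
    if identity and not params["flip"]:
        values = fmap.values.copy()
    elif identity and params["flip"]:
        values = fmap.values[:, ::-1].copy()
    else:
        inv = _affine_matrix(params, fmap.values.shape)
        values = ndimage.affine_transform(
            fmap.values.astype(np.float64),
            inv[:2, :2],
            offset=inv[:2, 2],
            order=1,
            mode="constant",
            cval=0.0,
        )
        np.clip(values, 0.0, None, out=values)
    return FixationMap(values.astype(np.float32), label=fmap.label,
                       provenance=dict(fmap.provenance))
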