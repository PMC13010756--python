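"""End-to-end orchestration: simulate/ingest -> split -> train -> infer ->
classification image -> ROI baseline, per image, from one config.

Per-stage seeds are derived by hashing (global seed, stage name, image id),
so adding images to a run never perturbs the randomness of existing
images. A run directory receives one JSON result bundle and one difference
PNG per image plus an append-only ``manifest.jsonl``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import yaml

from . import __version__
from .data import GazeDataset, dataset_census, read_fixation_table
from .decoder import (ArchitectureSpec, TrainConfig, build_decoder,
                      collect_stream, evaluate_accuracy, predict,
                      train_decoder)
from .geometry import ScreenGeometry, StimulusFrame
from .inference import (BootstrapConfig, bootstrap_accuracy,
                        classification_images, decide_significance,
                        empirical_chance, save_difference_png)
from .render import RenderConfig
from .roi import (EllipseROI, proportion_in_roi, rasterize_ellipse,
                  rm_anova_2x10)
from .sampling import (AugmentationSpec, SampleSpec, SplitSpec, sample_maps,
                       split_by_trial, write_split_manifest)
from .simulate import EffectSpec, SaliencyScene, SimConfig, sample_dataset

logger = logging.getLogger(__name__)


def derive_seed(global_seed: int, stage: str, image_id: str = "") -> int:
    """Deterministic per-(stage, image) seed below 2**31."""
    digest = hashlib.blake2s(
        f"{global_seed}:{stage}:{image_id}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)


@dataclass
class RunConfig:
    """Everything one experiment run needs, with a single global seed."""

    geometry: ScreenGeometry
    render: RenderConfig = field(default_factory=RenderConfig)
    split: SplitSpec = field(default_factory=SplitSpec)
    sample: SampleSpec = field(default_factory=SampleSpec)
    augmentation: AugmentationSpec | None = None
    architecture: ArchitectureSpec = field(default_factory=ArchitectureSpec)
    training: TrainConfig = field(default_factory=TrainConfig)
    bootstrap: BootstrapConfig = field(default_factory=BootstrapConfig)
    chance_runs: int = 1
    seed: int = 0
    data_path: str | None = None
    coordinate_frame: str = "image"
    frames: dict[str, StimulusFrame] = field(default_factory=dict)
    rois: dict[str, dict] = field(default_factory=dict)
    simulation: dict | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        geo = raw.get("geometry", {})
        if "diagonal_inch" in geo:
            geometry = ScreenGeometry.from_diagonal(
                geo["viewing_distance_cm"],
                tuple(geo["screen_px"]),
                geo["diagonal_inch"],
            )
        elif geo:
            geometry = ScreenGeometry(
                geo["viewing_distance_cm"], tuple(geo["screen_px"]),
                tuple(geo["screen_cm"]))
        else:
            geometry = ScreenGeometry(57.29, (640, 480), (32.0, 24.0))

        def build(klass, key, **extra):
            block = dict(raw.get(key) or {})
            block.update(extra)
            fields = {f.name for f in dataclasses.fields(klass)}
            kwargs = {}
            for k, v in block.items():
                if k in fields:
                    kwargs[k] = tuple(v) if isinstance(v, list) else v
            return klass(**kwargs)

        frames = {
            fid: StimulusFrame(fid, tuple(f["size_px"]),
                               tuple(f.get("screen_offset_px", (0, 0))))
            for fid, f in (raw.get("frames") or {}).items()
        }
        return cls(
            geometry=geometry,
            render=build(RenderConfig, "render"),
            split=build(SplitSpec, "split"),
            sample=build(SampleSpec, "sample"),
            augmentation=(build(AugmentationSpec, "augmentation")
                          if raw.get("augmentation") else None),
            architecture=build(ArchitectureSpec, "architecture"),
            training=build(TrainConfig, "training"),
            bootstrap=build(BootstrapConfig, "bootstrap"),
            chance_runs=int(raw.get("chance_runs", 1)),
            seed=int(raw.get("seed", 0)),
            data_path=raw.get("data_path"),
            coordinate_frame=raw.get("coordinate_frame", "image"),
            frames=frames,
            rois=raw.get("rois") or {},
            simulation=raw.get("simulation"),
        )


def load_or_simulate(config: RunConfig) -> GazeDataset:
    """Data source resolution: read the fixation table if configured,
    otherwise simulate from the config's scene block."""
    if config.data_path:
        return read_fixation_table(
            config.data_path, config.geometry, config.frames,
            coordinate_frame=config.coordinate_frame)
    sim_raw = config.simulation or {}
    scene = (SaliencyScene(**sim_raw["scene"]) if "scene" in sim_raw
             else SaliencyScene.default())
    effect = EffectSpec(**(sim_raw.get("effect") or {}))
    sim_fields = {f.name for f in dataclasses.fields(SimConfig)}
    sim_kwargs = {k: v for k, v in (sim_raw.get("sim") or {}).items()
                  if k in sim_fields}
    sim_kwargs.setdefault("seed", derive_seed(config.seed, "simulate"))
    sim = SimConfig(**sim_kwargs)
    return sample_dataset(scene, effect, sim,
                          image_id=sim_raw.get("image_id", "img1"))


def _with_seed(spec, seed: int):
    return dataclasses.replace(spec, seed=seed)


def analyse_image(
    dataset: GazeDataset, image_id: str, config: RunConfig
) -> dict[str, Any]:
    """Run the full decoding analysis for one image; returns the result
    record (all scalars JSON-ready, arrays included under numpy types)."""
    split_spec = _with_seed(config.split,
                            derive_seed(config.seed, "split", image_id))
    train_trials, val_trials = split_by_trial(dataset, image_id, split_spec)

    sample_spec = _with_seed(config.sample,
                             derive_seed(config.seed, "sample", image_id))
    tr_stream = sample_maps(dataset, image_id, train_trials, config.render,
                            sample_spec, n=sample_spec.n_train)
    va_stream = sample_maps(
        dataset, image_id, val_trials, config.render,
        _with_seed(sample_spec, sample_spec.seed + 1), n=sample_spec.n_val)
    tx, ty, labels = collect_stream(tr_stream, config.architecture)
    vx, vy, _ = collect_stream(va_stream, config.architecture)

    train_cfg = _with_seed(config.training,
                           derive_seed(config.seed, "train", image_id))
    dec = build_decoder(config.architecture,
                        seed=derive_seed(config.seed, "init", image_id))
    train_decoder(dec, tx, ty, vx, vy, train_cfg, class_labels=labels,
                  augmentation=config.augmentation)
    pred_idx, scores = predict(dec, vx)
    observed = float((pred_idx == vy).mean())

    chance = empirical_chance(
        dataset, image_id, (train_trials, val_trials), config.render,
        sample_spec, config.architecture, train_cfg,
        n_runs=config.chance_runs,
        seed=derive_seed(config.seed, "chance", image_id))

    boot_cfg = _with_seed(config.bootstrap,
                          derive_seed(config.seed, "bootstrap", image_id))
    boot = bootstrap_accuracy(pred_idx, vy, boot_cfg)
    sig = decide_significance(image_id, observed, chance.chance,
                              (boot.ci_lower, boot.ci_upper),
                              boot.replicates)
    ci_img = classification_images(
        vx[:, 0], [labels[i] for i in pred_idx], class_order=labels)
    return {
        "image": image_id,
        "labels": labels,
        "split": {"train": [list(k) for k in train_trials],
                  "validation": [list(k) for k in val_trials]},
        "observed_accuracy": observed,
        "empirical_chance": chance.chance,
        "chance_runs": chance.run_accuracies,
        "ci": [sig.ci_lower, sig.ci_upper],
        "ci_level": boot.ci_level,
        "bootstrap_replicates": boot.replicates.tolist(),
        "significant_above_chance": sig.significant_above_chance,
        "below_chance": sig.below_chance,
        "history": dec.history,
        "fingerprint": dec.fingerprint,
        "_classification_image": ci_img,
    }


def run_pipeline(
    config: RunConfig,
    out_dir: str | Path,
    images: Sequence[str] | None = None,
    dataset: GazeDataset | None = None,
) -> list[dict]:
    """Analyse each requested image and write result bundles + manifest.

    Failures abort only the offending image (logged in the manifest);
    other images continue.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = out / "manifest.jsonl"
    dataset = dataset or load_or_simulate(config)
    images = list(images) if images else dataset.images
    results = []
    for image_id in images:
        started = time.time()
        entry = {
            "image": image_id,
            "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
            "seed": config.seed,
            "version": __version__,
        }
        try:
            record = analyse_image(dataset, image_id, config)
            ci_img = record.pop("_classification_image")
            save_difference_png(ci_img, out / f"{image_id}_difference.png")
            np.savetxt(out / f"{image_id}_difference.txt", ci_img.difference)
            with open(out / f"{image_id}_result.json", "w") as fh:
                json.dump(record, fh, indent=1)
            entry.update(status="ok",
                         wall_clock_s=round(time.time() - started, 2),
                         result=f"{image_id}_result.json")
            results.append(record)
        except Exception as exc:  # noqa: BLE001 - per-image isolation
            logger.exception("image %s failed", image_id)
            entry.update(status="failed", reason=f"{type(exc).__name__}: {exc}")
        with open(manifest_path, "a") as fh:
            fh.write(json.dumps(entry) + "\n")
    return results


def roi_analysis(
    dataset: GazeDataset, config: RunConfig, variant: str = "original"
) -> dict[str, Any]:
    """ROI baseline: rasterise the configured ellipses (optionally eroded or
    dilated by 0.78 dva), build the proportion table, and run the two-way
    repeated-measures ANOVA."""
    from .roi import dilate_roi, erode_roi  # local: avoid cycle at import

    if not config.rois:
        raise KeyError("no ROI definitions in config")
    rois: dict[str, EllipseROI] = {}
    for image_id, spec in config.rois.items():
        frame = dataset.frames[image_id]
        roi = rasterize_ellipse(
            image_id, tuple(spec["center_px"]), tuple(spec["semi_axes_px"]),
            float(spec.get("rotation_deg", 0.0)), frame.size_px)
        if variant == "smaller":
            roi = erode_roi(roi, float(spec.get("margin_dva", 0.78)),
                            dataset.geometry)
        elif variant == "larger":
            roi = dilate_roi(roi, float(spec.get("margin_dva", 0.78)),
                             dataset.geometry)
        rois[image_id] = roi
    table = proportion_in_roi(dataset, rois)
    result: dict[str, Any] = {"variant": variant, "table": table}
    if table["image"].nunique() >= 2 and table["condition"].nunique() >= 2:
        result["anova"] = rm_anova_2x10(table)
    return result
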