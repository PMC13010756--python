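"""Fixation-density map rendering.

A single-fixation map is built by marking the fixation as a unit impulse in
a zero matrix at the native image resolution, convolving with an isotropic
Gaussian whose sigma corresponds to 1 dva (approximating foveal extent and
tracker resolution), and resizing to the decoder's input size with bilinear
interpolation. Because the input is a sum of impulses, the convolution is
computed exactly by stamping a truncated, renormalised Gaussian kernel at
each fixation pixel, which is orders of magnitude faster than filtering the
full raster and numerically identical.

Multi-trial condition heatmaps average trial maps within participant and
then across participants (equal participant weighting) and are peak-
normalised for display.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Sequence

import numpy as np
from skimage.transform import resize as _sk_resize

from .data import Fixation, GazeDataset
from .geometry import ScreenGeometry, StimulusFrame, px_per_dva


class EmptyInputError(ValueError):
    """No usable (in-bounds) fixations to render."""


@dataclass(frozen=True)
class RenderConfig:
    """How fixation maps are rendered.

    Parameters
    ----------
    sigma_dva
        Gaussian bandwidth in degrees of visual angle. 1 dva approximates
        the fovea plus the accepted calibration error (<= 0.5 dva).
    kernel_truncation_sigmas
        Kernel support half-width in sigmas; the truncated kernel is
        renormalised to unit sum.
    output_size_px
        (width, height) of the resized map fed to the decoder.
    normalization
        Pre-resize scaling: "unit-sum" (density; mass = number of
        fixations), "unit-peak", or "none".
    rescale_after_resize
        "unit-peak" rescales the resized map to max 1 so single- and
        multi-fixation maps share dynamic range at the decoder input;
        "none" leaves the resized values untouched.
    resize_order
        Interpolation order for the resize (1 = bilinear; 0 = nearest).
    weight_by_duration
        If True, each fixation's impulse is weighted by its duration in
        ms instead of 1. Off by default: each fixation counts equally.
    """

    sigma_dva: float = 1.0
    kernel_truncation_sigmas: float = 4.0
    output_size_px: tuple[int, int] = (227, 227)
    normalization: Literal["unit-sum", "unit-peak", "none"] = "unit-sum"
    rescale_after_resize: Literal["unit-peak", "none"] = "unit-peak"
    resize_order: int = 1
    weight_by_duration: bool = False

    def __post_init__(self) -> None:
        if self.sigma_dva <= 0 or self.kernel_truncation_sigmas <= 0:
            raise ValueError("sigma_dva and kernel truncation must be positive")
        if min(self.output_size_px) < 8:
            raise ValueError("output size must be at least 8 px per axis")


@dataclass
class FixationMap:
    """A rendered fixation-density map with its provenance.

    ``values`` is a non-negative 2D float32 array of shape
    (output height, output width); ``label`` is the condition the map's
    fixations were drawn from (None for mixed/exploratory maps).
    """

    values: np.ndarray
    label: str | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float32)
        if v.ndim != 2:
            raise ValueError("map values must be 2D")
        if not np.isfinite(v).all() or (v < 0).any():
            raise ValueError("map values must be finite and non-negative")
        self.values = v


def gaussian_kernel(sigma_px: tuple[float, float], truncate: float) -> np.ndarray:
    """Truncated 2D Gaussian, renormalised to unit sum.

    ``sigma_px`` is (sigma_x, sigma_y); support is +/- truncate sigmas
    rounded to whole pixels per axis.
    """
    sx, sy = sigma_px
    rx = max(1, int(round(truncate * sx)))
    ry = max(1, int(round(truncate * sy)))
    x = np.arange(-rx, rx + 1, dtype=np.float64)
    y = np.arange(-ry, ry + 1, dtype=np.float64)
    kx = np.exp(-0.5 * (x / sx) ** 2)
    ky = np.exp(-0.5 * (y / sy) ** 2)
    k = np.outer(ky, kx)
    return k / k.sum()


def _stamp(canvas: np.ndarray, kernel: np.ndarray, cx: int, cy: int,
           weight: float) -> None:
    """Add ``weight * kernel`` centred at (cx, cy), clipped to the canvas."""
    kh, kw = kernel.shape
    ry, rx = kh // 2, kw // 2
    h, w = canvas.shape
    y0, y1 = cy - ry, cy + ry + 1
    x0, x1 = cx - rx, cx + rx + 1
    ky0, kx0 = max(0, -y0), max(0, -x0)
    y0, x0 = max(0, y0), max(0, x0)
    y1, x1 = min(h, y1), min(w, x1)
    if y1 <= y0 or x1 <= x0:
        return
    canvas[y0:y1, x0:x1] += weight * kernel[ky0:ky0 + (y1 - y0),
                                            kx0:kx0 + (x1 - x0)]


def render_native(
    fixations,
    frame: StimulusFrame,
    geometry: ScreenGeometry,
    config: RenderConfig,
) -> np.ndarray:
    """Render the smoothed map at native image resolution (no resize).

    ``fixations`` is a sequence of :class:`Fixation` or an (n, 2) array of
    image-frame (x, y); out-of-image fixations are skipped.
    """
    w, h = frame.size_px
    if hasattr(fixations, "ndim"):
        arr = np.asarray(fixations, dtype=float).reshape(-1, 2)
        xs, ys = arr[:, 0], arr[:, 1]
        weights = np.ones(len(arr))
    else:
        fixations = list(fixations)
        xs = np.array([f.x for f in fixations], dtype=float)
        ys = np.array([f.y for f in fixations], dtype=float)
        weights = (
            np.array([f.duration_ms for f in fixations], dtype=float)
            if config.weight_by_duration
            else np.ones(len(fixations))
        )
    inb = (xs >= 0) & (xs < w) & (ys >= 0) & (ys < h)
    if not inb.any():
        raise EmptyInputError("no in-bounds fixations to render")
    sigma = tuple(config.sigma_dva * p for p in px_per_dva(geometry))
    kernel = gaussian_kernel(sigma, config.kernel_truncation_sigmas)
    canvas = np.zeros((h, w), dtype=np.float64)
    for x, y, wt in zip(xs[inb], ys[inb], weights[inb]):
        _stamp(canvas, kernel, int(round(x)), int(round(y)), wt)
    if config.normalization == "unit-sum":
        s = canvas.sum()
        if s > 0:
            canvas /= s
    elif config.normalization == "unit-peak":
        m = canvas.max()
        if m > 0:
            canvas /= m
    return canvas


def resize_map(native: np.ndarray, config: RenderConfig) -> np.ndarray:
    out_w, out_h = config.output_size_px
    resized = _sk_resize(
        native,
        (out_h, out_w),
        order=config.resize_order,
        mode="constant",
        anti_aliasing=False,
        preserve_range=True,
    )
    if config.rescale_after_resize == "unit-peak":
        m = resized.max()
        if m > 0:
            resized = resized / m
    return np.ascontiguousarray(resized, dtype=np.float32)


def render_map(
    fixations,
    frame: StimulusFrame,
    geometry: ScreenGeometry,
    config: RenderConfig | None = None,
    label: str | None = None,
    provenance: dict | None = None,
) -> FixationMap:
    """Render fixations into a decoder-ready :class:`FixationMap`."""
    config = config or RenderConfig()
    native = render_native(fixations, frame, geometry, config)
    values = resize_map(native, config)
    return FixationMap(values, label=label, provenance=provenance or {})


def export_map(fmap: FixationMap, basepath, config: RenderConfig) -> None:
    """Write a map as PNG (display) plus a flat numeric array with a JSON
    sidecar carrying label, provenance, and a config fingerprint."""
    import hashlib
    import json
    from dataclasses import asdict
    from pathlib import Path

    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    base = Path(basepath)
    plt.imsave(base.with_suffix(".png"), fmap.values, cmap="turbo")
    np.savetxt(base.with_suffix(".txt"), fmap.values)
    cfg = asdict(config)
    fingerprint = hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]
    with open(base.with_suffix(".json"), "w") as fh:
        json.dump({"label": fmap.label, "provenance": fmap.provenance,
                   "render_config": cfg, "config_fingerprint": fingerprint,
                   "shape": list(fmap.values.shape)}, fh, indent=1)


def render_heatmap(
    dataset: GazeDataset,
    image_id: str,
    condition: str,
    config: RenderConfig | None = None,
) -> FixationMap:
    """Condition heatmap: mean of trial maps within each participant, then
    mean across participants (equal participant weighting), peak-normalised
    for display."""
    config = config or RenderConfig()
    trial_cfg = replace(config, normalization="unit-sum",
                        rescale_after_resize="none")
    frame = dataset.frames[image_id]
    keys = [k for k in dataset.trial_keys(image_id) if k[2] == condition]
    per_participant: dict[str, list[np.ndarray]] = {}
    for key in keys:
        fx = dataset.trial_fixations(key)
        if fx.empty:
            continue
        m = render_map(fx[["x", "y"]].to_numpy(), frame, dataset.geometry,
                       trial_cfg)
        per_participant.setdefault(key[0], []).append(m.values)
    if not per_participant:
        raise EmptyInputError(
            f"no trials with in-image fixations for ({image_id}, {condition})"
        )
    participant_means = [np.mean(maps, axis=0) for maps in
                         per_participant.values()]
    mean_map = np.mean(participant_means, axis=0)
    peak = mean_map.max()
    if peak > 0:
        mean_map = mean_map / peak
    return FixationMap(
        mean_map.astype(np.float32),
        label=condition,
        provenance={
            "image": image_id,
            "participants": sorted(per_participant),
            "n_trials": sum(len(v) for v in per_participant.values()),
        },
    )
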