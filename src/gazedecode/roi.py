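"""The classical baseline: elliptical ROIs, margin variation by binary
morphology, fixation-proportion tables, two-way repeated-measures ANOVA
with partial eta squared, and the RM-ANOVA sample-size computation.

The margin-variation machinery exists because ROI results are fragile:
eroding or dilating the ellipse by a fraction of a degree of visual angle
can flip the significance of the condition effect, which is exactly the
phenomenon the decoding approach avoids.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from skimage.morphology import disk

from .data import GazeDataset
from .geometry import GeometryError, ScreenGeometry, mean_px_per_dva


class DegenerateROIError(ValueError):
    """Morphology emptied the ROI mask."""


class BalanceError(ValueError):
    """The ANOVA table is incomplete or unbalanced."""


@dataclass
class EllipseROI:
    """An elliptical region of interest with its rasterised mask.

    ``raster`` is a boolean array at image resolution; pixel (x, y) is set
    iff the pixel centre satisfies the rotated-ellipse inequality. After
    morphological operations the raster no longer matches the analytic
    ellipse; ``semi_axes_px`` then records the original definition.
    """

    image_id: str
    center_px: tuple[float, float]
    semi_axes_px: tuple[float, float]
    rotation_deg: float
    raster: np.ndarray

    def __post_init__(self) -> None:
        if min(self.semi_axes_px) <= 0:
            raise GeometryError("semi-axes must be positive")
        self.raster = np.asarray(self.raster, dtype=bool)
        if not self.raster.any():
            raise DegenerateROIError(f"empty ROI raster for {self.image_id!r}")

    @property
    def area_px(self) -> int:
        return int(self.raster.sum())

    def extent_px(self, axis: str = "major") -> int:
        """Full mask extent in pixels along the image x ("major" when the
        first semi-axis is the larger) or y axis."""
        proj = self.raster.any(axis=0) if axis in ("major", "x") else \
            self.raster.any(axis=1)
        nz = np.flatnonzero(proj)
        return int(nz[-1] - nz[0] + 1)


def rasterize_ellipse(
    image_id: str,
    center_px: tuple[float, float],
    semi_axes_px: tuple[float, float],
    rotation_deg: float,
    image_size_px: tuple[int, int],
) -> EllipseROI:
    """Rasterise a rotated ellipse, clipped to the image bounds.

    Pixel centres (x + 0 offset convention: pixel (i, j) tested at
    coordinates (j, i)) are tested against
    ``(x'/a)^2 + (y'/b)^2 <= 1`` in the ellipse's rotated frame.
    """
    w, h = image_size_px
    a, b = semi_axes_px
    cx, cy = center_px
    yy, xx = np.mgrid[0:h, 0:w]
    th = math.radians(rotation_deg)
    dx, dy = xx - cx, yy - cy
    xr = dx * math.cos(th) + dy * math.sin(th)
    yr = -dx * math.sin(th) + dy * math.cos(th)
    mask = (xr / a) ** 2 + (yr / b) ** 2 <= 1.0
    if not mask.any():
        raise GeometryError(
            f"ellipse (centre {center_px}, axes {semi_axes_px}) does not "
            f"intersect the {image_size_px} image"
        )
    return EllipseROI(image_id, center_px, semi_axes_px, rotation_deg, mask)


def _disc_radius_px(radius_dva: float, geometry: ScreenGeometry) -> int:
    if radius_dva <= 0:
        raise ValueError("radius_dva must be positive")
    return max(1, round(radius_dva * mean_px_per_dva(geometry)))


def erode_roi(roi: EllipseROI, radius_dva: float,
              geometry: ScreenGeometry) -> EllipseROI:
    """Binary erosion with a discrete Euclidean disc of the given radius in
    dva (rounded to whole pixels); uniformly shrinks the mask boundary."""
    r = _disc_radius_px(radius_dva, geometry)
    mask = ndimage.binary_erosion(roi.raster, structure=disk(r))
    if not mask.any():
        raise DegenerateROIError(
            f"eroding ROI {roi.image_id!r} by {radius_dva} dva ({r} px) "
            "emptied the mask"
        )
    return EllipseROI(roi.image_id, roi.center_px, roi.semi_axes_px,
                      roi.rotation_deg, mask)


def dilate_roi(roi: EllipseROI, radius_dva: float,
               geometry: ScreenGeometry) -> EllipseROI:
    """Binary dilation with the same disc element (the 'slightly larger'
    ROI variant)."""
    r = _disc_radius_px(radius_dva, geometry)
    mask = ndimage.binary_dilation(roi.raster, structure=disk(r))
    return EllipseROI(roi.image_id, roi.center_px, roi.semi_axes_px,
                      roi.rotation_deg, mask)


def proportion_in_roi(
    dataset: GazeDataset, rois: Mapping[str, EllipseROI]
) -> pd.DataFrame:
    """Per-cell proportion of fixations inside the image's ROI.

    One row per (participant, image, condition): in-ROI fixations divided
    by in-image fixations, pooled over repetitions. Cells with zero
    in-image fixations appear with proportion NaN (missing, not zero).
    Out-of-image fixations are excluded from both numerator and
    denominator.
    """
    missing = set(dataset.images) - set(rois)
    if missing:
        raise KeyError(f"images without a ROI: {sorted(missing)}")
    df = dataset.fixations
    rows = []
    for (p, im, c), sub in df.groupby(
            ["participant", "image", "condition"], observed=True):
        sub = sub[sub["in_image"]]
        n = len(sub)
        if n == 0:
            prop = np.nan
        else:
            mask = rois[im].raster
            xs = sub["x"].to_numpy(float).round().astype(int)
            ys = sub["y"].to_numpy(float).round().astype(int)
            h, w = mask.shape
            xs = np.clip(xs, 0, w - 1)
            ys = np.clip(ys, 0, h - 1)
            prop = float(mask[ys, xs].sum()) / n
        rows.append({"participant": p, "image": im, "condition": c,
                     "n_fixations": n, "proportion": prop})
    return pd.DataFrame(rows)


@dataclass
class EffectResult:
    ss: float
    df: int
    ms: float
    f: float
    p: float
    partial_eta_sq: float
    error_ss: float
    error_df: int


@dataclass
class AnovaResult:
    """Two-way within-subject ANOVA summary (condition x image)."""

    n_subjects: int
    effects: dict[str, EffectResult]
    ss_total: float
    ss_subject: float

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                name: {
                    "SS": e.ss, "df": e.df, "MS": e.ms, "F": e.f, "p": e.p,
                    "partial_eta_sq": e.partial_eta_sq,
                    "error_SS": e.error_ss, "error_df": e.error_df,
                }
                for name, e in self.effects.items()
            }
        ).T


def rm_anova_2x10(
    table: pd.DataFrame,
    dv: str = "proportion",
    within: tuple[str, str] = ("condition", "image"),
    subject: str = "participant",
) -> AnovaResult:
    """Two-way fully-within-subject ANOVA (any a x b layout, one value per
    cell per subject; named for the study's 2-condition x 10-image design).

    Each effect is tested against its own effect-by-subject interaction
    (uncorrected, central-F p values; with a 2-level factor sphericity is
    moot for that factor). Partial eta squared is
    ``SS_effect / (SS_effect + SS_error)``.
    """
    a_f, b_f = within
    cols = [subject, a_f, b_f, dv]
    miss = [c for c in cols if c not in table.columns]
    if miss:
        raise BalanceError(f"table missing columns {miss}")
    t = table[cols].dropna()
    subjects = sorted(t[subject].unique())
    a_levels = sorted(t[a_f].unique())
    b_levels = sorted(t[b_f].unique())
    n, a, b = len(subjects), len(a_levels), len(b_levels)
    if n < 2 or a < 2 or b < 2:
        raise BalanceError("need >= 2 subjects and >= 2 levels per factor")
    # pivot to a dense (subject, a, b) cube; any hole -> unbalanced
    cube = np.full((n, a, b), np.nan)
    idx = {
        (s, x, y): (i, j, k)
        for i, s in enumerate(subjects)
        for j, x in enumerate(a_levels)
        for k, y in enumerate(b_levels)
    }
    for row in t.itertuples(index=False):
        key = (getattr(row, subject), getattr(row, a_f), getattr(row, b_f))
        i, j, k = idx[key]
        if not np.isnan(cube[i, j, k]):
            raise BalanceError(f"duplicate cell {key}")
        cube[i, j, k] = getattr(row, dv)
    if np.isnan(cube).any():
        holes = int(np.isnan(cube).sum())
        raise BalanceError(f"{holes} missing design cells (no imputation)")

    grand = cube.mean()
    m_s = cube.mean(axis=(1, 2))          # subject means
    m_a = cube.mean(axis=(0, 2))
    m_b = cube.mean(axis=(0, 1))
    m_ab = cube.mean(axis=0)              # (a, b)
    m_sa = cube.mean(axis=2)              # (n, a)
    m_sb = cube.mean(axis=1)              # (n, b)

    ss_subj = a * b * np.sum((m_s - grand) ** 2)
    ss_a = n * b * np.sum((m_a - grand) ** 2)
    ss_b = n * a * np.sum((m_b - grand) ** 2)
    ss_ab = n * np.sum(
        (m_ab - m_a[:, None] - m_b[None, :] + grand) ** 2)
    ss_sa = b * np.sum(
        (m_sa - m_s[:, None] - m_a[None, :] + grand) ** 2)
    ss_sb = a * np.sum(
        (m_sb - m_s[:, None] - m_b[None, :] + grand) ** 2)
    ss_total = np.sum((cube - grand) ** 2)
    ss_sab = ss_total - ss_subj - ss_a - ss_b - ss_ab - ss_sa - ss_sb

    tiny = 1e-12 * max(1.0, float(ss_total))  # numerical-zero threshold

    def effect(ss, df, err_ss, err_df) -> EffectResult:
        ms, err_ms = ss / df, err_ss / err_df
        f = ms / err_ms if err_ms > tiny / err_df else 0.0
        p = float(stats.f.sf(f, df, err_df)) if f > 0 else 1.0
        denom = ss + err_ss
        eta = ss / denom if denom > tiny else 0.0
        return EffectResult(float(ss), df, float(ms), float(f), p,
                            float(eta), float(err_ss), err_df)

    effects = {
        a_f: effect(ss_a, a - 1, ss_sa, (a - 1) * (n - 1)),
        b_f: effect(ss_b, b - 1, ss_sb, (b - 1) * (n - 1)),
        f"{a_f}:{b_f}": effect(ss_ab, (a - 1) * (b - 1), ss_sab,
                               (a - 1) * (b - 1) * (n - 1)),
    }
    return AnovaResult(n_subjects=n, effects=effects,
                       ss_total=float(ss_total), ss_subject=float(ss_subj))


@dataclass(frozen=True)
class PowerSpec:
    """One-group repeated-measures ANOVA power settings.

    ``eta_sq`` is the (partial) eta-squared effect size; ``corr`` the
    assumed average correlation among repeated measures; ``epsilon`` the
    nonsphericity correction. ``effect_size_convention`` selects how the
    noncentrality parameter treats the correlation:

    * ``"spss"`` (default): the entered eta squared is SPSS-style partial
      eta squared, which already absorbs the within-subject error
      reduction, giving lambda = f^2 * n * m * eps / (1 - corr)^2.
    * ``"gpower"``: classic G*Power-3.0-style f, giving
      lambda = f^2 * n * m * eps / (1 - corr).
    """

    eta_sq: float = 0.14
    alpha: float = 0.05
    target_power: float = 0.8
    n_measurements: int = 4
    corr: float = 0.5
    epsilon: float = 1.0
    effect_size_convention: str = "spss"

    def __post_init__(self) -> None:
        if not (0 < self.eta_sq < 1):
            raise ValueError("eta_sq must lie in (0, 1)")
        if not (0 < self.alpha < 1) or not (0 < self.target_power < 1):
            raise ValueError("alpha and target_power must lie in (0, 1)")
        if not (0 < self.corr < 1):
            raise ValueError("corr must lie in (0, 1)")
        if not (0 < self.epsilon <= 1):
            raise ValueError("epsilon must lie in (0, 1]")
        if self.effect_size_convention not in {"spss", "gpower"}:
            raise ValueError("convention must be 'spss' or 'gpower'")


def rm_anova_power(spec: PowerSpec, n: int) -> float:
    """Power of the one-group within-subjects F test at sample size n,
    via the noncentral F distribution."""
    f2 = spec.eta_sq / (1.0 - spec.eta_sq)
    denom = (1.0 - spec.corr) ** (
        2 if spec.effect_size_convention == "spss" else 1)
    lam = f2 * n * spec.n_measurements * spec.epsilon / denom
    df1 = (spec.n_measurements - 1) * spec.epsilon
    df2 = (n - 1) * df1
    fcrit = stats.f.ppf(1.0 - spec.alpha, df1, df2)
    return float(stats.ncf.sf(fcrit, df1, df2, lam))


def required_sample_size(spec: PowerSpec, n_max: int = 10_000) -> int:
    """Smallest n >= 2 whose power meets ``spec.target_power``."""
    for n in range(2, n_max + 1):
        if rm_anova_power(spec, n) >= spec.target_power:
            return n
    raise ValueError(
        f"power {spec.target_power} not attainable within n <= {n_max}"
    )
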