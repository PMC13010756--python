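"""Fixation records, datasets, and delimited-text I/O.

The atomic observation is a fixation: one period of stable gaze, located in
image-frame pixel coordinates, belonging to one trial. A trial is one
2-second presentation of one image to one participant under one condition
(with repetitions), holding an ordered list of fixations.

A :class:`GazeDataset` wraps a validated pandas DataFrame of fixations plus
the screen geometry and per-image stimulus frames. Fixations landing
outside the image raster are retained (column ``in_image`` is False) but
excluded from map rendering and ROI counts downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple

import numpy as np
import pandas as pd

from .geometry import ScreenGeometry, StimulusFrame

logger = logging.getLogger(__name__)

#: canonical column order for fixation tables on disk
FIXATION_COLUMNS = [
    "participant",
    "image",
    "condition",
    "repetition",
    "index",
    "x",
    "y",
    "duration_ms",
    "onset_ms",
]

TRIAL_KEY = ["participant", "image", "condition", "repetition"]


class SchemaError(ValueError):
    """A fixation table does not match the expected schema."""


class IntegrityError(ValueError):
    """Duplicate or inconsistent records in a fixation table."""


class Fixation(NamedTuple):
    """One fixation in image-frame pixel coordinates."""

    participant: str
    image: str
    condition: str
    repetition: int
    index: int
    x: float
    y: float
    duration_ms: float = 0.0
    onset_ms: float = 0.0


@dataclass
class GazeDataset:
    """Validated collection of fixations with geometry and frames.

    ``fixations`` has the columns of :data:`FIXATION_COLUMNS` plus a boolean
    ``in_image`` flag; coordinates are image-frame pixels.
    """

    fixations: pd.DataFrame
    geometry: ScreenGeometry
    frames: dict[str, StimulusFrame]

    def __post_init__(self) -> None:
        df = self.fixations
        missing = [c for c in FIXATION_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"fixation table missing columns: {missing}")
        if not np.isfinite(df[["x", "y"]].to_numpy(dtype=float)).all():
            raise IntegrityError("non-finite fixation coordinates")
        if (df["duration_ms"] < 0).any() or (df["onset_ms"] < 0).any():
            raise IntegrityError("negative duration or onset")
        if (df["repetition"] < 1).any() or (df["index"] < 1).any():
            raise IntegrityError("repetition and index must be >= 1")
        dup = df.duplicated(subset=TRIAL_KEY + ["index"])
        if dup.any():
            raise IntegrityError(
                f"{int(dup.sum())} duplicate (participant,image,condition,"
                "repetition,index) rows"
            )
        unknown = set(df["image"].unique()) - set(self.frames)
        if unknown:
            raise SchemaError(f"images without a stimulus frame: {sorted(unknown)}")
        for frame in self.frames.values():
            frame.validate_on_screen(self.geometry)
        # within-trial ordering: indices strictly increasing per trial
        if not df.groupby(TRIAL_KEY, sort=False, observed=True)["index"].apply(
            lambda s: bool(s.is_monotonic_increasing and s.is_unique)
        ).all():
            raise IntegrityError("within-trial fixation indices must strictly increase")
        self.fixations = df.assign(in_image=self._in_image_mask(df)).reset_index(
            drop=True
        )
        n_out = int((~self.fixations["in_image"]).sum())
        if n_out:
            logger.info("%d fixations fall outside their image raster", n_out)

    def _in_image_mask(self, df: pd.DataFrame) -> np.ndarray:
        mask = np.zeros(len(df), dtype=bool)
        for image_id, idx in df.groupby("image", observed=True).groups.items():
            w, h = self.frames[image_id].size_px
            sub = df.loc[idx]
            mask[df.index.get_indexer(idx)] = (
                (sub["x"] >= 0) & (sub["x"] < w) & (sub["y"] >= 0) & (sub["y"] < h)
            ).to_numpy()
        return mask

    # -- accessors ---------------------------------------------------------

    @property
    def conditions(self) -> list[str]:
        return sorted(self.fixations["condition"].unique())

    @property
    def images(self) -> list[str]:
        return sorted(self.frames)

    def trial_keys(self, image_id: str | None = None) -> list[tuple]:
        """Distinct (participant, image, condition, repetition) keys."""
        df = self.fixations
        if image_id is not None:
            df = df[df["image"] == image_id]
        return sorted(map(tuple, df[TRIAL_KEY].drop_duplicates().to_numpy()))

    def trial_fixations(self, key: tuple, in_image_only: bool = True) -> pd.DataFrame:
        p, im, c, r = key
        df = self.fixations
        sel = (
            (df["participant"] == p)
            & (df["image"] == im)
            & (df["condition"] == c)
            & (df["repetition"] == r)
        )
        out = df[sel]
        if in_image_only:
            out = out[out["in_image"]]
        return out.sort_values("index")

    def iter_fixations(self, image_id: str) -> Iterable[Fixation]:
        df = self.fixations
        for row in df[df["image"] == image_id].itertuples(index=False):
            yield Fixation(
                row.participant, row.image, row.condition, int(row.repetition),
                int(row.index), float(row.x), float(row.y),
                float(row.duration_ms), float(row.onset_ms),
            )


def read_fixation_table(
    path: str | Path,
    geometry: ScreenGeometry,
    frames: Mapping[str, StimulusFrame],
    coordinate_frame: str = "image",
    delimiter: str | None = None,
) -> GazeDataset:
    """Read a delimited fixation table into a :class:`GazeDataset`.

    Parameters
    ----------
    coordinate_frame
        ``"image"`` if x/y are already image-frame pixels; ``"screen"`` if
        they are screen pixels, in which case each image's
        ``screen_offset_px`` is subtracted.
    delimiter
        Field delimiter; inferred from the extension when None
        (.tsv -> tab, otherwise comma).
    """
    path = Path(path)
    if delimiter is None:
        delimiter = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    df = pd.read_csv(path, sep=delimiter)
    missing = [c for c in FIXATION_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    df = df[FIXATION_COLUMNS].copy()
    df["participant"] = df["participant"].astype(str)
    df["image"] = df["image"].astype(str)
    df["condition"] = df["condition"].astype(str)
    if coordinate_frame not in {"image", "screen"}:
        raise SchemaError(f"unknown coordinate_frame {coordinate_frame!r}")
    if coordinate_frame == "screen":
        for image_id, idx in df.groupby("image", observed=True).groups.items():
            if image_id not in frames:
                raise SchemaError(f"image {image_id!r} has no stimulus frame")
            ox, oy = frames[image_id].screen_offset_px
            df.loc[idx, "x"] = df.loc[idx, "x"] - ox
            df.loc[idx, "y"] = df.loc[idx, "y"] - oy
    bad = ~np.isfinite(df[["x", "y"]].to_numpy(dtype=float)).all(axis=1)
    if bad.any():
        logger.warning("%s: dropping %d rows with non-finite coordinates",
                       path, int(bad.sum()))
        df = df[~bad]
    return GazeDataset(df, geometry, dict(frames))


def write_fixation_table(
    dataset: GazeDataset, path: str | Path, delimiter: str | None = None
) -> None:
    """Write the dataset back to delimited text (image-frame coordinates)."""
    path = Path(path)
    if delimiter is None:
        delimiter = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    dataset.fixations[FIXATION_COLUMNS].to_csv(path, sep=delimiter, index=False)


def dataset_census(dataset: GazeDataset) -> pd.DataFrame:
    """Repetition and fixation counts per (participant, image, condition).

    Returns a DataFrame with one row per design cell and columns
    ``n_repetitions`` / ``n_fixations``; ``census.attrs["n_trials"]`` holds
    the total trial count (distinct trial keys). Use it to verify design
    completeness before trial-held-out splitting.
    """
    df = dataset.fixations
    if df.empty:
        out = pd.DataFrame(
            columns=["participant", "image", "condition", "n_repetitions",
                     "n_fixations"]
        )
        out.attrs["n_trials"] = 0
        return out
    grouped = df.groupby(["participant", "image", "condition"], observed=True)
    out = grouped.agg(
        n_repetitions=("repetition", "nunique"), n_fixations=("x", "size")
    ).reset_index()
    out.attrs["n_trials"] = int(
        df[TRIAL_KEY].drop_duplicates().shape[0]
    )
    return out
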