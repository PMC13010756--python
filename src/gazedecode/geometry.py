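"""Screen geometry and pixel <-> degrees-of-visual-angle conversion.

Gaze coordinates are recorded in screen pixels, but all perceptually
meaningful quantities (smoothing bandwidth, ROI margins, calibration error)
are stated in degrees of visual angle (dva). The conversion depends on the
viewing distance and the physical pixel pitch of the display.

Conventions: pixel coordinates are 0-based with the origin at the top-left,
x increasing rightward and y increasing downward; pixel (i, j) covers the
half-open square [j, j+1) x [i, i+1). The dva conversion uses a single
symmetric tan(1 deg) factor centred on the line of sight; the
eccentricity-dependent magnification across a desktop display is below 1%
and is ignored.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field


class GeometryError(ValueError):
    """Raised when a screen/stimulus geometry is invalid."""


@dataclass(frozen=True)
class ScreenGeometry:
    """Physical viewing geometry of the display.

    Parameters
    ----------
    viewing_distance_cm
        Eye-to-screen distance in centimetres (chinrest distance).
    screen_px
        Display resolution as ``(width, height)`` in pixels.
    screen_cm
        Physical display size as ``(width, height)`` in centimetres.
        Horizontal and vertical pixel pitch may differ.
    """

    viewing_distance_cm: float
    screen_px: tuple[int, int]
    screen_cm: tuple[float, float]

    def __post_init__(self) -> None:
        vals = (self.viewing_distance_cm, *self.screen_px, *self.screen_cm)
        if not all(math.isfinite(v) and v > 0 for v in vals):
            raise GeometryError(
                "all geometry fields must be strictly positive and finite; "
                f"got distance={self.viewing_distance_cm}, "
                f"screen_px={self.screen_px}, screen_cm={self.screen_cm}"
            )

    @classmethod
    def from_diagonal(
        cls,
        viewing_distance_cm: float,
        screen_px: tuple[int, int],
        diagonal_inch: float,
    ) -> "ScreenGeometry":
        """Derive the physical size from a diagonal (e.g. a "24-inch" monitor),
        assuming square pixels so the aspect ratio follows the resolution."""
        w_px, h_px = screen_px
        diag_cm = diagonal_inch * 2.54
        aspect = math.hypot(w_px, h_px)
        return cls(
            viewing_distance_cm,
            screen_px,
            (diag_cm * w_px / aspect, diag_cm * h_px / aspect),
        )


@dataclass(frozen=True)
class StimulusFrame:
    """Placement of a stimulus image on the screen.

    ``screen_offset_px`` is the screen-pixel position of the image's
    top-left corner; images presented centrally on a larger screen have a
    positive offset.
    """

    image_id: str
    size_px: tuple[int, int]
    screen_offset_px: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if not all(s > 0 for s in self.size_px):
            raise GeometryError(f"image size must be positive, got {self.size_px}")

    def validate_on_screen(self, geometry: ScreenGeometry) -> None:
        for off, size, screen in zip(
            self.screen_offset_px, self.size_px, geometry.screen_px
        ):
            if off < 0 or off + size > screen:
                raise GeometryError(
                    f"image {self.image_id!r} (offset {self.screen_offset_px}, "
                    f"size {self.size_px}) does not fit on screen {geometry.screen_px}"
                )

    def to_image_frame(self, x_screen, y_screen):
        """Translate screen-frame coordinates into the image frame."""
        return (
            x_screen - self.screen_offset_px[0],
            y_screen - self.screen_offset_px[1],
        )

    def to_screen_frame(self, x_image, y_image):
        return (
            x_image + self.screen_offset_px[0],
            y_image + self.screen_offset_px[1],
        )


def px_per_dva(geometry: ScreenGeometry) -> tuple[float, float]:
    """Pixels subtended by one degree of visual angle, per axis.

    Computed as ``distance_cm * tan(1 deg) * (screen_px / screen_cm)``:
    the physical extent of 1 dva at the screen plane times the pixel
    density of each axis.

    Returns
    -------
    (px_per_dva_x, px_per_dva_y)
    """
    extent_cm = geometry.viewing_distance_cm * math.tan(math.radians(1.0))
    out = (
        extent_cm * geometry.screen_px[0] / geometry.screen_cm[0],
        extent_cm * geometry.screen_px[1] / geometry.screen_cm[1],
    )
    if not all(math.isfinite(v) and v > 0 for v in out):
        raise GeometryError(f"degenerate px/dva {out} for {geometry}")
    return out


def mean_px_per_dva(geometry: ScreenGeometry) -> float:
    """Scalar px/dva (arithmetic mean of the two axes), used where an
    isotropic quantity such as a disc radius is required."""
    px, py = px_per_dva(geometry)
    return 0.5 * (px + py)
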