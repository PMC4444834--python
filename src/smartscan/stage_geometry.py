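"""Coordinate frames linking mosaic pixel space to physical stage space.

The search mosaic is analysed in pixel coordinates; the microscope stage is
driven in micrometres.  A :class:`MosaicFrame` is the affine link between the
two: a stage-space origin (the centre of pixel ``(0, 0)``), an isotropic pixel
size, and a sign capturing whether pixel row index increases with stage Y
(vendors disagree on the Y direction).

Changing objective lenses between the low-resolution search scan and the
high-resolution second scan shifts the optical centre by a fixed, per-objective
translation (paracentricity).  Each :class:`ObjectiveProfile` records that
offset relative to one declared reference objective, and
:func:`apply_paracentricity` converts stage targets between objectives so the
re-acquired field stays centred on the detected object.

Conventions: pixel indices are 0-based, a pixel coordinate refers to the pixel
*centre* (sub-pixel centroids are meaningful), and stage X increases rightward.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "StagePoint",
    "ObjectiveProfile",
    "MosaicFrame",
    "pixel_to_stage",
    "stage_to_pixel",
    "apply_paracentricity",
]


@dataclass(frozen=True)
class StagePoint:
    """A physical stage position in micrometres."""

    x: float
    y: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValueError(f"StagePoint coordinates must be finite, got ({self.x}, {self.y})")


@dataclass(frozen=True)
class ObjectiveProfile:
    """An objective lens: magnification, native field of view, and paracentricity offset.

    ``fov_width``/``fov_height`` are the field of view in µm at zoom 1.
    ``paracentricity_dx``/``dy`` are the translation (µm) of this objective's
    optical centre relative to the declared reference objective, whose own
    offset is (0, 0) by definition.
    """

    name: str
    magnification: float
    fov_width: float
    fov_height: float
    paracentricity_dx: float = 0.0
    paracentricity_dy: float = 0.0

    def __post_init__(self) -> None:
        if self.magnification <= 0:
            raise ValueError(f"magnification must be > 0, got {self.magnification}")
        if self.fov_width <= 0 or self.fov_height <= 0:
            raise ValueError(
                f"field of view must be positive, got {self.fov_width} x {self.fov_height}"
            )


@dataclass(frozen=True)
class MosaicFrame:
    """Affine frame mapping mosaic pixel indices to stage micrometres.

    ``origin`` is the stage position of the centre of pixel ``(col=0, row=0)``;
    ``pixel_size`` is µm per pixel (isotropic); ``y_axis_sign`` is +1 when the
    pixel row index increases with stage Y and -1 otherwise.
    """

    origin: StagePoint
    pixel_size: float
    y_axis_sign: int = 1

    def __post_init__(self) -> None:
        if not (math.isfinite(self.pixel_size) and self.pixel_size > 0):
            raise ValueError(f"pixel_size must be a positive finite number, got {self.pixel_size}")
        if self.y_axis_sign not in (1, -1):
            raise ValueError(f"y_axis_sign must be +1 or -1, got {self.y_axis_sign}")


def pixel_to_stage(frame: MosaicFrame, col: float, row: float) -> StagePoint:
    """Map a (possibly fractional) pixel coordinate to a stage position.

    ``x = origin.x + col * pixel_size``; ``y = origin.y + y_axis_sign * row * pixel_size``.
    """
    if not (math.isfinite(col) and math.isfinite(row)):
        raise ValueError(f"pixel coordinates must be finite, got ({col}, {row})")
    return StagePoint(
        x=frame.origin.x + col * frame.pixel_size,
        y=frame.origin.y + frame.y_axis_sign * row * frame.pixel_size,
    )


def stage_to_pixel(frame: MosaicFrame, point: StagePoint) -> tuple[float, float]:
    """Map a stage position to continuous (col, row) pixel coordinates.

    Exact inverse of :func:`pixel_to_stage`.
    """
    col = (point.x - frame.origin.x) / frame.pixel_size
    row = (point.y - frame.origin.y) / (frame.y_axis_sign * frame.pixel_size)
    return col, row


def apply_paracentricity(
    point: StagePoint, from_obj: ObjectiveProfile, to_obj: ObjectiveProfile
) -> StagePoint:
    """Translate a stage target when switching objectives.

    Both profiles must declare their offsets against the same reference
    objective; the correction is then the difference of the two offsets, so
    corrections compose additively (A->B then B->C equals A->C) and A->B
    followed by B->A is the identity.
    """
    return StagePoint(
        x=point.x + (to_obj.paracentricity_dx - from_obj.paracentricity_dx),
        y=point.y + (to_obj.paracentricity_dy - from_obj.paracentricity_dy),
    )
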