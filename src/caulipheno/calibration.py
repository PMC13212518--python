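"""Pixel-to-physical scale calibration.

A top-view camera at fixed height images a reference ruler placed at canopy
level; the ruler's known length over its pixel span gives a pixel-to-length
coefficient (cm/px) per camera height, and its square gives the
pixel-to-area coefficient (cm²/px).  Under the pinhole model the
coefficients at two heights are related by the ratio of object distances,
but only the empirically calibrated coefficients are used for conversion.

The acquisition protocol images at 1.5 m early on and raises the camera to
2.2 m after day 70; :class:`CalibrationSet` encodes that switch rule for
records that carry a day but no explicit height.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

__all__ = [
    "CalibrationProfile",
    "CalibrationSet",
    "calibrate_from_ruler",
    "pixels_to_area",
    "pixels_to_length",
    "CalibrationError",
]


class CalibrationError(LookupError):
    """No calibration available for the requested camera height."""


@dataclass(frozen=True)
class CalibrationProfile:
    """Scale coefficients for one camera height.

    ``pixel_to_area`` is always the square of ``pixel_to_length`` — areas
    scale with the square of the linear magnification.
    """

    camera_height: float  # m
    pixel_to_length: float  # cm per pixel
    object_distance: float | None = None  # u, m
    image_distance: float | None = None  # v, m

    def __post_init__(self):
        if not self.pixel_to_length > 0:
            raise ValueError("pixel_to_length must be positive")
        if not self.camera_height > 0:
            raise ValueError("camera_height must be positive")

    @property
    def pixel_to_area(self) -> float:
        """cm² per pixel."""
        return self.pixel_to_length ** 2


def calibrate_from_ruler(
    ruler_length: float,
    ruler_pixel_span: float,
    camera_height: float,
) -> CalibrationProfile:
    """Calibration from a ruler of known length imaged at canopy level.

    Parameters
    ----------
    ruler_length
        Physical ruler length in cm.
    ruler_pixel_span
        The ruler's extent in the image, in pixels.
    """
    if ruler_length <= 0 or ruler_pixel_span <= 0:
        raise ValueError("ruler length and pixel span must be positive")
    return CalibrationProfile(
        camera_height=camera_height,
        pixel_to_length=ruler_length / ruler_pixel_span,
    )


def pixels_to_area(pixel_area: float, profile: CalibrationProfile) -> float:
    """Convert a segmented pixel count to physical area (cm²)."""
    if pixel_area < 0:
        raise ValueError("pixel area cannot be negative")
    return float(pixel_area) * profile.pixel_to_area


def pixels_to_length(pixel_span: float, profile: CalibrationProfile) -> float:
    """Convert a pixel span to physical length (cm)."""
    if pixel_span < 0:
        raise ValueError("pixel span cannot be negative")
    return float(pixel_span) * profile.pixel_to_length


@dataclass(frozen=True)
class CalibrationSet:
    """Camera-height -> profile lookup with the day-70 height-switch rule."""

    profiles: Mapping[float, CalibrationProfile]
    height_switch_day: float = 70.0
    early_height: float = 1.5
    late_height: float = 2.2

    def for_height(self, camera_height: float) -> CalibrationProfile:
        for h, prof in self.profiles.items():
            if abs(h - camera_height) < 1e-9:
                return prof
        raise CalibrationError(
            f"no calibration for camera height {camera_height} m "
            f"(available: {sorted(self.profiles)})"
        )

    def for_record(self, camera_height: float | None = None,
                   day: float | None = None) -> CalibrationProfile:
        """Profile for a record, preferring its explicit camera height.

        Without a height, the acquisition day selects the early (<= switch
        day) or late (> switch day) height.  Missing both is an error —
        silent fallback would corrupt every downstream area.
        """
        if camera_height is not None:
            return self.for_height(camera_height)
        if day is None:
            raise CalibrationError("record has neither camera height nor day")
        height = self.early_height if day <= self.height_switch_day else self.late_height
        return self.for_height(height)
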