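"""Label-mask measurement and filename conventions.

Segmentation output is consumed as integer-coded label masks (0 background,
1 plant, 2 curd) or as instance CSVs.  Measurement is deliberately simple:
per class, the pixel count and the tight bounding box of all its pixels
(multiple disjoint components of one class are merged — the acquisition
design has a single plant per image).  Bounding boxes are 0-based,
half-open ``(x, y, width, height)`` with origin at the top-left.

Image files follow the "X-Y-YYYY-MM-DD-number" convention, where X-Y is the
row-column position (the plant identity) and number the acquisition index.
"""

from __future__ import annotations

import datetime as _dt
import re
from dataclasses import dataclass

import numpy as np

from .calibration import CalibrationProfile, pixels_to_length

__all__ = [
    "InstanceRecord",
    "BoundingBox",
    "ParsedFilename",
    "extract_instances",
    "bbox_to_dimensions",
    "parse_filename",
    "format_filename",
    "PLANT_CODE",
    "CURD_CODE",
    "CLASS_NAMES",
]

PLANT_CODE = 1
CURD_CODE = 2
CLASS_NAMES = {PLANT_CODE: "plant", CURD_CODE: "curd"}


@dataclass(frozen=True)
class BoundingBox:
    """0-based half-open pixel box (x, y, width, height), origin top-left."""

    x: int
    y: int
    width: int
    height: int

    def __post_init__(self):
        if self.width < 0 or self.height < 0:
            raise ValueError("bounding box sides cannot be negative")

    @property
    def area(self) -> int:
        return self.width * self.height

    def translate(self, dx: int, dy: int) -> "BoundingBox":
        return BoundingBox(self.x + dx, self.y + dy, self.width, self.height)


@dataclass(frozen=True)
class InstanceRecord:
    """One segmented instance of a plant or curd."""

    plant_id: str
    class_label: str  # "plant" | "curd"
    pixel_area: int
    bbox: BoundingBox
    date: _dt.date | None = None
    day: float | None = None
    camera_height: float | None = None
    acquisition_index: int | None = None

    def __post_init__(self):
        if self.pixel_area <= 0:
            raise ValueError("pixel_area must be positive")
        if self.pixel_area > self.bbox.area:
            raise ValueError("pixel_area cannot exceed the bounding-box area")


def extract_instances(
    label_mask: np.ndarray,
    plant_id: str = "",
    date: _dt.date | None = None,
    day: float | None = None,
    camera_height: float | None = None,
) -> list[InstanceRecord]:
    """Measure a label mask: one record per class present.

    Per class the record holds the total pixel count and the tight bounding
    box of all pixels of that class.  Unknown codes are rejected.
    """
    mask = np.asarray(label_mask)
    codes = set(np.unique(mask).tolist())
    unknown = codes - {0, PLANT_CODE, CURD_CODE}
    if unknown:
        raise ValueError(f"unknown label codes in mask: {sorted(unknown)}")
    records = []
    for code in (PLANT_CODE, CURD_CODE):
        where = mask == code
        count = int(where.sum())
        if count == 0:
            continue
        rows, cols = np.nonzero(where)
        bbox = BoundingBox(
            x=int(cols.min()),
            y=int(rows.min()),
            width=int(cols.max() - cols.min() + 1),
            height=int(rows.max() - rows.min() + 1),
        )
        records.append(
            InstanceRecord(
                plant_id=plant_id,
                class_label=CLASS_NAMES[code],
                pixel_area=count,
                bbox=bbox,
                date=date,
                day=day,
                camera_height=camera_height,
            )
        )
    return records


def bbox_to_dimensions(
    record: InstanceRecord,
    profile: CalibrationProfile,
) -> dict[str, float]:
    """Convert a bounding box to physical dimensions (cm).

    The reported canopy-width / curd-diameter value is the mean of the two
    converted box sides, which is rotation-robust for near-circular organs;
    both sides and the long side are exposed alongside it.
    """
    if record.bbox.width == 0 or record.bbox.height == 0:
        raise ValueError("degenerate (zero-sized) bounding box")
    side_x = pixels_to_length(record.bbox.width, profile)
    side_y = pixels_to_length(record.bbox.height, profile)
    return {
        "value": 0.5 * (side_x + side_y),
        "side_x": side_x,
        "side_y": side_y,
        "max_side": max(side_x, side_y),
    }


@dataclass(frozen=True)
class ParsedFilename:
    row: int
    col: int
    date: _dt.date
    acquisition_index: int

    @property
    def plant_id(self) -> str:
        return f"{self.row}-{self.col}"


_NAME_RE = re.compile(
    r"^(?P<row>\d+)-(?P<col>\d+)-(?P<year>\d{4})-(?P<month>\d{2})-(?P<day>\d{2})"
    r"-(?P<index>\d+)$"
)


def parse_filename(name: str) -> ParsedFilename:
    """Parse the "X-Y-YYYY-MM-DD-number" image-name convention."""
    stem = name.rsplit(".", 1)[0] if name.endswith((".png", ".PNG")) else name
    m = _NAME_RE.match(stem)
    if not m:
        raise ValueError(
            f"filename {name!r} does not match the 'X-Y-YYYY-MM-DD-number' convention"
        )
    try:
        date = _dt.date(int(m["year"]), int(m["month"]), int(m["day"]))
    except ValueError as exc:
        raise ValueError(f"filename {name!r} has an invalid date: {exc}") from exc
    return ParsedFilename(int(m["row"]), int(m["col"]), date, int(m["index"]))


def format_filename(parsed: ParsedFilename) -> str:
    """Inverse of :func:`parse_filename` (without extension)."""
    return (
        f"{parsed.row}-{parsed.col}-{parsed.date.isoformat()}-{parsed.acquisition_index}"
    )
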