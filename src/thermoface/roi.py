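"""Facial regions of interest (ROIs) and their geometry.

Eleven square ROIs are placed on the face, five of them bilateral pairs
about a vertical facial symmetry axis (procerus/nose line):

====  =========================  ==========================
name  region                     side, fraction of face width
====  =========================  ==========================
LF    forehead, left side        14.28 %
RF    forehead, right side       14.28 %
LPO   periorbital, left          3.24 %
RPO   periorbital, right         3.24 %
TN    tip of nose                6.49 %
LC    cheek, left                9.74 %
RC    cheek, right               9.74 %
LPN   perinasal, left            3.24 %
RPN   perinasal, right           3.24 %
LCh   chin, left side            5.19 %
RCh   chin, right side           5.19 %
====  =========================  ==========================

The canonical ROI order above matters: the consecutive-difference
features (f8..f14) subtract features of ROI k−1 from ROI k in this
order.  Coordinates are 0-based, row-major, boxes half-open on
bottom/right.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

ROI_NAMES: tuple[str, ...] = (
    "LF", "RF", "LPO", "RPO", "TN", "LC", "RC", "LPN", "RPN", "LCh", "RCh",
)

#: side of each square ROI as a fraction of the face width
ROI_PROPORTIONS: dict[str, float] = {
    "LF": 0.1428, "RF": 0.1428,
    "LPO": 0.0324, "RPO": 0.0324,
    "TN": 0.0649,
    "LC": 0.0974, "RC": 0.0974,
    "LPN": 0.0324, "RPN": 0.0324,
    "LCh": 0.0519, "RCh": 0.0519,
}

#: (left, right) bilateral pairs, with a human-readable region name
BILATERAL_PAIRS: tuple[tuple[str, str, str], ...] = (
    ("LF", "RF", "forehead"),
    ("LPO", "RPO", "periorbital"),
    ("LC", "RC", "cheek"),
    ("LPN", "RPN", "perinasal"),
    ("LCh", "RCh", "chin"),
)


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


@dataclass(frozen=True)
class ROIBox:
    """An axis-aligned square ROI inside a frame (half-open box)."""

    name: str
    top_row: int
    left_col: int
    height: int
    width: int

    @property
    def bottom_row(self) -> int:
        return self.top_row + self.height

    @property
    def right_col(self) -> int:
        return self.left_col + self.width

    @property
    def slices(self) -> tuple[slice, slice]:
        return (slice(self.top_row, self.bottom_row),
                slice(self.left_col, self.right_col))

    def shifted(self, dr: int, dc: int) -> "ROIBox":
        return ROIBox(self.name, self.top_row + dr, self.left_col + dc,
                      self.height, self.width)

    def inside(self, top: int, bottom: int, left: int, right: int) -> bool:
        return (self.top_row >= top and self.bottom_row <= bottom
                and self.left_col >= left and self.right_col <= right)


@dataclass
class ROISet:
    """The 11 named ROI boxes of one frame plus the facial symmetry axis."""

    boxes: tuple[ROIBox, ...]
    symmetry_col: float
    flagged: bool = False
    _by_name: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        names = [b.name for b in self.boxes]
        if tuple(names) != ROI_NAMES:
            raise ValueError(
                f"ROISet requires the 11 canonical ROIs in order {ROI_NAMES}, "
                f"got {tuple(names)}")
        self._by_name = {b.name: b for b in self.boxes}

    def __getitem__(self, name: str) -> ROIBox:
        return self._by_name[name]

    def __iter__(self):
        return iter(self.boxes)

    def geometry_key(self) -> tuple:
        """Hashable key identifying the box placement (for frame grouping)."""
        return tuple((b.top_row, b.left_col, b.height, b.width)
                     for b in self.boxes)

    def shifted(self, dr: int, dc: int, flagged: bool | None = None) -> "ROISet":
        return ROISet(tuple(b.shifted(dr, dc) for b in self.boxes),
                      self.symmetry_col + dc,
                      self.flagged if flagged is None else flagged)


def build_roi_set(
    face_width: float,
    seeds: Mapping[str, tuple[float, float]],
    symmetry_col: float,
    *,
    crop_bounds: tuple[int, int, int, int] | None = None,
    strict: bool = False,
) -> ROISet:
    """Build the 11 square ROIs from first-frame seed centers.

    Each box is a square of side ``round(proportion * face_width)``
    (half-up, minimum 1 px) centered on its seed ``(row, col)``.  Seeds
    may be fractional: an even-sided square can only be centred exactly
    on a half-integer coordinate.

    Parameters
    ----------
    face_width
        Width of the face in pixels (the bounding-box width), the unit
        for the fixed ROI proportions.
    seeds
        Mapping from each of the 11 ROI names to its center (row, col).
    symmetry_col
        Column of the vertical facial symmetry axis.
    crop_bounds
        Optional (top, bottom, left, right) half-open bounds the boxes
        must lie in; violations are clipped with a warning, or raise in
        ``strict`` mode.
    """
    if face_width < 1:
        raise ValueError(f"face_width must be >= 1, got {face_width}")
    extra = set(seeds) - set(ROI_NAMES)
    missing = set(ROI_NAMES) - set(seeds)
    if extra:
        raise ValueError(f"unknown ROI name(s) in seeds: {sorted(extra)}; "
                         f"valid names are {ROI_NAMES}")
    if missing:
        raise ValueError(f"missing ROI seed(s): {sorted(missing)}")

    boxes = []
    for name in ROI_NAMES:
        side = max(1, _round_half_up(ROI_PROPORTIONS[name] * face_width))
        row, col = seeds[name]
        top = _round_half_up(row - (side - 1) / 2.0)
        left = _round_half_up(col - (side - 1) / 2.0)
        box = ROIBox(name, top, left, side, side)
        if crop_bounds is not None:
            t, b, l, r = crop_bounds
            if not box.inside(t, b, l, r):
                if strict:
                    raise ValueError(
                        f"ROI {name} box {box} leaves crop bounds {crop_bounds}")
                warnings.warn(f"ROI {name} clipped to crop bounds", stacklevel=2)
                top2 = min(max(box.top_row, t), b - 1)
                left2 = min(max(box.left_col, l), r - 1)
                h = max(1, min(box.bottom_row, b) - top2)
                w = max(1, min(box.right_col, r) - left2)
                box = ROIBox(name, top2, left2, h, w)
        boxes.append(box)
    return ROISet(tuple(boxes), float(symmetry_col))


def propagate_rois(
    roi_set: ROISet,
    face_boxes: Sequence,
    frame_shape: tuple[int, int] | None = None,
) -> list[ROISet]:
    """Propagate a first-frame ROISet across frames by face-box translation.

    The per-frame offset is the translation of the face box's top-left
    corner relative to the first frame; ROI sizes never change.  A frame
    whose shifted ROIs would leave its face box (or the frame) is
    *flagged* rather than clipped, mimicking manual discard of badly
    placed frames.
    """
    if len(face_boxes) == 0:
        raise ValueError("need at least one face box")
    ref = face_boxes[0]
    out: list[ROISet] = []
    for fb in face_boxes:
        dr = fb.top_row - ref.top_row
        dc = fb.left_col - ref.left_col
        shifted = roi_set.shifted(dr, dc)
        ok = all(b.inside(fb.top_row, fb.bottom_row, fb.left_col, fb.right_col)
                 for b in shifted.boxes)
        if ok and frame_shape is not None:
            h, w = frame_shape
            ok = all(b.inside(0, h, 0, w) for b in shifted.boxes)
        out.append(shifted if ok else
                   roi_set.shifted(dr, dc, flagged=True))
    return out


def extract_roi_pixels(frame: np.ndarray, box: ROIBox) -> np.ndarray:
    """Copy the pixel grid under an ROI box; rejects out-of-bounds boxes."""
    h, w = frame.shape
    if not (0 <= box.top_row < box.bottom_row <= h
            and 0 <= box.left_col < box.right_col <= w):
        raise ValueError(f"ROI box {box} out of bounds for frame {frame.shape}")
    return frame[box.slices].copy()
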