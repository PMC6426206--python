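"""Frame pre-processing: denoising, binarization and face localisation.

The face is the bright (high-emissivity) blob on a dark background.
Each frame is median- and Gaussian-filtered, thresholded to black and
white, cleaned of small connected components, and the face bounding box
is derived from the mask extrema: the uppermost white pixel gives the
top of the head, the leftmost/rightmost white pixels in a horizontal
band around the mask centroid give the lateral limits, and the bottom
is inferred proportionally from the top-to-centroid distance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.morphology import remove_small_objects


@dataclass(frozen=True)
class FaceBox:
    """Half-open face bounding box (0-based pixel indices)."""

    top_row: int
    bottom_row: int
    left_col: int
    right_col: int

    def __post_init__(self) -> None:
        if not (self.top_row < self.bottom_row and self.left_col < self.right_col):
            raise ValueError(f"degenerate FaceBox {self}")

    @property
    def height(self) -> int:
        return self.bottom_row - self.top_row

    @property
    def width(self) -> int:
        return self.right_col - self.left_col

    @property
    def bounds(self) -> tuple[int, int, int, int]:
        return (self.top_row, self.bottom_row, self.left_col, self.right_col)


def denoise(frame: np.ndarray, median_size: int = 3,
            gaussian_sigma: float = 1.0) -> np.ndarray:
    """Median then Gaussian filtering; edge handling by replication.

    ``median_size=1`` and ``gaussian_sigma=0`` each disable their stage,
    so that combination is the identity.  Integer frames are rounded and
    clipped back to their dtype range after the Gaussian stage.
    """
    if median_size < 1 or median_size % 2 == 0:
        raise ValueError(f"median_size must be odd and >= 1, got {median_size}")
    if gaussian_sigma < 0:
        raise ValueError(f"gaussian_sigma must be >= 0, got {gaussian_sigma}")
    out = np.asarray(frame)
    integer = np.issubdtype(out.dtype, np.integer)
    dtype = out.dtype
    if median_size > 1:
        out = ndimage.median_filter(out, size=median_size, mode="nearest")
    if gaussian_sigma > 0:
        out = ndimage.gaussian_filter(out.astype(np.float64), gaussian_sigma,
                                      mode="nearest")
        if integer:
            info = np.iinfo(dtype)
            out = np.clip(np.rint(out), info.min, info.max).astype(dtype)
    if out is frame:
        out = frame.copy()
    return out


def binarize(frame: np.ndarray, threshold: float | None = None) -> np.ndarray:
    """Threshold a grayscale frame into a boolean foreground mask.

    With ``threshold=None`` Otsu's method picks the threshold; pixels
    strictly above it are foreground.  The face must be *lighter* than
    the background (higher emissivity): on an inverted frame the mask
    will be the background, which is the caller's responsibility.
    """
    frame = np.asarray(frame)
    if frame.size == 0:
        raise ValueError("empty frame")
    if threshold is None:
        if frame.min() == frame.max():
            raise ValueError("constant frame: no separable foreground for Otsu")
        threshold = threshold_otsu(frame)
    return frame > threshold


def remove_small_components(mask: np.ndarray, min_pixels: int) -> np.ndarray:
    """Delete 8-connected components smaller than ``min_pixels``."""
    if min_pixels < 0:
        raise ValueError(f"min_pixels must be >= 0, got {min_pixels}")
    mask = np.asarray(mask, dtype=bool)
    if min_pixels <= 1:
        return mask.copy()
    # max_size semantics: components of size <= max_size are removed,
    # so surviving components have >= min_pixels pixels
    return remove_small_objects(mask, max_size=min_pixels - 1, connectivity=2)


def detect_face_box(mask: np.ndarray, bottom_factor: float = 2.0,
                    band_frac: float = 0.10) -> FaceBox:
    """Derive the face bounding box from a binary mask.

    top    = uppermost foreground row;
    left / right = extreme foreground columns within a horizontal band of
    half-width ``band_frac * mask height`` around the centroid row;
    bottom = top + round(bottom_factor * (centroid_row - top)),
    clipped to the frame.
    """
    mask = np.asarray(mask, dtype=bool)
    rows, cols = np.nonzero(mask)
    if rows.size == 0:
        raise ValueError("empty mask: no foreground to locate a face in")
    h = mask.shape[0]
    top = int(rows.min())
    centroid_row = float(rows.mean())
    half = band_frac * h
    in_band = np.abs(rows - centroid_row) <= half
    band_cols = cols[in_band] if in_band.any() else cols
    left = int(band_cols.min())
    right = int(band_cols.max()) + 1
    bottom = top + int(np.floor(bottom_factor * (centroid_row - top) + 0.5))
    bottom = min(h, max(bottom, top + 1))
    box = FaceBox(top, bottom, left, right)
    if box.height == 1 or box.width == 1:
        warnings.warn("degenerate face box (1 px extent)", stacklevel=2)
    return box


def crop_face(frame: np.ndarray, box: FaceBox) -> np.ndarray:
    """Copy the face region out of the frame (values unchanged)."""
    h, w = frame.shape
    if not (0 <= box.top_row and box.bottom_row <= h
            and 0 <= box.left_col and box.right_col <= w):
        raise ValueError(f"face box {box} out of bounds for frame {frame.shape}")
    return frame[box.top_row:box.bottom_row, box.left_col:box.right_col].copy()


def preprocess_frame(frame: np.ndarray, *, median_size: int = 3,
                     gaussian_sigma: float = 1.0, min_component: int = 50,
                     bottom_factor: float = 2.0, band_frac: float = 0.10,
                     threshold: float | None = None) -> FaceBox:
    """Full single-frame pipeline: denoise -> binarize -> clean -> face box."""
    den = denoise(frame, median_size, gaussian_sigma)
    mask = binarize(den, threshold)
    mask = remove_small_components(mask, min_component)
    return detect_face_box(mask, bottom_factor, band_frac)


def detect_session_boxes(frames: np.ndarray | Sequence[np.ndarray],
                         **params) -> list[FaceBox]:
    """Run :func:`preprocess_frame` over every frame of a session."""
    return [preprocess_frame(np.asarray(f), **params) for f in frames]
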