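"""Per-ROI emissivity features and the 154-feature frame vector.

Seven base statistics are computed from each ROI's pixel grid R (m x n,
intensities 0-255):

    f1  grand mean of all pixels
    f2  overall sample variance, denominator m*n - 1
    f3  mean over rows of the per-row sample variance (denominator n - 1)
    f4  mean over columns of the per-column sample variance (denominator m - 1)
    f5  median of all pixels
    f6  mean of the per-row medians
    f7  mean of the per-column medians

Seven more are consecutive-ROI differences in the canonical ROI order:
for ROI k >= 2, f(c+7)(k) = fc(k) - fc(k-1) for c = 1..7; the first
ROI's difference slots are 0 (the difference is undefined there, and
zero preserves the 11 x 14 = 154 vector length).  A ROI with a single
row (or column) has no per-column (per-row) dispersion; that variance
term is 0.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .roi import ROI_NAMES, ROISet

FEATURE_IDS: tuple[str, ...] = tuple(f"f{i}" for i in range(1, 15))
N_FEATURES: int = len(ROI_NAMES) * len(FEATURE_IDS)  # 154


def feature_names() -> list[str]:
    """Column names '<ROI>_<f#>' in canonical (ROI-major) order."""
    return [f"{roi}_{fid}" for roi in ROI_NAMES for fid in FEATURE_IDS]


def roi_features_stack(stack: np.ndarray) -> np.ndarray:
    """f1..f7 for a stack of ROI grids, shape (T, m, n) -> (T, 7)."""
    stack = np.asarray(stack, dtype=np.float64)
    if stack.ndim != 3 or stack.shape[1] < 1 or stack.shape[2] < 1:
        raise ValueError(f"expected a (T, m, n) stack, got shape {stack.shape}")
    t, m, n = stack.shape
    flat = stack.reshape(t, m * n)
    f1 = flat.mean(axis=1)
    f2 = flat.var(axis=1, ddof=1) if m * n > 1 else np.zeros(t)
    f3 = (stack.var(axis=2, ddof=1).mean(axis=1) if n > 1 else np.zeros(t))
    f4 = (stack.var(axis=1, ddof=1).mean(axis=1) if m > 1 else np.zeros(t))
    f5 = np.median(flat, axis=1)
    f6 = np.median(stack, axis=2).mean(axis=1)
    f7 = np.median(stack, axis=1).mean(axis=1)
    return np.column_stack([f1, f2, f3, f4, f5, f6, f7])


def roi_features(pixels: np.ndarray) -> np.ndarray:
    """f1..f7 of a single ROI grid (m x n) as a length-7 vector."""
    pixels = np.asarray(pixels)
    if pixels.ndim != 2 or pixels.size == 0:
        raise ValueError(f"expected a nonempty 2-D ROI grid, got shape {pixels.shape}")
    return roi_features_stack(pixels[None])[0]


def _assemble_vectors(base: np.ndarray) -> np.ndarray:
    """(T, 11, 7) base features -> (T, 154) with consecutive-ROI diffs."""
    t, k, _ = base.shape
    diffs = np.zeros_like(base)
    diffs[:, 1:, :] = base[:, 1:, :] - base[:, :-1, :]
    return np.concatenate([base, diffs], axis=2).reshape(t, k * 14)


def frame_features(frame: np.ndarray, rois: ROISet) -> np.ndarray:
    """The 154-feature vector of one frame given its placed ROISet."""
    if rois.flagged:
        raise ValueError("frame is flagged (ROI left the face crop); refused")
    frame = np.asarray(frame)
    base = np.stack([roi_features_stack(frame[box.slices][None])[0]
                     for box in rois.boxes])  # (11, 7)
    return _assemble_vectors(base[None])[0]


def segment_features(
    frames: np.ndarray | Sequence[np.ndarray],
    rois: ROISet | Sequence[ROISet],
    segments: pd.DataFrame,
) -> pd.DataFrame:
    """Labeled per-frame feature matrix for a session.

    Parameters
    ----------
    frames
        Frame stack (T, H, W) or sequence of frames.
    rois
        A single ROISet (static placement) or one per frame (from
        :func:`~thermoface.roi.propagate_rois`).  Flagged frames are
        dropped.
    segments
        Table with columns ``frame_start``, ``frame_end`` (half-open)
        and ``segment_name`` mapping frames to their segment label.

    Returns
    -------
    DataFrame with columns ``frame``, ``label`` and the 154 feature
    columns; one row per retained frame.  Frames outside every segment
    are excluded.
    """
    frames = np.asarray(frames)
    t = frames.shape[0]
    roi_list = [rois] * t if isinstance(rois, ROISet) else list(rois)
    if len(roi_list) != t:
        raise ValueError(f"{len(roi_list)} ROISets for {t} frames")

    labels = np.full(t, None, dtype=object)
    for _, row in segments.iterrows():
        labels[int(row.frame_start):int(row.frame_end)] = row.segment_name

    keep = np.array([labels[i] is not None and not roi_list[i].flagged
                     for i in range(t)])
    idx = np.nonzero(keep)[0]

    # group retained frames by identical ROI geometry so each group's
    # features can be computed with one vectorised pass per ROI
    vectors = np.empty((idx.size, N_FEATURES))
    groups: dict[tuple, list[int]] = {}
    for pos, i in enumerate(idx):
        groups.setdefault(roi_list[i].geometry_key(), []).append(pos)
    for key, positions in groups.items():
        sel = idx[positions]
        base = np.empty((sel.size, len(ROI_NAMES), 7))
        rset = roi_list[sel[0]]
        for j, box in enumerate(rset.boxes):
            base[:, j, :] = roi_features_stack(frames[sel][:, box.slices[0],
                                                           box.slices[1]])
        vectors[positions, :] = _assemble_vectors(base)

    out = pd.DataFrame(vectors, columns=feature_names())
    out.insert(0, "frame", idx)
    out.insert(1, "label", [labels[i] for i in idx])
    return out
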