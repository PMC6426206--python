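"""Session I/O and the end-to-end pipeline runner.

A session on disk is a directory of zero-padded 8-bit grayscale PNG (or
TIFF) frames plus three CSV tables:

    frame_00000.png ...        frames, index order = temporal order
    labels.csv                 frame_start, frame_end, segment_name
    roi_seeds.csv              roi_name, row, col   (first-frame centers)
    ground_truth.csv           emotion, roi_name, delta, onset_fraction
                               (synthetic sessions only)

``run_all`` chains preprocessing, ROI placement/propagation, feature
extraction, classification and the emissivity statistics, writing every
table plus a provenance record (package version, seed, config hash).
"""

from __future__ import annotations

import hashlib
import json
import re
from dataclasses import asdict, dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classify import PipelineResult, run_classification_pipeline
from .features import segment_features
from .preprocess import detect_session_boxes
from .roi import ROI_NAMES, build_roi_set, propagate_rois
from .stats import format_stats_summary, stats_report
from .synth import Session

_FRAME_RE = re.compile(r"frame_(\d+)\.(png|tif|tiff)$")


def write_session(session: Session, path: str | Path) -> Path:
    """Write a synthetic session to a directory (PNG frames + CSVs)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for i, frame in enumerate(session.frames):
        iio.imwrite(path / f"frame_{i:05d}.png", frame)
    session.segments.to_csv(path / "labels.csv", index=False)
    session.roi_seeds.to_csv(path / "roi_seeds.csv", index=False)
    session.ground_truth.to_csv(path / "ground_truth.csv", index=False)
    return path


def read_session(path: str | Path):
    """Read (frames, segments, roi_seeds) from a session directory.

    Frames must be 8-bit grayscale and contiguously numbered from 0.
    """
    path = Path(path)
    entries = []
    for p in path.iterdir():
        m = _FRAME_RE.match(p.name)
        if m:
            entries.append((int(m.group(1)), p))
    if not entries:
        raise FileNotFoundError(f"no frame_*.png/tif files in {path}")
    entries.sort()
    indices = [i for i, _ in entries]
    if indices != list(range(len(indices))):
        missing = sorted(set(range(indices[-1] + 1)) - set(indices))
        raise ValueError(f"gap in frame numbering; missing indices {missing[:10]}")
    frames = []
    for _, p in entries:
        img = iio.imread(p)
        if img.dtype != np.uint8:
            raise ValueError(f"{p.name}: expected 8-bit grayscale, got {img.dtype}")
        if img.ndim != 2:
            raise ValueError(f"{p.name}: expected a single-channel image")
        frames.append(img)
    segments = pd.read_csv(path / "labels.csv")
    roi_seeds = pd.read_csv(path / "roi_seeds.csv")
    return np.stack(frames), segments, roi_seeds


@dataclass
class PipelineConfig:
    """Parameters of the end-to-end run (paths + per-stage knobs)."""

    session_dir: str = ""
    out_dir: str = "thermoface_run"
    # preprocessing
    median_size: int = 3
    gaussian_sigma: float = 1.0
    min_component: int = 50
    bottom_factor: float = 2.0
    band_frac: float = 0.10
    detect_face: bool = True  # False: static ROIs straight from the seeds
    # selection / classification
    sigma: float = 1.0
    lam: float | None = None
    tau: float = 0.1
    k: int = 3
    seed: int = 0
    max_nca_samples: int = 200
    nca_max_iter: int = 50
    # statistics
    baseline_label: str = "baseline"
    baseline_family: int | None = None
    bilateral_family: int | None = None

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update(overrides)
        return cls(**data)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class RunBundle:
    features: pd.DataFrame
    result: PipelineResult
    stats_table: pd.DataFrame
    face_boxes: list = field(default_factory=list)
    provenance: dict = field(default_factory=dict)


def extract_session_features(frames: np.ndarray, segments: pd.DataFrame,
                             roi_seeds: pd.DataFrame,
                             config: PipelineConfig) -> tuple[pd.DataFrame, list]:
    """Preprocess + place/propagate ROIs + per-frame features."""
    seeds = {row.roi_name: (float(row.row), float(row.col))
             for row in roi_seeds.itertuples()}
    missing = set(ROI_NAMES) - set(seeds)
    if missing:
        raise ValueError(f"roi_seeds missing ROIs: {sorted(missing)}")
    symmetry_col = (seeds["TN"][1] if "TN" in seeds
                    else float(np.mean([c for _, c in seeds.values()])))
    face_boxes: list = []
    if config.detect_face:
        face_boxes = detect_session_boxes(
            frames, median_size=config.median_size,
            gaussian_sigma=config.gaussian_sigma,
            min_component=config.min_component,
            bottom_factor=config.bottom_factor, band_frac=config.band_frac)
        roi_set = build_roi_set(face_boxes[0].width, seeds, symmetry_col)
        frame_rois = propagate_rois(roi_set, face_boxes, frames.shape[1:])
        feats = segment_features(frames, frame_rois, segments)
    else:
        # static placement: face width from the seeds' horizontal extent
        width = max(c for _, c in seeds.values()) - min(
            c for _, c in seeds.values())
        roi_set = build_roi_set(max(1.0, width * 1.3), seeds, symmetry_col)
        feats = segment_features(frames, roi_set, segments)
    return feats, face_boxes


def run_all(config: PipelineConfig) -> RunBundle:
    """Execute the full pipeline on a session directory and write outputs."""
    frames, segments, roi_seeds = read_session(config.session_dir)
    feats, face_boxes = extract_session_features(frames, segments, roi_seeds,
                                                 config)
    result = run_classification_pipeline(
        feats, k=config.k, seed=config.seed, sigma=config.sigma,
        lam=config.lam, tau=config.tau,
        max_nca_samples=config.max_nca_samples,
        nca_max_iter=config.nca_max_iter,
        baseline_label=config.baseline_label)
    table = stats_report(feats, baseline_label=config.baseline_label,
                         baseline_family=config.baseline_family,
                         bilateral_family=config.bilateral_family)
    provenance = {
        "thermoface_version": __version__,
        "numpy_version": np.__version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "config": asdict(config),
        "n_frames": int(frames.shape[0]),
    }
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    feats.to_csv(out / "features.csv", index=False)
    table.to_csv(out / "stats_table.csv", index=False)
    result.frequency.to_csv(out / "selection_frequency.csv")
    pd.DataFrame(result.report.confusion, index=result.report.labels,
                 columns=result.report.labels).to_csv(out / "confusion_pooled.csv")
    report = {
        "accuracy": result.report.accuracy,
        "kappa": result.report.kappa,
        "per_class": result.report.per_class.to_dict(orient="index"),
        "fold_accuracies": [r.accuracy for r in result.fold_reports],
    }
    (out / "classification_report.json").write_text(
        json.dumps(report, indent=2))
    (out / "stats_summary.txt").write_text(format_stats_summary(table))
    (out / "provenance.json").write_text(json.dumps(provenance, indent=2))
    if face_boxes:
        pd.DataFrame([{"frame": i, "top": b.top_row, "bottom": b.bottom_row,
                       "left": b.left_col, "right": b.right_col}
                      for i, b in enumerate(face_boxes)]).to_csv(
            out / "face_boxes.csv", index=False)
    return RunBundle(features=feats, result=result, stats_table=table,
                     face_boxes=face_boxes, provenance=provenance)
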