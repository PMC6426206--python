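"""Synthetic thermal-video sessions with known ground truth.

The generator emulates the recording design the analysis pipeline is
built for: 8-bit grayscale frames (default 384 x 288 at 8.7 Hz) showing
a bright elliptical "face" on a dark background, a short neutral
baseline segment followed by one 30 s segment per emotion, and
ROI-localized, emotion-dependent emissivity offsets (optionally
left/right asymmetric) as the planted ground truth.  A companion
sampler produces SAM-style 1-9 valence/arousal self-report tables.

Everything is deterministic given (config, effects, seed): identical
inputs give bit-identical frames.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .roi import ROI_NAMES, ROISet, build_roi_set

DEFAULT_EMOTIONS: tuple[str, ...] = (
    "disgust", "fear", "happiness", "sadness", "surprise")


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


@dataclass(frozen=True)
class SessionConfig:
    """Geometry, timing and noise of one synthetic recording session."""

    frame_height: int = 288
    frame_width: int = 384
    fps: float = 8.7
    baseline_seconds: float = 3.0
    emotion_seconds: float = 30.0
    emotions: tuple[str, ...] = DEFAULT_EMOTIONS
    face_center: tuple[float, float] = (144.0, 192.0)  # (row, col)
    face_axes: tuple[float, float] = (110.0, 77.0)  # (semi-height, semi-width)
    background_level: int = 60
    face_level: int = 180
    noise_sd: float = 0.0
    drift_px_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ValueError(f"fps must be > 0, got {self.fps}")
        if not (0 <= self.background_level <= 255
                and 0 <= self.face_level <= 255):
            raise ValueError("intensity levels must lie in [0, 255]")
        if self.face_level <= self.background_level:
            raise ValueError("face_level must exceed background_level "
                             "(the face is the lighter region)")
        r0, c0 = self.face_center
        a, b = self.face_axes
        if (r0 - a < 0 or r0 + a >= self.frame_height
                or c0 - b < 0 or c0 + b >= self.frame_width):
            raise ValueError("face ellipse exceeds the frame bounds")
        if self.noise_sd < 0 or self.drift_px_sd < 0:
            raise ValueError("noise_sd and drift_px_sd must be >= 0")

    def scaled(self, factor: float) -> "SessionConfig":
        """Spatially scaled copy (same timing/noise); handy for small tests."""
        return replace(
            self,
            frame_height=max(8, _round_half_up(self.frame_height * factor)),
            frame_width=max(8, _round_half_up(self.frame_width * factor)),
            face_center=(self.face_center[0] * factor,
                         self.face_center[1] * factor),
            face_axes=(self.face_axes[0] * factor,
                       self.face_axes[1] * factor),
        )


@dataclass(frozen=True)
class EffectSpec:
    """A planted emissivity offset: ROI `roi_name` shifts by `delta`
    intensity units during `emotion`, from `onset_fraction` of the
    segment onward."""

    emotion: str
    roi_name: str
    delta: float
    onset_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.roi_name not in ROI_NAMES:
            raise ValueError(f"unknown ROI name {self.roi_name!r}; "
                             f"valid names are {ROI_NAMES}")
        if abs(self.delta) > 255:
            raise ValueError(f"|delta| must be <= 255, got {self.delta}")
        if not 0.0 <= self.onset_fraction <= 1.0:
            raise ValueError("onset_fraction must lie in [0, 1]")


@dataclass(frozen=True)
class SamProfile:
    """Per-emotion SAM valence/arousal means and SDs on the 1-9 scale."""

    valence_mean: Mapping[str, float]
    valence_sd: Mapping[str, float]
    arousal_mean: Mapping[str, float]
    arousal_sd: Mapping[str, float]

    def __post_init__(self) -> None:
        for means in (self.valence_mean, self.arousal_mean):
            for emotion, mu in means.items():
                if not 1.0 <= mu <= 9.0:
                    raise ValueError(
                        f"SAM mean for {emotion!r} must lie in [1, 9], got {mu}")
        for sds in (self.valence_sd, self.arousal_sd):
            for emotion, sd in sds.items():
                if sd < 0:
                    raise ValueError(f"SAM SD for {emotion!r} must be >= 0")


#: default SAM profile for the five emotions (child self-report scale)
DEFAULT_SAM_PROFILE = SamProfile(
    valence_mean={"disgust": 2.64, "fear": 2.96, "happiness": 8.68,
                  "sadness": 1.68, "surprise": 7.93},
    valence_sd={"disgust": 1.64, "fear": 1.69, "happiness": 0.82,
                "sadness": 1.44, "surprise": 1.49},
    arousal_mean={"disgust": 4.93, "fear": 5.71, "happiness": 5.36,
                  "sadness": 3.25, "surprise": 5.68},
    arousal_sd={"disgust": 2.69, "fear": 3.28, "happiness": 3.03,
                "sadness": 2.69, "surprise": 3.29},
)


def frame_schedule(config: SessionConfig) -> pd.DataFrame:
    """Segment table: baseline first, then each emotion, half-open ranges.

    Frames per segment = round(fps * seconds), half up.
    """
    rows = []
    start = 0
    segs = [("baseline", config.baseline_seconds)] + [
        (e, config.emotion_seconds) for e in config.emotions]
    for name, seconds in segs:
        n = _round_half_up(config.fps * seconds)
        rows.append({"frame_start": start, "frame_end": start + n,
                     "segment_name": name})
        start += n
    return pd.DataFrame(rows)


def face_mask(config: SessionConfig, dr: int = 0, dc: int = 0) -> np.ndarray:
    """Boolean mask of the (possibly shifted) face ellipse."""
    r0, c0 = config.face_center
    a, b = config.face_axes
    rr = np.arange(config.frame_height)[:, None] - (r0 + dr)
    cc = np.arange(config.frame_width)[None, :] - (c0 + dc)
    return (rr / a) ** 2 + (cc / b) ** 2 <= 1.0


def measured_face_width(config: SessionConfig) -> int:
    """Face-box width of the noiseless mask (detector convention)."""
    mask = face_mask(config)
    cols = np.nonzero(mask.any(axis=0))[0]
    return int(cols.max() - cols.min() + 1)


def default_roi_seeds(config: SessionConfig) -> dict[str, tuple[float, float]]:
    """Anatomically plausible ROI centers inside the face ellipse."""
    r0, c0 = config.face_center
    a, b = config.face_axes
    rel = {
        "LF": (-0.70, -0.30), "RF": (-0.70, +0.30),
        "LPO": (-0.25, -0.45), "RPO": (-0.25, +0.45),
        "TN": (+0.10, 0.0),
        "LC": (+0.30, -0.55), "RC": (+0.30, +0.55),
        "LPN": (+0.25, -0.20), "RPN": (+0.25, +0.20),
        "LCh": (+0.75, -0.15), "RCh": (+0.75, +0.15),
    }
    return {name: (r0 + fa * a, c0 + fb * b) for name, (fa, fb) in rel.items()}


def session_roi_set(config: SessionConfig,
                    seeds: Mapping[str, tuple[float, float]] | None = None
                    ) -> ROISet:
    """Ground-truth ROISet for the session (frame coordinates)."""
    seeds = default_roi_seeds(config) if seeds is None else dict(seeds)
    return build_roi_set(measured_face_width(config), seeds,
                         symmetry_col=config.face_center[1])


@dataclass
class Session:
    """A generated session: frames plus every table downstream stages need."""

    config: SessionConfig
    frames: np.ndarray  # (T, H, W) uint8
    segments: pd.DataFrame  # frame_start, frame_end, segment_name
    roi_seeds: pd.DataFrame  # roi_name, row, col
    ground_truth: pd.DataFrame  # emotion, roi_name, delta, onset_fraction
    roi_set: ROISet
    drift: np.ndarray = field(default=None)  # (T, 2) int offsets


def generate_session(config: SessionConfig,
                     effects: Sequence[EffectSpec] = (),
                     seeds: Mapping[str, tuple[float, float]] | None = None,
                     ) -> Session:
    """Render a full synthetic session.

    Frames are built as background + face ellipse at ``face_level``,
    ROI offsets added during their emotion segments, i.i.d. Gaussian
    noise of sd ``noise_sd`` added, then rounded and clipped to
    [0, 255] uint8.  ``drift_px_sd > 0`` jitters the face center (and
    ROIs/effects with it) by per-frame integer offsets.
    """
    for eff in effects:
        if eff.emotion not in config.emotions:
            raise ValueError(f"effect references unknown emotion "
                             f"{eff.emotion!r}; configured: {config.emotions}")
    seeds = default_roi_seeds(config) if seeds is None else dict(seeds)
    roi_set = build_roi_set(measured_face_width(config), seeds,
                            symmetry_col=config.face_center[1])
    segments = frame_schedule(config)
    t_total = int(segments["frame_end"].iloc[-1])
    h, w = config.frame_height, config.frame_width
    rng = np.random.default_rng(config.seed)

    # per-frame integer face jitter
    if config.drift_px_sd > 0:
        drift = np.rint(rng.normal(0.0, config.drift_px_sd,
                                   size=(t_total, 2))).astype(int)
    else:
        drift = np.zeros((t_total, 2), dtype=int)

    # segment-level effect map: segment -> list of (box, delta, onset frame)
    seg_effects: dict[str, list] = {}
    for eff in effects:
        seg_effects.setdefault(eff.emotion, []).append(eff)

    frames = np.empty((t_total, h, w), dtype=np.uint8)
    base_cache: dict[tuple, np.ndarray] = {}
    for _, seg in segments.iterrows():
        name = seg.segment_name
        start, end = int(seg.frame_start), int(seg.frame_end)
        seg_len = end - start
        active = seg_effects.get(name, [])
        for t in range(start, end):
            dr, dc = drift[t]
            key_effects = tuple(
                (e.roi_name, e.delta) for e in active
                if t - start >= int(np.floor(e.onset_fraction * seg_len)))
            key = (dr, dc, key_effects)
            base = base_cache.get(key)
            if base is None:
                base = np.full((h, w), float(config.background_level))
                base[face_mask(config, dr, dc)] = float(config.face_level)
                for roi_name, delta in key_effects:
                    box = roi_set[roi_name].shifted(dr, dc)
                    base[box.slices] += delta
                base_cache[key] = base
            if config.noise_sd > 0:
                frame = base + rng.normal(0.0, config.noise_sd, size=(h, w))
                frames[t] = np.clip(np.rint(frame), 0, 255).astype(np.uint8)
            else:
                q = base_cache.get(("u8",) + key)
                if q is None:
                    q = np.clip(np.rint(base), 0, 255).astype(np.uint8)
                    base_cache[("u8",) + key] = q
                frames[t] = q

    roi_seed_df = pd.DataFrame(
        [{"roi_name": n, "row": seeds[n][0], "col": seeds[n][1]}
         for n in ROI_NAMES])
    gt = pd.DataFrame(
        [{"emotion": e.emotion, "roi_name": e.roi_name, "delta": e.delta,
          "onset_fraction": e.onset_fraction} for e in effects],
        columns=["emotion", "roi_name", "delta", "onset_fraction"])
    return Session(config=config, frames=frames, segments=segments,
                   roi_seeds=roi_seed_df, ground_truth=gt,
                   roi_set=roi_set, drift=drift)


def example_effects(scale: float = 1.0,
                    emotions: Sequence[str] = DEFAULT_EMOTIONS
                    ) -> list[EffectSpec]:
    """A distinct, physiologically flavoured effect pattern per emotion.

    Nose/periorbital/perinasal/chin/forehead decrements and a divergent
    cheek pair (left increase, right decrease) give every emotion a
    separable ROI signature with |delta| >= 8*scale.
    """
    pattern = {
        "disgust": {"TN": -10, "LPN": -8, "RPN": -8, "LF": -8, "RF": -8,
                    "LPO": +8, "RPO": -8, "LC": +8, "RC": -8},
        "fear": {"TN": -12, "LC": +8, "RC": -8},
        "happiness": {"TN": -10, "LPO": -8, "RPO": -8, "LPN": -10,
                      "RPN": -10, "LCh": -8, "RCh": -8, "LC": +8, "RC": -8},
        "sadness": {"LPO": -8, "RPO": -8, "LCh": -10, "RCh": -10,
                    "LPN": +8, "RPN": -8, "LC": +8, "RC": -8},
        "surprise": {"LF": -8, "RF": -8, "LPO": -8, "RPO": -8, "TN": +10,
                     "LCh": -8, "RCh": -8, "LPN": +8, "RPN": -8,
                     "LC": +8, "RC": -8},
    }
    out = []
    for emotion in emotions:
        for roi_name, delta in pattern.get(emotion, {}).items():
            out.append(EffectSpec(emotion, roi_name, delta * scale))
    return out


def generate_sam_scores(n_children: int,
                        profile: SamProfile = DEFAULT_SAM_PROFILE,
                        seed: int = 0) -> pd.DataFrame:
    """Sample integer SAM scores: child x emotion x {valence, arousal}.

    Scores are truncated normals on [1, 9] with the profile's moments,
    rounded to integers (still within [1, 9]).  SD = 0 degenerates to
    the rounded mean.
    """
    if n_children < 1:
        raise ValueError("n_children must be >= 1")
    rng = np.random.default_rng(seed)
    emotions = sorted(profile.valence_mean)
    frames = []
    for emotion in emotions:
        rec = pd.DataFrame({"child": np.arange(n_children),
                            "emotion": emotion})
        for dim, means, sds in (
                ("valence", profile.valence_mean, profile.valence_sd),
                ("arousal", profile.arousal_mean, profile.arousal_sd)):
            mu, sd = means[emotion], sds[emotion]
            if sd == 0:
                x = np.full(n_children, mu)
            else:
                a, b = (1.0 - mu) / sd, (9.0 - mu) / sd
                x = truncnorm.rvs(a, b, loc=mu, scale=sd,
                                  size=n_children, random_state=rng)
            rec[dim] = np.clip(np.rint(x), 1, 9).astype(int)
        frames.append(rec)
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["child", "emotion"],
                           kind="stable").reset_index(drop=True)


def summarize_sam(scores: pd.DataFrame) -> pd.DataFrame:
    """Per-emotion mean and SD of valence and arousal."""
    return scores.groupby("emotion")[["valence", "arousal"]].agg(
        ["mean", "std"])
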