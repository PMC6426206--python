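"""Emissivity-variation statistics: baseline contrasts and facial asymmetry.

For each ROI and emotion the *emissivity variation* is the mean ROI
intensity (feature f1) during the emotion segment minus the baseline
mean.  Significance is assessed with a two-sample Student's t test on
log2-transformed intensities (log2(x + 1); pixel intensity 0 is legal)
with a Bonferroni correction over the contrast family: 55 tests for the
emotion-vs-baseline panel (11 ROIs x 5 emotions) and 25 for the
bilateral panel (5 pairs x 5 emotions).  Bilateral contrasts compare
left- and right-side variation series on the log2 scale, since raw
variations are signed.  Significance tiers follow the usual stars:
ns p > 0.05, * p <= 0.05, ** p <= 0.01, *** p <= 0.001 (adjusted p);
the thermal tendency is the sign of the mean variation when the
contrast is significant and "stable" otherwise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .roi import BILATERAL_PAIRS, ROI_NAMES

TIERS = ("ns", "*", "**", "***")


def tier_from_p(p_adj: float) -> str:
    if not np.isfinite(p_adj) or p_adj > 0.05:
        return "ns"
    if p_adj <= 0.001:
        return "***"
    if p_adj <= 0.01:
        return "**"
    return "*"


def emissivity_variation(emotion_f1: np.ndarray,
                         baseline_f1: np.ndarray) -> float:
    """mean(emotion f1) - mean(baseline f1), the per-ROI heat signature."""
    emotion_f1 = np.asarray(emotion_f1, dtype=np.float64)
    baseline_f1 = np.asarray(baseline_f1, dtype=np.float64)
    if emotion_f1.size == 0 or baseline_f1.size == 0:
        raise ValueError("empty f1 series")
    return float(emotion_f1.mean() - baseline_f1.mean())


def normality_check(values: np.ndarray) -> tuple[float, float]:
    """One-sample KS test against a normal with moment-estimated parameters."""
    values = np.asarray(values, dtype=np.float64)
    if values.size < 5:
        raise ValueError("need at least 5 values for the KS normality check")
    sd = values.std(ddof=1)
    if sd == 0:
        raise ValueError("zero-variance input: KS reference is undefined")
    res = sps.kstest(values, "norm", args=(values.mean(), sd))
    return float(res.statistic), float(res.pvalue)


def log2_transform(values: np.ndarray) -> np.ndarray:
    """log2(x + 1) on the 0-255 intensity scale (offset admits zeros)."""
    values = np.asarray(values, dtype=np.float64)
    if np.any(values + 1 <= 0):
        raise ValueError("log2 transform needs values > -1 (intensities >= 0)")
    return np.log2(values + 1.0)


def inverse_log2(values: np.ndarray) -> np.ndarray:
    return np.exp2(np.asarray(values, dtype=np.float64)) - 1.0


@dataclass(frozen=True)
class ContrastResult:
    t: float
    p_raw: float
    p_adj: float
    tier: str


def paired_contrast(a: np.ndarray, b: np.ndarray, family_size: int = 1,
                    *, pre_transformed: bool = False) -> ContrastResult:
    """Two-sample Student's t contrast with Bonferroni adjustment.

    By default both series are log2(x+1)-transformed first; pass
    ``pre_transformed=True`` for series already on the analysis scale
    (e.g. signed log-scale variation series).
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.size < 2 or b.size < 2:
        raise ValueError("need >= 2 values per series for a t test")
    if family_size < 1:
        raise ValueError("family_size must be >= 1")
    if not pre_transformed:
        a, b = log2_transform(a), log2_transform(b)
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        warnings.warn("zero pooled variance: t undefined, reported as ns",
                      stacklevel=2)
        return ContrastResult(np.nan, np.nan, np.nan, "ns")
    t, p = sps.ttest_ind(a, b, equal_var=True)
    p_adj = min(1.0, family_size * float(p))
    return ContrastResult(float(t), float(p), p_adj, tier_from_p(p_adj))


def _f1_series(features_df: pd.DataFrame, roi: str,
               label: str) -> np.ndarray:
    col = f"{roi}_f1"
    if col not in features_df.columns:
        raise ValueError(f"feature column {col!r} missing")
    vals = features_df.loc[features_df["label"] == label, col].to_numpy()
    if vals.size == 0:
        raise ValueError(f"no rows labeled {label!r}")
    return vals.astype(np.float64)


def baseline_contrast_table(
    features_df: pd.DataFrame,
    emotions: Sequence[str] | None = None,
    rois: Sequence[str] = ROI_NAMES,
    baseline_label: str = "baseline",
    family_size: int | None = None,
) -> pd.DataFrame:
    """Emotion-vs-baseline emissivity variation per ROI (one family).

    Returns one row per (emotion, ROI) with the raw-scale mean
    variation, t statistic, raw and Bonferroni-adjusted p, significance
    tier and tendency label.
    """
    if emotions is None:
        emotions = [l for l in pd.unique(features_df["label"])
                    if l != baseline_label]
    m = family_size if family_size is not None else len(emotions) * len(rois)
    rows = []
    for emotion in emotions:
        for roi in rois:
            emo = _f1_series(features_df, roi, emotion)
            base = _f1_series(features_df, roi, baseline_label)
            variation = emissivity_variation(emo, base)
            res = paired_contrast(emo, base, family_size=m)
            tendency = ("stable" if res.tier == "ns"
                        else ("increase" if variation > 0 else "decrease"))
            rows.append({"emotion": emotion, "roi": roi,
                         "contrast": "vs_baseline",
                         "mean_variation": variation, "t": res.t,
                         "p_raw": res.p_raw, "p_adj": res.p_adj,
                         "tier": res.tier, "tendency": tendency})
    return pd.DataFrame(rows)


def bilateral_analysis(
    features_df: pd.DataFrame,
    emotions: Sequence[str] | None = None,
    baseline_label: str = "baseline",
    family_size: int | None = None,
) -> pd.DataFrame:
    """Left-right asymmetry contrasts for the five bilateral ROI pairs.

    The tested quantity is the difference between the left and right
    variations: per frame the log-scale asymmetry s = log2(L f1 + 1) -
    log2(R f1 + 1) is formed, and the emotion-segment s series is
    contrasted against the baseline s series with a two-sample t,
    Bonferroni-corrected over the 25-test family (5 pairs x 5 emotions
    by default).  Referencing both segments to the same asymmetry
    series keeps the test calibrated: a static left-right offset or the
    sampling error of the baseline mean cancels instead of inflating
    the t statistic.  Per-side tendencies come from the raw-scale mean
    variation signs.
    """
    if emotions is None:
        emotions = [l for l in pd.unique(features_df["label"])
                    if l != baseline_label]
    m = (family_size if family_size is not None
         else len(emotions) * len(BILATERAL_PAIRS))
    rows = []
    for emotion in emotions:
        for left, right, region in BILATERAL_PAIRS:
            lt = log2_transform(_f1_series(features_df, left, emotion))
            lb = log2_transform(_f1_series(features_df, left, baseline_label))
            rt = log2_transform(_f1_series(features_df, right, emotion))
            rb = log2_transform(_f1_series(features_df, right, baseline_label))
            res = paired_contrast(lt - rt, lb - rb, family_size=m,
                                  pre_transformed=True)
            var_l = emissivity_variation(
                _f1_series(features_df, left, emotion),
                _f1_series(features_df, left, baseline_label))
            var_r = emissivity_variation(
                _f1_series(features_df, right, emotion),
                _f1_series(features_df, right, baseline_label))
            sig = res.tier != "ns"
            rows.append({
                "emotion": emotion, "roi": f"{left}/{right}",
                "region": region, "contrast": "bilateral",
                "mean_variation": var_l - var_r,
                "mean_variation_left": var_l,
                "mean_variation_right": var_r,
                "t": res.t, "p_raw": res.p_raw, "p_adj": res.p_adj,
                "tier": res.tier,
                "tendency_left": ("stable" if not sig else
                                  ("increase" if var_l > 0 else "decrease")),
                "tendency_right": ("stable" if not sig else
                                   ("increase" if var_r > 0 else "decrease")),
            })
    return pd.DataFrame(rows)


def stats_report(features_df: pd.DataFrame,
                 baseline_label: str = "baseline",
                 baseline_family: int | None = None,
                 bilateral_family: int | None = None) -> pd.DataFrame:
    """Both contrast families stacked into one emissivity-stats table."""
    vs = baseline_contrast_table(features_df, baseline_label=baseline_label,
                                 family_size=baseline_family)
    bi = bilateral_analysis(features_df, baseline_label=baseline_label,
                            family_size=bilateral_family)
    return pd.concat([vs, bi], ignore_index=True)


def format_stats_summary(table: pd.DataFrame) -> str:
    """Compact text panel of significance stars per ROI and emotion."""
    out = []
    for contrast in ("vs_baseline", "bilateral"):
        sub = table[table["contrast"] == contrast]
        if sub.empty:
            continue
        piv = sub.pivot(index="roi", columns="emotion", values="tier")
        out.append(f"[{contrast}]")
        out.append(piv.to_string())
    return "\n".join(out)
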