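# thermoface

Emotion analysis from facial infrared thermal imaging (IRTI).  The
package implements a complete pipeline for 8-bit grayscale thermal
video of a face — pixel intensity (0–255) is the *emissivity* proxy
for skin temperature, lighter = warmer:

1. **Preprocessing** — median + Gaussian denoising, Otsu binarization,
   small-component removal, and face bounding-box detection from the
   mask extrema (uppermost head pixel, lateral extrema near the
   centroid, proportionally inferred chin line).
2. **ROI geometry** — eleven square regions of interest (forehead,
   periorbital, nose tip, cheek, perinasal, chin; left/right where
   bilateral) sized by fixed fractions of the face width (nose 6.49 %,
   forehead 14.28 %, periorbital 3.24 %, cheek 9.74 %, perinasal
   3.24 %, chin 5.19 %), seeded on the first frame and propagated by
   the face-box translation.
3. **Features** — 14 statistics per ROI, 154 per frame: the grand mean
   f₁, overall sample variance f₂, means of per-row/per-column
   variances f₃/f₄, overall median f₅, means of per-row/per-column
   medians f₆/f₇, and the consecutive-ROI differences f₈–f₁₄.
4. **Feature selection** — diagonal, L2-regularized Neighborhood
   Component Analysis (NCA): weights wₗ maximize
   ξ(w) = Σᵢ pᵢ − λ Σₗ wₗ², where pᵢ = Σⱼ yᵢⱼ pᵢⱼ and
   pᵢⱼ ∝ exp(−d(xᵢ,xⱼ)/σ) with the weighted absolute-difference
   distance d(xᵢ,xⱼ) = Σₗ wₗ² |xᵢₗ − xⱼₗ|.  Features with
   wₗ > τ·max(w) are kept.
5. **Classification** — shared-covariance Linear Discriminant Analysis
   over five emotions (disgust, fear, happiness, sadness, surprise)
   under segment-wise 3-fold cross-validation, reporting per-class
   one-vs-rest accuracy/TPR/FPR, overall accuracy and Cohen's κ.
6. **Emissivity statistics** — per-ROI mean emissivity variation vs the
   neutral baseline and left/right bilateral asymmetry contrasts,
   tested with Student's t on log₂(x+1)-transformed intensities under
   Bonferroni correction (55- and 25-test families), with significance
   stars and increase/decrease/stable tendency labels.

Because the analysis is built for recordings that cannot be
redistributed, the package ships a first-class **synthetic session
generator**: 384×288 frames at 8.7 Hz, a bright elliptical face on a
dark background, a 3 s baseline segment plus 30 s per emotion, planted
per-ROI emissivity offsets (including left/right-asymmetric ones) as
ground truth, and a SAM-style 1–9 valence/arousal score sampler.
Every stage of the pipeline is validated by recovering those planted
parameters.

## Worked example

```python
import thermoface as tf

# a synthetic session: study timing, 1/3 spatial scale, noise sd 2,
# planted per-emotion ROI offsets of >= 8 intensity units
config = tf.SessionConfig(noise_sd=2.0, seed=0).scaled(1/3)
session = tf.generate_session(config, tf.example_effects())
features = tf.segment_features(session.frames, session.roi_set,
                               session.segments)

result = tf.run_classification_pipeline(features, k=3, seed=0)
print(result.report.summary())
```

```
overall accuracy: 1.0000   Cohen's kappa: 1.0000
           accuracy    tpr    fpr
disgust      1.0000 1.0000 0.0000
fear         1.0000 1.0000 0.0000
happiness    1.0000 1.0000 0.0000
sadness      1.0000 1.0000 0.0000
surprise     1.0000 1.0000 0.0000
```

At this signal-to-noise ratio (ROI offsets ≥ 8 intensity units against
ROI-mean noise well below 1 unit) the five emotions are perfectly
separable; the interesting checks are the chance-level behaviour of a
label-permuted control (≈ 0.20) and the statistics below.

```python
table = tf.stats_report(features)
print(table[(table.roi == "TN") & (table.emotion == "happiness")]
      [["emotion", "roi", "mean_variation", "p_adj", "tier", "tendency"]])
```

```
  emotion roi  mean_variation         p_adj tier tendency
happiness  TN      -10.053951 9.763035e-186  *** decrease
```

The planted −10 nose-tip decrement during happiness is recovered as a
mean emissivity variation of −10.05 with a *** (p ≤ 0.001,
Bonferroni-adjusted) significance tier, and the planted cheek
asymmetry (left +8, right −8) appears in the bilateral panel:

```
emotion   roi  mean_variation_left  mean_variation_right tier
   fear LC/RC             8.104533             -7.968724  ***
```

The same pipeline is scriptable from the shell:

```bash
thermoface simulate --out sess/ --seed 1 --scale 0.3
thermoface features --session sess/ --out features.csv
thermoface classify --features features.csv --k 3 --seed 0
thermoface stats --features features.csv
thermoface run-all --session sess/ --out run/
```

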