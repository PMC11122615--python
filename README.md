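# fafseg

Ambiguity-aware evaluation and prediction tools for lesion segmentation in
retinal fundus autofluorescence (FAF) imaging.

Hyperfluorescent (HF) lesions in FAF images of central serous
chorioretinopathy have unsharp borders, and experienced graders disagree
about them in two qualitatively different ways: they draw the *outline* of
an agreed lesion differently (edge errors), or they disagree about a lesion
*being there at all* (area errors). A plain Dice score conflates the two.
This package provides, for researchers working on segmentation quality and
inter-rater agreement:

- **Error-decomposed Dice.** Given two binary masks, every disagreeing
  pixel in FP ∪ FN is classified by its Euclidean distance to the nearest
  mutually agreed (TP) pixel: within a tolerance μ_EE it is an edge error
  (EE), beyond it an area error (AE), with the distance set to the image
  diagonal when TP = ∅. The adjusted score
  `DcS_AE = 2|TP| / (2|TP| + |AE|) ≥ DcS` forgives border placement, and
  `mDcS_AE = mean over μ_EE ∈ {0,…,100}` removes the dependence on any
  single tolerance.
- **Ternary maps and metrics.** Pixels are labeled confident lesion (C),
  potential lesion (P), or background (B) — from an ensemble's mean and
  variance maps (high variance ⇒ P; otherwise mean > μ_mean ⇒ C), from a
  single probability map (p ≥ μ_C ⇒ C, p ≤ μ_P ⇒ B), or from a
  multi-rater stack by rater count (≥ μ_aC raters ⇒ C, ≥ μ_aP ⇒ P). Six
  agreement metrics (strict and lenient precision/recall over the C and
  C ∪ P regions, plus their Dice) compare predicted and annotated ternary
  maps; empty-region denominators yield explicit nulls, never zeros.
- **Bagged ensembles with a pluggable member contract** plus a fast
  intensity-calibration baseline (CLAHE → median filter → center crop →
  per-intensity HF probability p(I)), aggregated into per-pixel mean and
  variance maps.
- **Diversity-based sub-ensemble selection.** Pairwise member distances
  (mean MSE between probability maps over a validation set, no ground
  truth needed) feed the maximum diversity problem; solvers: exhaustive
  enumeration, a seeded genetic algorithm with local-search polish, and
  score-based n-best / n-steps baselines.
- **A synthetic FAF scene generator** (bright HF blobs, dark
  reduced-autofluorescence patches and optic disc on textured background)
  with simulated multi-rater annotations whose disagreement decomposes
  into controllable edge jitter and component drops, so every stage runs
  and is testable without clinical data.

## Worked example

```python
import numpy as np
from fafseg import (generate_scene, simulate_expert_annotations, dice,
                    mean_dice_ae, ae_ratio_curve, run_synthetic_ensemble_study)

scene = generate_scene(width=256, height=256, n_hf_components=3,
                       n_ra_components=1, seed=7)
stack = simulate_expert_annotations(scene, n_experts=5, edge_jitter_px=3,
                                    area_disagreement_prob=0.3, seed=8)

pair = stack[0], stack[1]
print(f"rater 1 vs rater 2:  DcS = {dice(*pair):.3f}   mDcSAE = {mean_dice_ae(*pair):.3f}")
curve = ae_ratio_curve(stack, thresholds=np.arange(0, 51))
print(f"AE fraction at mu_EE = 0/10/50 px: {curve[0]:.2f} / {curve[10]:.2f} / {curve[50]:.2f}")

study = run_synthetic_ensemble_study(n_scenes=10, k_members=10, scene_size=160, seed=3)
print(f"ensemble variance inside contested components: {study.var_in_dropped:.4f}")
print(f"ensemble variance inside anchor components:    {study.var_in_anchor:.4f}")
```

prints

```
rater 1 vs rater 2:  DcS = 0.696   mDcSAE = 0.942
AE fraction at mu_EE = 0/10/50 px: 1.00 / 0.29 / 0.00
ensemble variance inside contested components: 0.0247
ensemble variance inside anchor components:    0.0119
```

Two raters who only disagree about borders and one faint lesion score a
mediocre Dice of 0.70, but the tolerance-averaged mDcSAE of 0.94 reveals
that almost all of the disagreement is border placement: by a 10 px
tolerance only 29 % of the disagreeing pixels remain area errors, and by
50 px none do. In the ensemble study, prediction variance concentrates in
the components some raters dropped (2× the variance inside the anchor
lesions every rater annotated) — the signal the ternary "potential" class
is built from.

## Command line

Every stage is exposed as a subcommand of `fafseg`:
`simulate`, `align`, `fit-baseline`, `predict`, `aggregate`, `ternary`,
`evaluate`, `select-subensemble`, `report`. For example:

```bash
fafseg simulate --seed 7 --n-experts 5 --out scene/
fafseg ternary --annotation scene/expert_0.png --annotation scene/expert_1.png \
       --annotation scene/expert_2.png --annotation scene/expert_3.png \
       --annotation scene/expert_4.png --out annot.png
fafseg evaluate --task segmentation --pred scene/expert_0.png --ref scene/expert_1.png
```

Masks are 0/255 single-channel rasters, ternary maps 0/128/255, thresholds
live in a YAML config (see `fafseg.config.MetricConfig` for names and
defaults), and runs with the same seed and config produce byte-identical
artifacts.

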