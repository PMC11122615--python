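# Methods

This note documents the models and conventions implemented in `fafseg`,
the default parameter values and why they were chosen, what the synthetic
data generator does and does not emulate, and the design choices made
where more than one reasonable option existed.

## Segmentation agreement with an edge/area decomposition

Two binary masks on one grid are compared by treating the first as
prediction and the second as reference; every quantity is symmetric under
swapping the two (FP and FN trade places). The Dice score is
`DcS = 2|TP| / (2|TP| + |FP| + |FN|)`, defined as 1.0 when both masks are
empty (perfect agreement on absence); reports flag such pairs.

The disagreeing set FP ∪ FN is partitioned by an exact Euclidean distance
transform seeded at the TP pixels: a disagreeing pixel with distance
≤ μ_EE is an **edge error**, otherwise an **area error**. The inclusive
comparison matters: a pixel at distance exactly μ_EE is an edge error.
When TP is empty the distance of every disagreeing pixel is defined as
the image diagonal √(W² + H²), so any disagreement between
non-overlapping masks is an area error under every practical tolerance.
An exact transform (not a chamfer approximation) keeps the ≤ comparison
unambiguous.

The adjusted score `DcS_AE(μ_EE) = 2|TP| / (2|TP| + |AE|)` is
non-decreasing in μ_EE, equals DcS at μ_EE = 0 and never falls below it.
Because the choice of μ_EE is the sensitive part, the headline statistic
is the mean over the integer lattice μ_EE ∈ {0, 1, …, μ_EEmax} (default
μ_EEmax = 100 px, i.e. 101 equally spaced tolerances). The
implementation computes the distance transform once per pair and derives
all thresholds from the sorted error distances, which is algebraically
identical to recomputing the partition per threshold.

The area-error fraction curve |AE| / (|FP| + |FN|) as a function of μ_EE,
averaged over all rater pairs of an annotation stack (pairs without any
disagreement are excluded; a mean over zero pairs is returned as an empty
curve), summarizes *why* raters disagree: a curve that decays to zero by
small tolerances indicates border jitter; a persistent floor indicates
genuine presence/absence disputes. Pairs with no mutual overlap
contribute a fraction of 1 at every tolerance below the diagonal — their
disagreement is an area error by default.

The thresholded-mean form is the only one implemented; reformulating the
mean as a per-pixel linear weighting of FP/FN distances would be
equivalent but is not exposed.

## Ternary maps

Pixels carry one of three labels: background B = 0, potential P = 1,
confident C = 2 (stored as uint8; on disk 0/128/255). Three constructions:

- **mean + variance** (ensembles): `var ≥ μ_var ⇒ P`; otherwise
  `mean > μ_mean ⇒ C`, else B. High variance takes precedence even at
  near-zero mean: disagreement among members is precisely what the
  potential class encodes, and the rule stays well defined in the corner
  the diagrammatic definition leaves open. The mean comparison is strict
  so that with μ_mean = 0.2 strictly more than a fifth of the ensemble
  mass is required for a confident call.
- **single probability map**: `p ≥ μ_C ⇒ C`, `p ≤ μ_P ⇒ B`, else P
  (inclusive at both thresholds). A hard 0/1 annotation therefore never
  produces potential pixels.
- **annotation stack**: with per-pixel rater count c, `c ≥ μ_aC ⇒ C`,
  `μ_aP ≤ c < μ_aC ⇒ P`, else B. With one rater and both thresholds 1
  this reduces exactly to the single-annotation behavior (no P).

Defaults: μ_mean = 0.2, μ_var = 0.1, μ_C = 0.9, μ_P = 0.1, μ_aC = 5,
μ_aP = 2 (five raters: confident requires unanimity; two raters guard
against single-rater slips). All are configurable through
`MetricConfig` / the YAML config.

### Ternary metrics

With predC/predP and annotC/annotP the label regions of prediction and
annotation:

1. `precision_C = |predC ∩ annotC| / |predC|` — confident output is
   definitely right;
2. `recall_CP = |(predC ∪ predP) ∩ (annotC ∪ annotP)| / |annotC ∪ annotP|`
   — no annotated lesion is missed;
3. `precision_C→CP = |predC ∩ (annotC ∪ annotP)| / |predC|` — confident
   output is at least not definitely wrong;
4. `recall_CP→C = |(predC ∪ predP) ∩ annotC| / |annotC|` — no confident
   annotation is missed;
5. `precision_CP = |(predC ∪ predP) ∩ (annotC ∪ annotP)| / |predC ∪ predP|`;
6. `DcS_CP` = harmonic mean of (5) and (2).

Any empty denominator region makes the metric **undefined**; undefined
values propagate as null through serialization and are excluded from
aggregates (which also report how many entries were defined). They are
never coerced to 0. If (5) and (2) are both defined and both 0, (6) is
defined as 0. The degenerate prediction that labels every pixel P games
(2) and (4) to 1 while (1) and (3) become undefined — which is why (5)
and (6) are part of the suite. Edge/area decomposition is not computed
for ternary maps.

## Annotation alignment

Fine pixel-accurate annotations are made comparable to coarse ones by
morphological closing with a 15 × 15 square structuring element (the
literal reading of a "15 × 15 pixels kernel"; the shape is configurable
only through the kernel size). The mask is zero-padded before the
dilate/erode pair so the image border cannot generate spurious
foreground. Closing is extensive and idempotent. HF and RA are closed
independently and any pixel then claimed by both is assigned to HF.
Whether conflicts should be resolved between the two closings instead is
unobservable from the end state; close-both-then-resolve is the simpler
composition.

## Intensity-calibration baseline

Preprocessing: CLAHE (scikit-image `equalize_adapthist`; default clip
limit 0.01 in its histogram-fraction units, tile grid 8 × 8 via
`kernel_size = min_side / 8`), then a median filter (default 5 px), then
a center crop (default 768 → 700 px, removing the fuzzy 34 px FAF
border; `crop_to=None` disables cropping for inputs without such a
border, e.g. synthetic scenes). For each 8-bit intensity I the
calibration counts occurrences and HF-mask hits over the training set and
stores `p(I) = hf / occ` (0 for unseen intensities). Prediction marks
pixels with `p(I) ≥ μ_HE` (default 0.07) inside the crop and re-embeds
the result into the original frame with the cropped border as background,
so all downstream metrics operate in one coordinate frame (row-major,
origin top-left). p(I) is always fitted on pixels preprocessed with the
configured parameters — calibration and prediction see the same
representation.

## Bagged ensembles

Members implement `fit(images, masks) → state` and
`predict(image) → probability map`; prediction is deterministic given the
state. `build_ensemble` draws, per member, a bootstrap resample (with
replacement, default resample size = training-set size) from a seed
stream derived deterministically from the master seed, so ensembles are
reproducible. Aggregation produces the per-pixel arithmetic mean and the
population variance (÷k, so identical members give exactly 0 and the
maximum is 0.25; sample variance is available via `ddof`). Binary
segmentation thresholds the mean strictly above μ_seg (default 0.5 —
the natural midpoint; exposed in config since nothing pins it down).

The default desk-scale member is the intensity-calibration predictor. In
the end-to-end pipeline each member additionally draws its own
preprocessing parameters (CLAHE clip ∈ U(0.005, 0.02), tiles ∈ {6, 8, 10},
median ∈ {3, 5, 7}) from the member seed stream — the analog, for a
deterministic member, of the augmentation and optimization stochasticity
that decorrelates deep ensemble members. A deep segmentation network
honoring the same contract plugs in unchanged; network architecture and
training are outside this package's scope.

## Sub-ensemble selection

Member dissimilarity is the MSE between two members' probability maps,
`(1/WH) Σ (p₁ − p₂)²`, averaged over a validation image set — computable
without any ground truth. Selecting the m-subset maximizing the sum of
pairwise distances is the maximum diversity problem (MDP); the max–min
variant (MMDP) is available behind an objective flag. Solvers:

- `mdp_exact`: exhaustive enumeration, guarded to n ≤ 15; ties break to
  the lexicographically smallest index set.
- `mdp_heuristic`: a genetic algorithm over boolean subset masks
  (population 50, up to 200 generations, early stop after 30 stale
  generations, tournament selection, common-core crossover with random
  fill from the symmetric difference, single-swap mutation, elitism),
  seeded with a greedy construction so the result never falls below the
  greedy baseline, and finished by 2-swap hill climbing from the elite
  and a few random restarts. Deterministic given its seed.

Baselines: `select_n_best` (m highest validation scores, ties to lower
indices) and `select_n_steps` (rank members by ascending score and take
ranks `round(i·(n−1)/(m−1))`, i = 0…m−1 — worst, evenly spaced
intermediates, best; rounding is floor(x + 0.5) so rank midpoints resolve
upward deterministically).

## Synthetic scenes and simulated raters

Scenes emulate the *structure* that matters for ambiguity-aware
evaluation, not FAF photometry. Background: a Gaussian random field
(sd 8, correlation scale 12 px) around a per-scene base level drawn from
U(75, 110) — acquisition brightness varies between eyes and devices. A
dark optic-disc circle (radius 7 % of the short side) sits near a lateral
border. Lesions are ellipses with smooth low-order radial wobble
(semi-axes 4–10 % of the short side), placed without overlap (a failure
to place within the budget raises rather than silently overlapping). HF
components add 45–95 intensity units, RA components subtract 45–80, both
feathered with a Gaussian of width proportional to image scale (2 px at
768) so borders are unsharp; offsets are assigned by component area —
large lesions are the conspicuous bright ones, small faint ones the
ambiguous ones. True masks are the crisp pre-feather component pixels.

Simulated raters disagree through exactly two mechanisms:

- **edge jitter**: per rater and component, a signed morphological
  disk offset of at most `edge_jitter_px` plus sparse single-pixel
  boundary noise — spatially coherent, like human outlining, not
  pixel-i.i.d. An erosion that would annihilate a component is backed
  off until the component survives, which bounds the distance of any
  jitter-induced disagreement pixel from the pair's mutual overlap by
  `max_pairwise_displacement = 2·(edge_jitter_px + 1)`; with zero jitter
  all raters reproduce the truth exactly.
- **area disagreement**: each non-anchor component is dropped
  independently per rater with probability `area_disagreement_prob`.
  The largest HF component is the anchor, visible to every rater, so a
  unanimous confident region always exists.

Default study conditions: 5 raters, 3 px jitter, 0.3 drop probability,
20 scenes, 20 ensemble members; tests and the end-to-end study run at
160–256 px scene sizes (the generator's native default is 768 px), with
components, feather and disc scaled proportionally so the geometry is
size-consistent.

What the generator does **not** emulate — and therefore what passing
tests cannot show about clinical data: vessel trees, disease-specific
lesion morphology and texture, intensity inhomogeneity fields,
device-specific noise, rater-specific bias (systematic over- or
under-segmentation), or correlations between raters' drop decisions.
Conclusions about the *mechanics* of the metrics and the pipeline
transfer; absolute score levels do not.

## Known limitations

- The intensity-calibration member classifies on a global per-intensity
  table, so its ensemble-mean map is smooth in [0, 1] rather than
  near-binary like deep segmentation networks. With the default
  thresholds (μ_mean = 0.2 vs μ_P = 0.1, μ_var = 0.1) a single member's
  ternary potential region is then systematically at least as inclusive
  as the ensemble's C ∪ P region, so ensemble-vs-single-member recall
  comparisons that favor deep ensembles come out as near-ties (±0.01)
  at desk scale; the variance-localization effect, by contrast, is
  robust. With near-binary members (e.g. plugged-in networks) the
  ordering reverts to the expected one.
- The MDP heuristic is exact in practice for small pools (validated
  exhaustively up to n = 12) but carries no optimality guarantee at
  n = 100.
- Ternary maps support exactly three labels; hierarchical or
  probabilistic uncertainty labels are out of scope.
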