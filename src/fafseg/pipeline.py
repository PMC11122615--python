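"""End-to-end synthetic study: scenes -> bagged ensemble -> ternary evaluation.

Composes the toolkit the way it is meant to be used on clinical data:

1. generate scenes with multi-rater annotation stacks;
2. fit a bagged ensemble of intensity-calibration members, each member on
   a bootstrap resample of the training set (one annotation per training
   scene, as in routine clinical annotation where only a dedicated
   agreement subset is read by multiple raters) and with its own draw of
   preprocessing parameters — the desk-scale analog of the training-time
   augmentation and optimization stochasticity that diversifies deep
   ensemble members;
3. aggregate member predictions into mean/variance maps, build ternary
   maps for the ensemble, the single best member, and the expert stack;
4. measure where the ensemble variance concentrates and how ensemble and
   single-member recall compare against the accumulated expert reference.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from . import metrics
from . import ternary as tern
from .config import MetricConfig
from .ensemble import aggregate, build_ensemble, predict_stack, threshold_segmentation
from .hyperextract import IntensityCalibrationPredictor, PreprocessParams
from .synthetic import SyntheticScene, generate_scene, simulate_expert_annotations


def varied_member_factory(seed):
    """Predictor factory whose members draw their own preprocessing.

    CLAHE clip limit, tile count and median kernel are jittered around
    the clinical defaults per member, so ensemble diversity comes from
    bagging *and* member-level stochasticity, mirroring how augmentation
    and training noise decorrelate deep ensemble members.
    """
    rng = np.random.default_rng(seed)

    def factory() -> IntensityCalibrationPredictor:
        return IntensityCalibrationPredictor(PreprocessParams(
            clahe_clip=float(rng.uniform(0.005, 0.02)),
            clahe_tiles=int(rng.choice([6, 8, 10])),
            median_kernel=int(rng.choice([3, 5, 7])),
            crop_to=None))

    return factory


@dataclasses.dataclass
class StudyResult:
    """Summary measurements of one synthetic ensemble study."""

    scenes: list[SyntheticScene]
    members: list
    best_member: int
    member_scores: list[float]
    var_in_dropped: float
    var_in_anchor: float
    recall_cp_ensemble: float
    recall_cp_best_member: float
    reports_ensemble: list[tern.TernaryReport]
    reports_best_member: list[tern.TernaryReport]


def run_synthetic_ensemble_study(n_scenes: int = 20, n_experts: int = 5,
                                 k_members: int = 20, scene_size: int = 160,
                                 n_hf: int = 3, n_ra: int = 1,
                                 edge_jitter_px: int = 3,
                                 area_disagreement_prob: float = 0.3,
                                 config: MetricConfig | None = None,
                                 seed: int = 0) -> StudyResult:
    """Run the full synthetic pipeline and collect its headline measurements.

    Ensemble variance is compared between pixels of components that at
    least one rater dropped and pixels of the anchor components everyone
    annotated (pooled over scenes); recall of the whole predicted lesion
    region is compared between the ensemble ternary (mean/variance rule)
    and the validation-best single member's ternary (two-threshold rule),
    both against the rater-count ternary of the expert stack.
    """
    cfg = config or MetricConfig()
    ss = np.random.SeedSequence(seed)
    s_scene, s_ann, s_pick, s_ens, s_fac = ss.spawn(5)
    scene_seeds = s_scene.generate_state(n_scenes) % (2**31)
    ann_seeds = s_ann.generate_state(n_scenes) % (2**31)

    scenes: list[SyntheticScene] = []
    for i in range(n_scenes):
        scene = generate_scene(scene_size, scene_size, n_hf, n_ra,
                               seed=int(scene_seeds[i]))
        simulate_expert_annotations(scene, n_experts=n_experts,
                                    edge_jitter_px=edge_jitter_px,
                                    area_disagreement_prob=area_disagreement_prob,
                                    seed=int(ann_seeds[i]))
        scenes.append(scene)

    # routine annotation: one rater per training image
    rng = np.random.default_rng(s_pick)
    train_images = [s.image for s in scenes]
    train_masks = [s.expert_stack[rng.integers(n_experts)] for s in scenes]

    members = build_ensemble(train_images, train_masks, k_members,
                             varied_member_factory(s_fac), seed=s_ens)
    stacks = [predict_stack(members, s.image) for s in scenes]

    member_scores = [
        float(np.mean([metrics.dice(threshold_segmentation(st[k], cfg.mu_seg), m)
                       for st, m in zip(stacks, train_masks)]))
        for k in range(k_members)
    ]
    best = int(np.argmax(member_scores))

    var_dropped: list[np.ndarray] = []
    var_anchor: list[np.ndarray] = []
    reports_ens: list[tern.TernaryReport] = []
    reports_best: list[tern.TernaryReport] = []
    for scene, stack in zip(scenes, stacks):
        mean, var = aggregate(stack)
        for comp in scene.components_of("hf"):
            if comp.anchor:
                var_anchor.append(var[comp.mask])
            elif comp.visibility and not all(comp.visibility):
                var_dropped.append(var[comp.mask])
        annot = tern.ternary_from_annotation_stack(scene.expert_stack,
                                                   cfg.mu_a_c, cfg.mu_a_p)
        t_ens = tern.ternary_from_mean_variance(mean, var, cfg.mu_mean, cfg.mu_var)
        t_best = tern.ternary_from_probability(stack[best], cfg.mu_c, cfg.mu_p)
        reports_ens.append(tern.ternary_metrics(t_ens, annot))
        reports_best.append(tern.ternary_metrics(t_best, annot))

    recall_ens = float(np.mean([r.recall_cp for r in reports_ens]))
    recall_best = float(np.mean([r.recall_cp for r in reports_best]))
    return StudyResult(
        scenes=scenes,
        members=members,
        best_member=best,
        member_scores=member_scores,
        var_in_dropped=float(np.mean(np.concatenate(var_dropped))) if var_dropped else float("nan"),
        var_in_anchor=float(np.mean(np.concatenate(var_anchor))) if var_anchor else float("nan"),
        recall_cp_ensemble=recall_ens,
        recall_cp_best_member=recall_best,
        reports_ensemble=reports_ens,
        reports_best_member=reports_best,
    )
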