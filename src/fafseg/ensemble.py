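"""Bagged ensembles over a pluggable predictor contract.

Every member is fitted on a bootstrap resample (sampling training items
with replacement) so that members disagree exactly where the training
data is ambiguous; aggregating the member probability maps into a
per-pixel mean and variance then turns that disagreement into a
confidence signal.  The mean map thresholded gives a binary
segmentation; mean and variance together feed the ternary labeling.

The predictor contract is structural: anything with
``fit(images, masks) -> self`` and ``predict(image) -> probability map``
plugs in.  The default desk-scale member is the intensity-calibration
predictor; a deep segmentation network honoring the same contract drops
in without changes here.
"""

from __future__ import annotations

from typing import Callable, Protocol, Sequence

import numpy as np


class Predictor(Protocol):
    def fit(self, images: Sequence[np.ndarray], masks: Sequence[np.ndarray]) -> "Predictor": ...

    def predict(self, image: np.ndarray) -> np.ndarray: ...


def bootstrap_indices(n_items: int, sample_size: int, seed=None) -> np.ndarray:
    """Sample ``sample_size`` item indices with replacement (bagging draw)."""
    if n_items < 1 or sample_size < 1:
        raise ValueError("n_items and sample_size must be positive")
    rng = np.random.default_rng(seed)
    return rng.integers(0, n_items, size=sample_size)


def member_seed(master_seed, member_index: int) -> np.random.SeedSequence:
    """Deterministic, mutually independent per-member seed stream."""
    if isinstance(master_seed, np.random.SeedSequence):
        return np.random.SeedSequence(entropy=master_seed.entropy,
                                      spawn_key=(*master_seed.spawn_key, member_index))
    return np.random.SeedSequence(entropy=(0 if master_seed is None else master_seed),
                                  spawn_key=(member_index,))


def build_ensemble(train_images: Sequence[np.ndarray],
                   train_masks: Sequence[np.ndarray],
                   k_members: int,
                   predictor_factory: Callable[[], Predictor],
                   sample_size: int | None = None,
                   seed: int | None = None) -> list[Predictor]:
    """Fit ``k_members`` predictors, each on its own bootstrap resample.

    ``sample_size`` defaults to the training-set size; member ``i`` draws
    its resample from a seed stream derived deterministically from the
    master seed, so rebuilding with the same seed reproduces the ensemble.
    """
    if k_members < 1:
        raise ValueError("need at least one member")
    n = len(train_images)
    if n != len(train_masks):
        raise ValueError("images and masks must pair up")
    if n < 1:
        raise ValueError("empty training set")
    sample_size = sample_size or n
    members: list[Predictor] = []
    for i in range(k_members):
        idx = bootstrap_indices(n, sample_size, seed=member_seed(seed, i))
        try:
            member = predictor_factory().fit([train_images[j] for j in idx],
                                             [train_masks[j] for j in idx])
        except Exception as exc:  # noqa: BLE001 - annotate which member failed
            raise RuntimeError(f"fitting ensemble member {i} failed") from exc
        members.append(member)
    return members


def predict_stack(members: Sequence[Predictor], image: np.ndarray) -> np.ndarray:
    """Stack the member probability maps for one image into (k, H, W)."""
    maps = [np.asarray(m.predict(image), dtype=float) for m in members]
    shapes = {p.shape for p in maps}
    if len(shapes) != 1:
        raise ValueError(f"members disagree on grid: {shapes}")
    return np.stack(maps)


def aggregate(stack: np.ndarray, ddof: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel mean and variance of a (k, H, W) prediction stack.

    Variance is the population variance (``ddof=0``) by default, so a
    stack of identical maps has exactly zero variance and the maximum —
    half the members at 0 and half at 1 — is 0.25.
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3 or stack.shape[0] < 1:
        raise ValueError("prediction stack must be (k, H, W) with k >= 1")
    return stack.mean(axis=0), stack.var(axis=0, ddof=ddof)


def threshold_segmentation(mean: np.ndarray, mu_seg: float = 0.5) -> np.ndarray:
    """Binary mask: foreground strictly above the probability threshold."""
    if not 0.0 <= mu_seg <= 1.0:
        raise ValueError("mu_seg must lie in [0, 1]")
    return np.asarray(mean, dtype=float) > mu_seg
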