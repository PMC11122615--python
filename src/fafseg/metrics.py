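"""Binary segmentation agreement metrics with an edge/area error split.

The Dice score alone cannot tell *why* two segmentations of the same image
differ: raters may agree that a lesion is present but draw its unsharp
border differently (edge errors, EE), or they may disagree about the lesion
being there at all (area errors, AE).  The metrics here decompose the
disagreeing pixels ``FP ∪ FN`` into those two sets by distance to the
mutually agreed foreground ``TP`` and derive an adjusted Dice score that
forgives border placement up to a tolerance.

Conventions used throughout:

* masks are boolean ``(H, W)`` arrays; the first argument plays the role of
  the prediction, the second the reference, but every quantity here is
  symmetric under swapping the two (``FP`` and ``FN`` trade places);
* when ``TP`` is empty the distance of every disagreeing pixel is defined
  as the image diagonal ``sqrt(W**2 + H**2)``;
* when both masks are empty the Dice score is defined as 1.0 (perfect
  agreement on absence).
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
from scipy import ndimage


def _as_mask(a) -> np.ndarray:
    m = np.asarray(a)
    if m.ndim != 2:
        raise ValueError(f"mask must be 2-D, got shape {m.shape}")
    return m.astype(bool)


def _check_same_grid(pred: np.ndarray, ref: np.ndarray) -> None:
    if pred.shape != ref.shape:
        raise ValueError(f"grid mismatch: {pred.shape} vs {ref.shape}")


def image_diagonal(shape: tuple[int, int]) -> float:
    """Length of the image diagonal in pixels, ``sqrt(W**2 + H**2)``."""
    h, w = shape
    return math.hypot(w, h)


@dataclasses.dataclass
class ErrorPartition:
    """Confusion counts plus the edge/area split of the disagreement.

    ``ee`` and ``ae`` are boolean masks partitioning ``FP ∪ FN``: pixels
    whose Euclidean distance to the nearest ``TP`` pixel is at most
    ``mu_ee`` are edge errors, the rest area errors.
    """

    tp: int
    fp: int
    fn: int
    tn: int
    mu_ee: float | None = None
    ee: np.ndarray | None = None
    ae: np.ndarray | None = None

    @property
    def n_ee(self) -> int:
        return 0 if self.ee is None else int(self.ee.sum())

    @property
    def n_ae(self) -> int:
        return 0 if self.ae is None else int(self.ae.sum())


def confusion(pred, ref) -> ErrorPartition:
    """Pixel-wise confusion counts of a prediction against a reference."""
    pred, ref = _as_mask(pred), _as_mask(ref)
    _check_same_grid(pred, ref)
    tp = int(np.count_nonzero(pred & ref))
    fp = int(np.count_nonzero(pred & ~ref))
    fn = int(np.count_nonzero(~pred & ref))
    tn = pred.size - tp - fp - fn
    return ErrorPartition(tp=tp, fp=fp, fn=fn, tn=tn)


def dice(pred, ref) -> float:
    """Dice overlap ``2|TP| / (2|TP| + |FP| + |FN|)``; both-empty -> 1.0."""
    c = confusion(pred, ref)
    denom = 2 * c.tp + c.fp + c.fn
    if denom == 0:
        return 1.0
    return 2.0 * c.tp / denom


def distance_to_tp(pred, ref) -> np.ndarray:
    """Euclidean distance of every pixel to the nearest mutually agreed pixel.

    Returns an ``(H, W)`` float array that is exactly 0 on ``TP``.  If
    ``TP`` is empty, every pixel gets the image-diagonal length, so all
    disagreements become area errors under any reasonable threshold.
    """
    pred, ref = _as_mask(pred), _as_mask(ref)
    _check_same_grid(pred, ref)
    tp = pred & ref
    if not tp.any():
        return np.full(pred.shape, image_diagonal(pred.shape), dtype=float)
    # exact EDT: distance of background-of-TP pixels to the TP set
    return ndimage.distance_transform_edt(~tp)


def partition_errors(pred, ref, mu_ee: float) -> ErrorPartition:
    """Split the disagreeing pixels into edge errors and area errors.

    A disagreeing pixel is an edge error when its distance to ``TP`` is
    smaller or equal to ``mu_ee`` (inclusive), an area error otherwise.
    """
    if mu_ee < 0:
        raise ValueError("mu_ee must be non-negative")
    pred, ref = _as_mask(pred), _as_mask(ref)
    part = confusion(pred, ref)
    errors = pred ^ ref  # FP ∪ FN
    d = distance_to_tp(pred, ref)
    ee = errors & (d <= mu_ee)
    ae = errors & ~ee
    part.mu_ee = float(mu_ee)
    part.ee = ee
    part.ae = ae
    return part


def dice_ae(pred, ref, mu_ee: float) -> float:
    """Area-error-adjusted Dice ``2|TP| / (2|TP| + |AE|)``.

    Edge errors within ``mu_ee`` pixels of the agreed foreground are
    forgiven, so this is never smaller than the plain Dice score; at
    ``mu_ee = 0`` the two coincide.
    """
    part = partition_errors(pred, ref, mu_ee)
    denom = 2 * part.tp + part.n_ae
    if denom == 0:
        return 1.0
    return 2.0 * part.tp / denom


def _ae_counts_per_threshold(pred, ref, thresholds: np.ndarray) -> tuple[int, np.ndarray, int]:
    """(|TP|, |AE| per threshold, |FP|+|FN|) computed from one distance map."""
    pred, ref = _as_mask(pred), _as_mask(ref)
    c = confusion(pred, ref)
    err = pred ^ ref
    d = np.sort(distance_to_tp(pred, ref)[err])
    n_err = d.size
    # AE(t) = number of error pixels with distance strictly greater than t
    n_ee = np.searchsorted(d, thresholds, side="right")
    return c.tp, n_err - n_ee, n_err


def mean_dice_ae(pred, ref, mu_ee_max: int = 100) -> float:
    """Mean adjusted Dice over the integer threshold lattice ``0..mu_ee_max``.

    Averaging over thresholds removes the bias a single hand-picked
    ``mu_ee`` would introduce; the lattice has ``mu_ee_max + 1`` entries.
    """
    if mu_ee_max < 0:
        raise ValueError("mu_ee_max must be a non-negative integer")
    return float(dice_ae_curve(pred, ref, mu_ee_max).mean())


def dice_ae_curve(pred, ref, mu_ee_max: int = 100) -> np.ndarray:
    """Adjusted Dice at every integer threshold ``0..mu_ee_max``."""
    thresholds = np.arange(int(mu_ee_max) + 1, dtype=float)
    tp, n_ae, _ = _ae_counts_per_threshold(pred, ref, thresholds)
    denom = (2 * tp + n_ae).astype(float)
    out = np.ones_like(denom)
    np.divide(2.0 * tp, denom, out=out, where=denom != 0)
    return out


def ae_ratio_curve(stack, thresholds=None) -> np.ndarray:
    """Fraction of disagreement that is area error, averaged over rater pairs.

    For every ordered pair of annotations in the stack, the ratio
    ``|AE| / (|FP| + |FN|)`` is evaluated on the given threshold grid
    (default ``0..100``); pairs with no disagreement are excluded from the
    average.  Pairs with no mutual overlap contribute a ratio of 1 at every
    threshold below the image diagonal — their disagreement is an area
    error by default.  Returns an empty array when no pair disagrees.
    """
    stack = np.asarray(stack).astype(bool)
    if stack.ndim != 3 or stack.shape[0] < 2:
        raise ValueError("need a (k, H, W) stack with at least 2 annotations")
    if thresholds is None:
        thresholds = np.arange(101, dtype=float)
    thresholds = np.asarray(thresholds, dtype=float)
    k = stack.shape[0]
    ratios = []
    for i in range(k):
        for j in range(k):
            if i == j:
                continue
            _, n_ae, n_err = _ae_counts_per_threshold(stack[i], stack[j], thresholds)
            if n_err == 0:
                continue
            ratios.append(n_ae / n_err)
    if not ratios:
        return np.empty((0,))
    return np.mean(ratios, axis=0)
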