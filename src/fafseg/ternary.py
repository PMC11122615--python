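"""Ternary (confident / potential / background) maps and their metric suite.

A ternary map assigns every pixel one of three labels: ``C`` (confidently
lesion), ``P`` (potentially lesion) and ``B`` (background).  Three
constructions are supported, depending on the available input:

* an ensemble mean map plus a variance map — high variance marks a pixel
  as potential; low variance yields confident or background depending on
  the mean;
* a single probability map — two thresholds carve out confident
  (``p >= mu_c``), background (``p <= mu_p``) and potential in between;
  a hard 0/1 annotation therefore never produces potential pixels;
* a stack of binary annotations — the per-pixel rater count is compared
  against two count thresholds.

Maps are stored as ``(H, W)`` uint8 arrays over the constants ``B``, ``P``
and ``C`` below.
"""

from __future__ import annotations

import dataclasses

import numpy as np

B: int = 0
P: int = 1
C: int = 2

_LABELS = (B, P, C)


def _as_probability(a) -> np.ndarray:
    p = np.asarray(a, dtype=float)
    if p.ndim != 2:
        raise ValueError(f"probability map must be 2-D, got shape {p.shape}")
    return np.clip(p, 0.0, 1.0)


def validate_ternary(tmap) -> np.ndarray:
    """Return the map as uint8, checking labels are within {B, P, C}."""
    t = np.asarray(tmap)
    if t.ndim != 2:
        raise ValueError(f"ternary map must be 2-D, got shape {t.shape}")
    if not np.isin(t, _LABELS).all():
        raise ValueError("ternary map contains labels outside {B, P, C}")
    return t.astype(np.uint8)


def ternary_from_mean_variance(mean, var, mu_mean: float = 0.2, mu_var: float = 0.1) -> np.ndarray:
    """Label pixels from an ensemble mean map and variance map.

    ``var >= mu_var`` -> P; otherwise ``mean > mu_mean`` -> C, else B.  The
    mean comparison is strict so that, with the default 0.2, strictly more
    than a fifth of the ensemble must support a pixel for it to count as
    confident.
    """
    mean = _as_probability(mean)
    var = np.asarray(var, dtype=float)
    if mean.shape != var.shape:
        raise ValueError(f"grid mismatch: {mean.shape} vs {var.shape}")
    out = np.full(mean.shape, B, dtype=np.uint8)
    out[mean > mu_mean] = C
    out[var >= mu_var] = P
    return out


def ternary_from_probability(p, mu_c: float = 0.9, mu_p: float = 0.1) -> np.ndarray:
    """Label pixels of a single probability map with two thresholds.

    ``p >= mu_c`` -> C, ``p <= mu_p`` -> B, anything strictly between -> P.
    """
    if not mu_p < mu_c:
        raise ValueError("mu_p must be strictly smaller than mu_c")
    p = _as_probability(p)
    out = np.full(p.shape, P, dtype=np.uint8)
    out[p >= mu_c] = C
    out[p <= mu_p] = B
    return out


def ternary_from_annotation_stack(stack, mu_a_c: int = 5, mu_a_p: int = 2) -> np.ndarray:
    """Label pixels from a multi-rater annotation stack by rater count.

    A pixel is confident when at least ``mu_a_c`` raters marked it,
    potential when at least ``mu_a_p`` but fewer than ``mu_a_c`` did, and
    background otherwise.  With a single rater and both thresholds 1 this
    reduces to the single-annotation rule: no pixel can be potential.
    """
    stack = np.asarray(stack).astype(bool)
    if stack.ndim != 3:
        raise ValueError("annotation stack must be (k, H, W)")
    k = stack.shape[0]
    if not (1 <= mu_a_p <= mu_a_c <= k):
        raise ValueError(f"need 1 <= mu_a_p <= mu_a_c <= k={k}, got ({mu_a_p}, {mu_a_c})")
    count = stack.sum(axis=0)
    out = np.full(count.shape, B, dtype=np.uint8)
    out[count >= mu_a_p] = P
    out[count >= mu_a_c] = C
    return out


def ternary_collapse(tmap, mode: str) -> np.ndarray:
    """Degenerate collapses used as sanity baselines.

    ``all_C`` maps every potential pixel to confident (background stays);
    ``all_P`` maps every pixel, background included, to potential — the
    trivial predictor that games the recall-style metrics.
    """
    t = validate_ternary(tmap)
    if mode == "all_C":
        out = t.copy()
        out[out == P] = C
        return out
    if mode == "all_P":
        return np.full(t.shape, P, dtype=np.uint8)
    raise ValueError(f"unknown collapse mode {mode!r}")


@dataclasses.dataclass
class TernaryReport:
    """The six agreement scores between a predicted and an annotated ternary map.

    Every field is a float in [0, 1] or ``None`` when its denominator is an
    empty region (e.g. no pixel predicted confident); undefined values stay
    ``None`` through aggregation and serialize as JSON null.
    """

    precision_c: float | None
    recall_cp: float | None
    precision_c_to_cp: float | None
    recall_cp_to_c: float | None
    precision_cp: float | None
    dcs_cp: float | None

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _ratio(num: int, denom: int) -> float | None:
    return None if denom == 0 else num / denom


def ternary_metrics(pred, annot) -> TernaryReport:
    """Score a predicted ternary map against an annotated one.

    The strict pair — precision of confident predictions against confident
    annotation, and recall of the whole predicted lesion region against the
    whole annotated one — guarantees that confident output is definitely
    right and that no annotated lesion is missed.  The lenient pair relaxes
    one side each.  A combined precision and its harmonic mean with the
    recall (a Dice score) guard against the degenerate all-potential
    predictor, for which the confident precisions are undefined and both
    recalls are trivially 1.
    """
    pred = validate_ternary(pred)
    annot = validate_ternary(annot)
    if pred.shape != annot.shape:
        raise ValueError(f"grid mismatch: {pred.shape} vs {annot.shape}")

    pred_c = pred == C
    pred_cp = pred != B
    annot_c = annot == C
    annot_cp = annot != B

    n_pred_c = int(pred_c.sum())
    n_pred_cp = int(pred_cp.sum())
    n_annot_c = int(annot_c.sum())
    n_annot_cp = int(annot_cp.sum())

    precision_c = _ratio(int((pred_c & annot_c).sum()), n_pred_c)
    recall_cp = _ratio(int((pred_cp & annot_cp).sum()), n_annot_cp)
    precision_c_to_cp = _ratio(int((pred_c & annot_cp).sum()), n_pred_c)
    recall_cp_to_c = _ratio(int((pred_cp & annot_c).sum()), n_annot_c)
    precision_cp = _ratio(int((pred_cp & annot_cp).sum()), n_pred_cp)

    if precision_cp is None or recall_cp is None:
        dcs_cp = None
    elif precision_cp + recall_cp == 0:
        dcs_cp = 0.0
    else:
        dcs_cp = 2.0 * precision_cp * recall_cp / (precision_cp + recall_cp)

    return TernaryReport(
        precision_c=precision_c,
        recall_cp=recall_cp,
        precision_c_to_cp=precision_c_to_cp,
        recall_cp_to_c=recall_cp_to_c,
        precision_cp=precision_cp,
        dcs_cp=dcs_cp,
    )


def aggregate_reports(reports: list[TernaryReport]) -> dict:
    """Mean of each metric over the reports, ignoring undefined entries.

    Returns ``{metric: {"mean": float | None, "n_defined": int}}``; a mean
    is ``None`` when the metric was undefined in every report.
    """
    out: dict = {}
    for field in dataclasses.fields(TernaryReport):
        vals = [getattr(r, field.name) for r in reports]
        defined = [v for v in vals if v is not None]
        out[field.name] = {
            "mean": float(np.mean(defined)) if defined else None,
            "n_defined": len(defined),
        }
    return out
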