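"""Losses and evaluation metrics.

This module houses three things:

* the α-balanced focal loss used for training the pixel classifier,
  with class weights derived from inverse training-set frequencies;
* the per-class Dice coefficient ``2|T ∩ P| / (|T| + |P|)``;
* the per-image malignant / benign / healthy classification protocol:
  each image is reduced to the presence or absence of malignant and
  benign content, tallied into TP/TN/FP/FN confusion counts per
  category, from which precision, recall (sensitivity) and F-score are
  derived in percent.

The focal loss down-weights well-classified pixels: the plain
cross-entropy ``-log(p_t)`` is scaled by ``(1 - p_t)^γ`` so pixels the
model already classifies confidently contribute little, and by a
per-class weight ``α_t`` so rare classes are not drowned out. With
``γ = 0`` and all ``α = 1`` it reduces exactly to cross-entropy.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .scheme import ClassScheme, DEFAULT_SCHEME, N_CLASSES

log = logging.getLogger(__name__)

#: probabilities are floored here inside the log so the loss stays finite
LOG_CLAMP = 1e-12


@dataclass
class FocalLossParams:
    """Focusing parameter γ >= 0 and per-class weights α in (0, 1]."""

    gamma: float = 2.0
    alpha: np.ndarray = field(default_factory=lambda: np.ones(N_CLASSES))

    def __post_init__(self) -> None:
        self.alpha = np.asarray(self.alpha, dtype=np.float64)
        if self.gamma < 0:
            raise ValueError(f"gamma must be >= 0, got {self.gamma}")
        if np.any(self.alpha <= 0):
            raise ValueError("all alpha weights must be positive")


def class_alphas(masks, n_classes: int = N_CLASSES) -> np.ndarray:
    """Inverse-frequency class weights, max-normalized to 1.

    ``α_c ∝ 1 / f_c`` where ``f_c`` is the fraction of training pixels
    labelled ``c``; the rarest present class gets weight 1. A class that
    never occurs gets the maximum weight 1 and a warning is logged.
    """
    counts = np.zeros(n_classes, dtype=np.int64)
    for m in masks:
        counts += np.bincount(np.asarray(m).ravel(), minlength=n_classes)[:n_classes]
    total = counts.sum()
    if total == 0:
        raise ValueError("no mask pixels given")
    alphas = np.ones(n_classes, dtype=np.float64)
    present = counts > 0
    if not present.all():
        absent = [int(i) for i in np.flatnonzero(~present)]
        log.warning("class_alphas: classes %s absent from the masks; "
                    "assigning maximum weight 1", absent)
    freq = counts[present] / total
    inv = 1.0 / freq
    alphas[present] = inv / inv.max()
    return alphas


def softmax(scores: np.ndarray, axis: int = -1) -> np.ndarray:
    z = scores - scores.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def focal_loss(scores: np.ndarray, truth: np.ndarray,
               params: FocalLossParams) -> float:
    """Mean α-balanced focal loss over pixels.

    ``scores`` is (..., C) raw class scores (softmaxed internally),
    ``truth`` the integer class map of matching leading shape. Per pixel
    the loss is ``-α_c* (1 - p_c*)^γ log(p_c*)`` at the true class c*.
    """
    loss, _ = focal_loss_with_grad(scores, truth, params, need_grad=False)
    return loss


def focal_loss_with_grad(scores: np.ndarray, truth: np.ndarray,
                         params: FocalLossParams, need_grad: bool = True
                         ) -> tuple[float, np.ndarray | None]:
    """Focal loss and (optionally) its gradient with respect to scores.

    The gradient is analytic: with ``p = softmax(z)`` and true class t,
    ``dL/dp_t = α_t [γ (1-p_t)^{γ-1} log p_t - (1-p_t)^γ / p_t]`` and
    ``dp_t/dz_j = p_t (δ_tj - p_j)``, mean-reduced over pixels.
    """
    scores = np.asarray(scores, dtype=np.float64)
    truth = np.asarray(truth)
    if scores.shape[:-1] != truth.shape:
        raise ValueError(f"scores {scores.shape} vs truth {truth.shape}: "
                         "leading shapes must match")
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores contain non-finite values")
    c = scores.shape[-1]
    p = softmax(scores)
    flat_p = p.reshape(-1, c)
    flat_t = truth.reshape(-1)
    n = flat_t.size
    idx = np.arange(n)
    pt = np.clip(flat_p[idx, flat_t], LOG_CLAMP, 1.0)
    at = params.alpha[flat_t]
    gamma = params.gamma
    one_minus = 1.0 - pt
    logpt = np.log(pt)
    mod = one_minus ** gamma
    loss = float(np.mean(-at * mod * logpt))
    if not need_grad:
        return loss, None
    # dL/dp_t; the gamma term vanishes identically when gamma == 0
    if gamma == 0.0:
        dldpt = -at / pt
    else:
        om = np.maximum(one_minus, LOG_CLAMP)
        dldpt = at * (gamma * om ** (gamma - 1.0) * logpt - mod / pt)
    grad_flat = flat_p * (-dldpt * pt)[:, None]
    grad_flat[idx, flat_t] += dldpt * pt
    grad = (grad_flat / n).reshape(scores.shape)
    return loss, grad


def cross_entropy(scores: np.ndarray, truth: np.ndarray) -> float:
    """Mean softmax cross-entropy; the γ=0, α=1 focal-loss special case."""
    return focal_loss(scores, truth,
                      FocalLossParams(gamma=0.0, alpha=np.ones(scores.shape[-1])))


@dataclass
class DiceResult:
    """Per-class Dice values (NaN where undefined) and their mean."""

    per_class: np.ndarray
    mean: float


def dice(pred: np.ndarray, truth: np.ndarray,
         n_classes: int = N_CLASSES, absent_as_one: bool = False) -> DiceResult:
    """Per-class Dice ``2|T ∩ P| / (|T| + |P|)`` and the class mean.

    Classes absent from both maps have an undefined Dice; by default
    they are excluded from the mean (``absent_as_one=True`` counts them
    as a perfect 1 instead).
    """
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    per = np.full(n_classes, np.nan)
    for c in range(n_classes):
        p = pred == c
        t = truth == c
        denom = int(p.sum()) + int(t.sum())
        if denom == 0:
            if absent_as_one:
                per[c] = 1.0
            continue
        per[c] = 2.0 * int(np.logical_and(p, t).sum()) / denom
    defined = ~np.isnan(per)
    mean = float(per[defined].mean()) if defined.any() else float("nan")
    return DiceResult(per_class=per, mean=mean)


# Per-image categorization -------------------------------------------------

#: outcome marker for images outside a category's defining conditions
NOT_APPLICABLE = "n/a"


def _content(seg: np.ndarray, scheme: ClassScheme) -> tuple[bool, bool]:
    """(has malignant pixel, has benign pixel) for a segmentation map."""
    present = np.unique(seg)
    has_mal = any(c in present for c in scheme.malignant_classes)
    has_ben = any(c in present for c in scheme.benign_classes)
    return has_mal, has_ben


def categorize_image(pred: np.ndarray, truth: np.ndarray,
                     scheme: ClassScheme = DEFAULT_SCHEME
                     ) -> tuple[str, str]:
    """Classify one image into (malignant outcome, benign outcome).

    The malignant category compares the presence of any malignant-class
    pixel in the prediction against the ground truth; every image is
    applicable. The benign category only applies to images where
    neither the prediction nor the truth shows a malignant region (the
    protocol's benign definitions all carry a "no malignant region"
    condition); within that subset, presence of a benign feature is
    compared the same way. Outcomes are 'TP', 'TN', 'FP', 'FN' or
    'n/a'.
    """
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    pm, pb = _content(pred, scheme)
    tm, tb = _content(truth, scheme)
    mal = {(True, True): "TP", (False, False): "TN",
           (True, False): "FP", (False, True): "FN"}[(pm, tm)]
    if pm or tm:
        ben = NOT_APPLICABLE
    else:
        ben = {(True, True): "TP", (False, False): "TN",
               (True, False): "FP", (False, True): "FN"}[(pb, tb)]
    return mal, ben


@dataclass
class ConfusionCounts:
    """Per-image TP/TN/FP/FN tallies for one category."""

    category: str
    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def add(self, outcome: str) -> None:
        if outcome == NOT_APPLICABLE:
            return
        setattr(self, outcome.lower(), getattr(self, outcome.lower()) + 1)


def tally(outcomes, category: str) -> ConfusionCounts:
    """Aggregate per-image outcomes for one category into counts."""
    counts = ConfusionCounts(category=category)
    for o in outcomes:
        counts.add(o)
    return counts


def prf(counts: ConfusionCounts) -> tuple[float, float, float]:
    """(precision, recall, F-score) in percent from confusion counts.

    ``precision = TP/(TP+FP)``, ``recall = TP/(TP+FN)`` and the harmonic
    mean ``F = TP / (TP + (FP+FN)/2)``, each times 100. A zero
    denominator yields NaN for that metric rather than an exception.
    """
    tp, fp, fn = counts.tp, counts.fp, counts.fn
    precision = 100.0 * tp / (tp + fp) if tp + fp > 0 else float("nan")
    recall = 100.0 * tp / (tp + fn) if tp + fn > 0 else float("nan")
    f_denom = tp + 0.5 * (fp + fn)
    f_score = 100.0 * tp / f_denom if f_denom > 0 else float("nan")
    return precision, recall, f_score


def format_percent(x: float) -> str:
    """Percentages are reported at 4 decimal places."""
    return "nan" if math.isnan(x) else f"{x:.4f}"
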