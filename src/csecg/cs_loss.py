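"""Dynamic cost-sensitive loss for imbalanced heartbeat classification.

For every mini-batch, a per-class misclassification cost

    phi_c = CW_c + HM_c

is recomputed from two signals:

* **class distribution** — inverse-frequency balanced weights
  ``w_c = n_total / (C * n_c)`` are computed for the batch (``CW_b``) and for
  the whole training set (``CW_D``) and blended by their quadratic mean
  ``CW_c = sqrt((CW_b,c^2 + CW_D,c^2) / 2)``, so a batch whose composition
  drifts from the dataset's still receives a stable weight;
* **model performance** — the one-vs-rest false-positive and false-negative
  rates of the model's current predictions on the batch, combined per class
  by their harmonic mean ``HM_c = 2 / (FPR_c^-1 + FNR_c^-1)`` (zero when
  either rate is zero: a class the model gets right on one side earns no
  extra penalty).

The batch loss is the phi-weighted cross-entropy,
``mean_i phi[y_i] * (-log p_i[y_i])`` (natural log). ``phi`` is a batch
statistic: no gradient flows through it. Classes absent from a batch fall
back to their dataset weight, so phi is always finite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Smoothing constant inside the harmonic-mean reciprocals.
EPSILON = 1e-7

#: Clamp for log-probabilities in the cross-entropy term.
PROB_FLOOR = 1e-12


@dataclass(frozen=True)
class BatchCostState:
    """All per-class quantities behind one batch's misclassification cost."""

    CW_b: np.ndarray       # batch inverse-frequency weights
    CW_D: np.ndarray       # dataset inverse-frequency weights
    CW: np.ndarray         # quadratic-mean blend
    FPR: np.ndarray        # one-vs-rest false-positive rates on the batch
    FNR: np.ndarray        # one-vs-rest false-negative rates on the batch
    HM_b: np.ndarray       # harmonic mean of FPR and FNR
    phi: np.ndarray        # misclassification cost, CW + HM_b
    batch_size: int

    def to_row(self) -> list[float]:
        """Flatten to a training-log row (6 quantities x C classes)."""
        return [
            float(v)
            for vec in (self.CW_b, self.CW_D, self.CW, self.FPR, self.FNR,
                        self.HM_b)
            for v in vec
        ]


def class_weights(counts: np.ndarray, total: int, C: int) -> np.ndarray:
    """Inverse-frequency balanced weights ``w_c = total / (C * counts_c)``.

    Classes with a zero count get ``nan`` — the caller substitutes the
    dataset weight (see :func:`compute_batch_cost`). Balanced counts give
    unit weights.
    """
    counts = np.asarray(counts, dtype=float)
    if total <= 0:
        raise ValueError("total count must be positive")
    if C < 2:
        raise ValueError("need at least 2 classes")
    if counts.size != C:
        raise ValueError(f"expected {C} counts, got {counts.size}")
    with np.errstate(divide="ignore"):
        w = total / (C * counts)
    return np.where(counts > 0, w, np.nan)


def blend_weights(CW_b: np.ndarray, CW_D: np.ndarray) -> np.ndarray:
    """Quadratic mean of the batch and dataset weights, componentwise."""
    CW_b = np.asarray(CW_b, dtype=float)
    CW_D = np.asarray(CW_D, dtype=float)
    if CW_b.shape != CW_D.shape:
        raise ValueError("weight vectors must have the same length")
    if np.any(CW_b < 0) or np.any(CW_D < 0):
        raise ValueError("class weights must be nonnegative")
    return np.sqrt((CW_b**2 + CW_D**2) / 2.0)


def batch_rates(
    true_labels: np.ndarray, predicted_labels: np.ndarray, C: int
) -> tuple[np.ndarray, np.ndarray]:
    """One-vs-rest FPR and FNR per class; empty denominators yield 0."""
    true_labels = np.asarray(true_labels, dtype=int)
    predicted_labels = np.asarray(predicted_labels, dtype=int)
    if true_labels.shape != predicted_labels.shape:
        raise ValueError("label sequences must have the same length")
    fpr = np.zeros(C)
    fnr = np.zeros(C)
    for c in range(C):
        is_true = true_labels == c
        is_pred = predicted_labels == c
        fp = int(np.sum(~is_true & is_pred))
        tn = int(np.sum(~is_true & ~is_pred))
        fn = int(np.sum(is_true & ~is_pred))
        tp = int(np.sum(is_true & is_pred))
        if fp + tn > 0:
            fpr[c] = fp / (fp + tn)
        if fn + tp > 0:
            fnr[c] = fn / (fn + tp)
    return fpr, fnr


def harmonic_cost(FPR: np.ndarray, FNR: np.ndarray) -> np.ndarray:
    """Per-class harmonic mean of FPR and FNR (zero if either rate is zero)."""
    FPR = np.asarray(FPR, dtype=float)
    FNR = np.asarray(FNR, dtype=float)
    hm = 2.0 / (1.0 / (FPR + EPSILON) + 1.0 / (FNR + EPSILON))
    return np.where((FPR == 0) | (FNR == 0), 0.0, hm)


def misclassification_cost(CW: np.ndarray, HM_b: np.ndarray) -> np.ndarray:
    """phi = CW + HM_b, componentwise."""
    return np.asarray(CW, dtype=float) + np.asarray(HM_b, dtype=float)


def total_loss(
    probabilities: np.ndarray,
    labels: np.ndarray,
    phi: np.ndarray,
    phi_max: float | None = None,
) -> float:
    """phi-weighted mean cross-entropy (natural log).

    With ``phi == 1`` this is the plain cross-entropy. Probabilities at the
    true label are clamped away from zero so the loss is always finite.
    """
    probabilities = np.asarray(probabilities, dtype=float)
    labels = np.asarray(labels, dtype=int)
    phi = np.asarray(phi, dtype=float)
    if phi_max is not None:
        phi = np.minimum(phi, phi_max)
    p_true = np.clip(probabilities[np.arange(labels.size), labels],
                     PROB_FLOOR, 1.0)
    return float(np.mean(phi[labels] * -np.log(p_true)))


def compute_batch_cost(
    batch_labels: np.ndarray,
    batch_predictions: np.ndarray,
    dataset_counts: np.ndarray,
    C: int,
) -> BatchCostState:
    """Recompute the full per-class cost state for one mini-batch.

    ``batch_predictions`` are the model's arg-max decisions on this batch
    from the forward pass that produces the loss. Classes absent from the
    batch inherit their dataset weight ``CW_D`` so the blend is finite.
    """
    batch_labels = np.asarray(batch_labels, dtype=int)
    if batch_labels.size == 0:
        raise ValueError("batch must be non-empty")
    dataset_counts = np.asarray(dataset_counts, dtype=float)

    batch_counts = np.bincount(batch_labels, minlength=C)
    cw_b = class_weights(batch_counts, int(batch_labels.size), C)
    cw_d = class_weights(dataset_counts, int(dataset_counts.sum()), C)
    cw_d = np.where(np.isnan(cw_d), 0.0, cw_d)  # class absent from the dataset
    cw_b = np.where(np.isnan(cw_b), cw_d, cw_b)
    cw = blend_weights(cw_b, cw_d)
    fpr, fnr = batch_rates(batch_labels, batch_predictions, C)
    hm = harmonic_cost(fpr, fnr)
    phi = misclassification_cost(cw, hm)
    return BatchCostState(
        CW_b=cw_b, CW_D=cw_d, CW=cw, FPR=fpr, FNR=fnr, HM_b=hm, phi=phi,
        batch_size=int(batch_labels.size),
    )
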