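"""Training losses, the consistency-weight ramp, and evaluation metrics.

The total objective is

    L = L_ce + omega(epoch) * L_consis + a * L_recon

with L_ce the supervised cross-entropy on labeled items, L_consis the
mean squared distance between student and teacher outputs on unlabeled
items, and L_recon the binary cross-entropy between the autoencoder
reconstruction and its min-max-normalized input.  omega ramps from 0 to
``omega_max`` over the first ``ramp_fraction`` of training (smooth
Gaussian-shaped ramp, exact at both endpoints) and then stays constant;
``a`` defaults to 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

LABEL_ORDER = ("truth", "lie")  # confusion-matrix axis order; 'lie' is positive
_EPS = 1e-12


@dataclass(frozen=True)
class LossWeights:
    omega_max: float = 1.0
    a: float = 0.5
    ramp_fraction: float = 0.3

    def __post_init__(self) -> None:
        if self.omega_max < 0 or self.a < 0 or self.ramp_fraction < 0:
            raise ValueError("loss weights must be >= 0")


def reconstruction_loss(inputs_01: np.ndarray, reconstructions: np.ndarray) -> float:
    """Mean elementwise binary cross-entropy, averaged over batch and feature.

    Inputs must lie in [0, 1] (min-max normalized IS09 vectors) and
    reconstructions in (0, 1) (sigmoid outputs).
    """
    x = np.atleast_2d(np.asarray(inputs_01, dtype=np.float64))
    r = np.atleast_2d(np.asarray(reconstructions, dtype=np.float64))
    if x.shape != r.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {r.shape}")
    if x.min() < 0 or x.max() > 1:
        raise ValueError("inputs must be within [0, 1]")
    if r.min() <= 0 or r.max() >= 1:
        raise ValueError("reconstructions must be within (0, 1)")
    return float(-np.mean(x * np.log(r) + (1.0 - x) * np.log(1.0 - r)))


def reconstruction_loss_grad(inputs_01: np.ndarray, reconstructions: np.ndarray) -> np.ndarray:
    """d L_recon / d reconstructions for the mean elementwise BCE."""
    x = np.atleast_2d(inputs_01)
    r = np.atleast_2d(reconstructions)
    return (-x / r + (1.0 - x) / (1.0 - r)) / x.size


def supervised_loss(probs: np.ndarray, labels: np.ndarray) -> float:
    """Mean cross-entropy between predicted class probabilities and labels.

    ``labels`` are integer class indices (0 = truth, 1 = lie).  An empty
    labeled batch is defined as loss 0.
    """
    probs = np.atleast_2d(np.asarray(probs, dtype=np.float64))
    labels = np.atleast_1d(np.asarray(labels))
    if labels.size == 0:
        return 0.0
    if probs.shape[0] != labels.size:
        raise ValueError("probs and labels disagree on batch size")
    if np.any(np.abs(probs.sum(axis=1) - 1.0) > 1e-6) or probs.min() < -1e-9:
        raise ValueError("probability rows must lie on the simplex")
    p_true = probs[np.arange(labels.size), labels]
    return float(-np.mean(np.log(np.clip(p_true, _EPS, 1.0))))


def consistency_loss(student_out: np.ndarray, teacher_out: np.ndarray,
                     reduce: str = "batchmean") -> float:
    """Mean squared distance between student and teacher outputs.

    ``batchmean`` (default) averages the squared Euclidean norms over
    the batch; ``elementwise`` additionally divides by the output
    dimension.
    """
    s = np.atleast_2d(np.asarray(student_out, dtype=np.float64))
    t = np.atleast_2d(np.asarray(teacher_out, dtype=np.float64))
    if s.shape != t.shape:
        raise ValueError(f"shape mismatch: {s.shape} vs {t.shape}")
    if s.shape[0] == 0:
        return 0.0
    sq = np.sum((s - t) ** 2, axis=1)
    if reduce == "batchmean":
        return float(np.mean(sq))
    if reduce == "elementwise":
        return float(np.mean(sq) / s.shape[1])
    raise ValueError(f"unknown reduce mode {reduce!r}")


def consistency_loss_grad(student_out: np.ndarray, teacher_out: np.ndarray,
                          reduce: str = "batchmean") -> np.ndarray:
    """Gradient of the consistency loss with respect to the student output."""
    s = np.atleast_2d(student_out)
    t = np.atleast_2d(teacher_out)
    g = 2.0 * (s - t) / s.shape[0]
    if reduce == "elementwise":
        g = g / s.shape[1]
    return g


def consistency_weight(epoch: int, n_epochs: int, weights: LossWeights) -> float:
    """omega(epoch): 0 at epoch 0, omega_max from the end of the ramp on.

    Smooth ramp omega_max * (exp(-5 (1-t)^2) - exp(-5)) / (1 - exp(-5))
    with t = epoch / ramp_epochs clipped to [0, 1]; monotone
    non-decreasing and exact at both endpoints.
    """
    if weights.omega_max == 0:
        return 0.0
    ramp_epochs = max(int(round(weights.ramp_fraction * n_epochs)), 1)
    t = min(max(epoch / ramp_epochs, 0.0), 1.0)
    e5 = np.exp(-5.0)
    return float(weights.omega_max * (np.exp(-5.0 * (1.0 - t) ** 2) - e5) / (1.0 - e5))


def total_loss(parts: tuple[float, float, float], weights: LossWeights,
               epoch: int, n_epochs: int) -> float:
    """L = L_ce + omega(epoch) * L_consis + a * L_recon."""
    l_ce, l_consis, l_recon = parts
    if min(l_ce, l_consis, l_recon) < 0:
        raise ValueError("component losses must be non-negative")
    return l_ce + consistency_weight(epoch, n_epochs, weights) * l_consis + weights.a * l_recon


def evaluate(predictions, truth) -> tuple[float, float, np.ndarray]:
    """Accuracy, f1 (positive class 'lie') and the 2x2 confusion matrix.

    accuracy = n_correct / N; f1 = 2 TP / (2 TP + FP + FN).  Confusion
    rows are the true class, columns the predicted class, both in the
    order (truth, lie).  Labels may be strings or 0/1 indices.
    """
    pred = _as_indices(predictions)
    true = _as_indices(truth)
    if pred.size == 0 or pred.size != true.size:
        raise ValueError("predictions and truth must be equal-length and non-empty")
    confusion = np.zeros((2, 2), dtype=int)
    for t, p in zip(true, pred):
        confusion[t, p] += 1
    accuracy = float(np.trace(confusion) / pred.size)
    tp = confusion[1, 1]
    fp = confusion[0, 1]
    fn = confusion[1, 0]
    f1 = float(2 * tp / (2 * tp + fp + fn)) if (2 * tp + fp + fn) > 0 else 0.0
    return accuracy, f1, confusion


def _as_indices(labels) -> np.ndarray:
    arr = np.asarray(labels)
    if arr.dtype.kind in "iub":
        return arr.astype(int)
    lookup = {name: i for i, name in enumerate(LABEL_ORDER)}
    try:
        return np.array([lookup[str(v)] for v in arr])
    except KeyError as err:
        raise ValueError(f"unknown class label {err.args[0]!r}") from None
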