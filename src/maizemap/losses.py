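"""Training losses: cross-entropy, center loss, and their weighted sum.

The classifier is trained on the composite loss L = L_ce + w * L_c, where
L_ce is the mean multiclass cross-entropy and L_c the center loss — half
the summed squared Euclidean distance between each sample's deep feature
and its class center.  The center loss shapes the 64-dim feature space into
compact per-class clusters; centers are maintained by an explicit running
update, not by the gradient optimizer.
"""

from __future__ import annotations

import numpy as np

EPS = 1e-12


def one_hot(labels: np.ndarray, n_classes: int) -> np.ndarray:
    labels = np.asarray(labels, int)
    q = np.zeros((labels.size, n_classes))
    q[np.arange(labels.size), labels] = 1.0
    return q


def cross_entropy(probs: np.ndarray, targets_onehot: np.ndarray) -> float:
    """Mean negative log-probability of the true class.

    ``probs`` rows are class distributions; ``targets_onehot`` rows are
    one-hot.  Probabilities are clipped to [1e-12, 1 - 1e-12] before the log.
    """
    p = np.clip(probs, EPS, 1.0 - EPS)
    n = probs.shape[0]
    return float(-(targets_onehot * np.log(p)).sum() / n)


def center_loss(features: np.ndarray, labels: np.ndarray,
                centers: np.ndarray) -> float:
    """L_c = 1/2 sum_i ||f_i - c_{y_i}||^2 (summed, not averaged)."""
    diff = features - centers[np.asarray(labels, int)]
    return float(0.5 * np.sum(diff * diff))


def total_loss(l_ce: float, l_c: float, weight: float) -> float:
    """L = L_ce + w * L_c."""
    return l_ce + weight * l_c


def center_loss_grad(features: np.ndarray, labels: np.ndarray,
                     centers: np.ndarray, weight: float) -> np.ndarray:
    """Gradient of w * L_c with respect to the features."""
    return weight * (features - centers[np.asarray(labels, int)])


def update_centers(centers: np.ndarray, features: np.ndarray,
                   labels: np.ndarray, alpha: float = 0.5) -> np.ndarray:
    """Running class-center update c_j <- c_j - alpha * mean_j(c_j - f_i).

    Only classes present in the batch move; alpha = 1 snaps a center to the
    batch mean of its class, alpha = 0 is a no-op.  Returns a new array.
    """
    if not (0.0 <= alpha <= 1.0):
        raise ValueError("alpha must be in [0, 1]")
    labels = np.asarray(labels, int)
    out = centers.copy()
    for j in np.unique(labels):
        sel = features[labels == j]
        delta = (out[j] - sel).mean(axis=0)
        out[j] = out[j] - alpha * delta
    return out
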