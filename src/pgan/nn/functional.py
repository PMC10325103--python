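"""Loss heads and their gradients.

Probabilities are clamped to [CLAMP, 1-CLAMP] before any logarithm so a
saturated head cannot produce an infinite loss.
"""

from __future__ import annotations

import numpy as np

CLAMP = 1e-7


def clamp_prob(p: np.ndarray | float) -> np.ndarray:
    return np.clip(p, CLAMP, 1.0 - CLAMP)


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=np.float64)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def softmax(x: np.ndarray) -> np.ndarray:
    z = x - x.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def bce_with_logits(logits: np.ndarray, target: float) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy against a constant 0/1 target.

    Returns (loss, dloss/dlogits). Computed from logits for stability.
    """
    p = clamp_prob(sigmoid(logits))
    if target == 1.0:
        loss = -np.log(p).mean()
    else:
        loss = -np.log(1.0 - p).mean()
    grad = (p - target) / logits.size
    return float(loss), grad


def cross_entropy_with_logits(logits: np.ndarray,
                              labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean categorical cross-entropy; labels are 0-based class indices.

    Returns (loss, dloss/dlogits).
    """
    n = logits.shape[0]
    p = softmax(logits)
    pc = clamp_prob(p[np.arange(n), labels])
    loss = -np.log(pc).mean()
    grad = p.copy()
    grad[np.arange(n), labels] -= 1.0
    grad /= n
    return float(loss), grad
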