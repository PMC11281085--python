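"""Softmax and multi-class cross-entropy with its analytic gradient."""

from __future__ import annotations

import warnings

import numpy as np

PROB_FLOOR = 1e-12


def softmax(logits: np.ndarray) -> np.ndarray:
    """Row-wise softmax, numerically stabilised by max subtraction."""
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy(probs: np.ndarray, onehot: np.ndarray) -> float:
    """L = -(1/N) sum_i sum_c y_ic log p_ic.

    Probabilities at a true class that underflow to < 1e-12 are clamped
    (with a warning) so the loss stays finite.
    """
    probs = np.asarray(probs, dtype=float)
    onehot = np.asarray(onehot, dtype=float)
    if probs.shape != onehot.shape:
        raise ValueError("probs and labels must have the same shape")
    picked = (probs * onehot).sum(axis=-1)
    if np.any(picked < PROB_FLOOR):
        warnings.warn(
            "true-class probability below 1e-12 clamped in cross-entropy",
            RuntimeWarning,
            stacklevel=2,
        )
        picked = np.clip(picked, PROB_FLOOR, None)
    return float(-np.mean(np.log(picked)))


def softmax_cross_entropy_grad(probs: np.ndarray, onehot: np.ndarray) -> np.ndarray:
    """d L / d logits for softmax followed by mean cross-entropy."""
    n = probs.shape[0]
    return ((probs - onehot) / n).astype(np.float32)
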