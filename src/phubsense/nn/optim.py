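"""SGD with classical momentum: v_t = gamma v_{t-1} + eta grad; theta -= v_t."""

from __future__ import annotations

import numpy as np


def sgd_momentum_step(
    theta: np.ndarray,
    gradient: np.ndarray,
    velocity: np.ndarray,
    learning_rate: float,
    momentum: float,
) -> tuple[np.ndarray, np.ndarray]:
    """One momentum-SGD update; returns (new_theta, new_velocity)."""
    theta = np.asarray(theta, dtype=float)
    gradient = np.asarray(gradient, dtype=float)
    velocity = np.asarray(velocity, dtype=float)
    if theta.shape != gradient.shape or theta.shape != velocity.shape:
        raise ValueError("theta, gradient and velocity must share a shape")
    new_velocity = momentum * velocity + learning_rate * gradient
    return theta - new_velocity, new_velocity


class SGDMomentum:
    """Applies the momentum update in place over a model's parameters."""

    def __init__(self, param_items, learning_rate: float = 0.01, momentum: float = 0.9):
        self.items = list(param_items)  # (layer, key) pairs
        self.lr = learning_rate
        self.momentum = momentum
        self.velocity = [np.zeros_like(layer.params[key]) for layer, key in self.items]

    def step(self) -> None:
        for idx, (layer, key) in enumerate(self.items):
            grad = layer.grads.get(key)
            if grad is None:
                continue
            v = self.momentum * self.velocity[idx] + self.lr * grad
            self.velocity[idx] = v.astype(layer.params[key].dtype)
            layer.params[key] -= self.velocity[idx]

    def zero_grad(self) -> None:
        for layer, key in self.items:
            layer.grads.pop(key, None)
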