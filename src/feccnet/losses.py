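"""Segmentation losses: BCE, Dice, their L2 hybrid, and a focal baseline.

Let y be the {0,1} ground-truth mask and p the predicted probabilities,
both flattened over every pixel of the batch (N pixels):

* ``bce``     −(1/N) Σ [ y ln p + (1−y) ln(1−p) ]           (mean-reduced)
* ``dice``    1 − (2 Σ y·p + δ) / (Σ y² + Σ p² + δ)
* ``hybrid``  sqrt(bce² + dice²)
* ``focal``   −(1/N) Σ [ α(1−p)^γ y ln p + (1−α) p^γ (1−y) ln(1−p) ]

δ (default 1e−15, sensible anywhere in [1e−15, 1e−13]) guards the Dice
denominator and lets all-background batches contribute gradient.
Probabilities are clamped to [ε, 1−ε] with ε = 1e−7 before logs.

Each loss has a matching ``*_grad`` giving the exact derivative w.r.t. the
predictions; the pairs are verified by finite differences in the tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError

EPS = 1e-7
DEFAULT_DELTA = 1e-15


@dataclass
class LossInputs:
    """Ground truth, predictions, and the Dice smoothing term."""

    y: np.ndarray
    y_hat: np.ndarray
    delta: float = DEFAULT_DELTA

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=np.float64)
        self.y_hat = np.asarray(self.y_hat, dtype=np.float64)
        if self.y.shape != self.y_hat.shape:
            raise ConfigurationError("y and y_hat must have the same shape")
        if self.delta <= 0:
            raise ConfigurationError("delta must be positive")


def _prep(y, y_hat):
    y = np.asarray(y, dtype=np.float64).ravel()
    p = np.clip(np.asarray(y_hat, dtype=np.float64).ravel(), EPS, 1.0 - EPS)
    return y, p


def bce_loss(y, y_hat) -> float:
    """Mean binary cross entropy over all pixels."""
    y, p = _prep(y, y_hat)
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


def bce_grad(y, y_hat) -> np.ndarray:
    """d bce / d y_hat; zero where the clamp is active (the loss is flat there)."""
    shape = np.shape(y_hat)
    y, p = _prep(y, y_hat)
    g = -(y / p - (1.0 - y) / (1.0 - p)) / y.size
    inside = (np.asarray(y_hat, dtype=np.float64).ravel() > EPS) & (
        np.asarray(y_hat, dtype=np.float64).ravel() < 1.0 - EPS
    )
    return np.where(inside, g, 0.0).reshape(shape)


def dice_loss(y, y_hat, delta: float = DEFAULT_DELTA) -> float:
    """Soft Dice loss over the flattened batch; in [0, 1).

    No probability clamping here (there are no logs): with exact zeros on
    both sides the δ terms cancel and all-background agreement scores 0.
    """
    if delta <= 0:
        raise ConfigurationError("delta must be positive")
    y = np.asarray(y, dtype=np.float64).ravel()
    p = np.asarray(y_hat, dtype=np.float64).ravel()
    num = 2.0 * np.dot(y, p) + delta
    den = np.dot(y, y) + np.dot(p, p) + delta
    return float(1.0 - num / den)


def dice_grad(y, y_hat, delta: float = DEFAULT_DELTA) -> np.ndarray:
    shape = np.shape(y_hat)
    y = np.asarray(y, dtype=np.float64).ravel()
    p = np.asarray(y_hat, dtype=np.float64).ravel()
    num = 2.0 * np.dot(y, p) + delta
    den = np.dot(y, y) + np.dot(p, p) + delta
    g = -(2.0 * y * den - num * 2.0 * p) / den**2
    return g.reshape(shape)


def hybrid_loss(y, y_hat, delta: float = DEFAULT_DELTA) -> float:
    """L2 combination sqrt(bce² + dice²); >= max and <= sum of the parts."""
    b = bce_loss(y, y_hat)
    d = dice_loss(y, y_hat, delta)
    return float(np.hypot(b, d))


def hybrid_grad(y, y_hat, delta: float = DEFAULT_DELTA) -> np.ndarray:
    b = bce_loss(y, y_hat)
    d = dice_loss(y, y_hat, delta)
    h = np.hypot(b, d)
    if h < 1e-300:
        return np.zeros(np.shape(y_hat))
    return (b * bce_grad(y, y_hat) + d * dice_grad(y, y_hat, delta)) / h


def focal_loss(y, y_hat, gamma: float = 2.0, alpha: float = 0.25) -> float:
    """Focal loss; at gamma=0 it reduces to alpha-weighted BCE."""
    if gamma < 0:
        raise ConfigurationError("gamma must be >= 0")
    if not 0.0 < alpha < 1.0:
        raise ConfigurationError("alpha must lie in (0, 1)")
    y, p = _prep(y, y_hat)
    pos = alpha * (1.0 - p) ** gamma * y * np.log(p)
    neg = (1.0 - alpha) * p**gamma * (1.0 - y) * np.log(1.0 - p)
    return float(-np.mean(pos + neg))


def focal_grad(y, y_hat, gamma: float = 2.0, alpha: float = 0.25) -> np.ndarray:
    shape = np.shape(y_hat)
    y, p = _prep(y, y_hat)
    q = 1.0 - p
    if gamma == 0.0:
        dpos = alpha * y / p
        dneg = -(1.0 - alpha) * (1.0 - y) / q
    else:
        dpos = alpha * y * (-gamma * q ** (gamma - 1.0) * np.log(p) + q**gamma / p)
        dneg = (1.0 - alpha) * (1.0 - y) * (gamma * p ** (gamma - 1.0) * np.log(q) - p**gamma / q)
    g = -(dpos + dneg) / y.size
    inside = (np.asarray(y_hat, dtype=np.float64).ravel() > EPS) & (
        np.asarray(y_hat, dtype=np.float64).ravel() < 1.0 - EPS
    )
    return np.where(inside, g, 0.0).reshape(shape)


def get_loss(name: str, **kwargs):
    """Return (value_fn, grad_fn) closures for a named loss."""
    if name == "bce":
        return (lambda y, p: bce_loss(y, p), lambda y, p: bce_grad(y, p))
    if name == "dice":
        delta = kwargs.get("delta", DEFAULT_DELTA)
        return (lambda y, p: dice_loss(y, p, delta), lambda y, p: dice_grad(y, p, delta))
    if name == "hybrid":
        delta = kwargs.get("delta", DEFAULT_DELTA)
        return (lambda y, p: hybrid_loss(y, p, delta), lambda y, p: hybrid_grad(y, p, delta))
    if name == "focal":
        gamma = kwargs.get("gamma", 2.0)
        alpha = kwargs.get("alpha", 0.25)
        return (
            lambda y, p: focal_loss(y, p, gamma, alpha),
            lambda y, p: focal_grad(y, p, gamma, alpha),
        )
    raise ConfigurationError(f"unknown loss '{name}'")
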