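"""Optimisation: back-propagated gradient descent with LR decay and shadow weights.

The loop is deliberately plain: per step, a seeded minibatch is drawn, exact
gradients of mean cross-entropy plus the L2 penalty are back-propagated, every
parameter takes one gradient-descent step at the exponentially decayed learning
rate R = r·d^(g/s), and the shadow copy of every parameter is pulled toward the
live value by S ← d_ema·S + (1−d_ema)·V.  Inference (``predict``) always uses
the shadow parameters — the sliding-average model — for robustness on test
data; live parameters are touched only during training.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .features import EncodedDataset, SplitIndex
from .network import (NetworkState, forward, init_network, l2_penalty,
                      layer_forward, relu, identity, softmax, cross_entropy)


@dataclass
class TrainConfig:
    """Optimiser settings.

    Defaults are engineering choices (the optimisation *rules* are fixed, their
    constants are not prescribed): base LR 0.1 decaying by 0.96 every 200 steps,
    L2 weight 1e−4, EMA decay 0.99, batch 128.
    """

    base_lr: float = 0.1
    decay_rate: float = 0.96
    decay_steps: int = 200
    staircase: bool = False
    l2_weight: float = 1e-4
    ema_decay: float = 0.99
    batch_size: int = 128
    max_steps: int = 5000
    seed: int = 0
    loss_log_interval: int = 50

    def __post_init__(self) -> None:
        if not 0 < self.decay_rate <= 1:
            raise ValueError("decay_rate must be in (0, 1]")
        if self.decay_steps < 1:
            raise ValueError("decay_steps must be >= 1")
        if not 0 < self.ema_decay < 1:
            raise ValueError("ema_decay must be in (0, 1)")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.max_steps < 1:
            raise ValueError("max_steps must be >= 1")
        if self.l2_weight < 0:
            raise ValueError("l2_weight must be >= 0")


@dataclass
class TrainTrace:
    """Per-logged-step records: (global step, learning rate, data loss, total loss)."""

    steps: list[int] = field(default_factory=list)
    learning_rates: list[float] = field(default_factory=list)
    data_losses: list[float] = field(default_factory=list)
    total_losses: list[float] = field(default_factory=list)

    def log(self, step: int, lr: float, data_loss: float, total_loss: float) -> None:
        self.steps.append(step)
        self.learning_rates.append(lr)
        self.data_losses.append(data_loss)
        self.total_losses.append(total_loss)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("step\tlearning_rate\tdata_loss\ttotal_loss\n")
            for row in zip(self.steps, self.learning_rates, self.data_losses, self.total_losses):
                fh.write("{}\t{:.10g}\t{:.10g}\t{:.10g}\n".format(*row))


def decayed_learning_rate(r: float, d: float, g: int | float, s: int,
                          staircase: bool = False) -> float:
    """Exponential decay R = r·d^(g/s); staircase floors the exponent."""
    exponent = math.floor(g / s) if staircase else g / s
    return r * d ** exponent


def ema_update(S, V, d: float):
    """Shadow update S' = d·S + (1−d)·V, elementwise."""
    if not 0 < d < 1:
        raise ValueError("ema decay must be in (0, 1)")
    return d * np.asarray(S) + (1 - d) * np.asarray(V)


def backprop_gradients(state: NetworkState, X: np.ndarray, Y: np.ndarray,
                       lam: float) -> list[tuple[np.ndarray, np.ndarray]]:
    """Exact gradients of mean cross-entropy + L2 penalty w.r.t. every w and b.

    Returns one (dW, db) pair per layer.  The softmax/cross-entropy pair gives
    the standard output-score gradient (p − y)/B; the L2 term contributes
    2·λ·w on each weight matrix and nothing on biases.
    """
    X = np.asarray(X, dtype=np.float64)
    Y = np.asarray(Y, dtype=np.float64)
    if X.ndim != 2 or X.shape[0] == 0:
        raise ValueError("batch must be a non-empty matrix")
    B = X.shape[0]

    # forward, caching post-activation outputs and pre-activation signs
    activations = [X]
    zs = []
    a = X
    for lp in state.layers[:-1]:
        z = a @ lp.w + lp.b
        zs.append(z)
        a = relu(z)
        activations.append(a)
    scores = a @ state.layers[-1].w + state.layers[-1].b
    probs = softmax(scores)
    loss = float(cross_entropy(probs, Y).mean()) + l2_penalty(state, lam)
    if not np.isfinite(loss):
        raise FloatingPointError(
            "non-finite training loss; lower the learning rate or shrink the initialisation")

    grads: list[tuple[np.ndarray, np.ndarray]] = [None] * len(state.layers)
    delta = (probs - Y) / B
    for li in range(len(state.layers) - 1, -1, -1):
        lp = state.layers[li]
        dW = activations[li].T @ delta + 2.0 * lam * lp.w
        db = delta.sum(axis=0)
        grads[li] = (dW, db)
        if li > 0:
            delta = (delta @ lp.w.T) * (zs[li - 1] > 0)
    return grads


def train(data: EncodedDataset, split: SplitIndex,
          hidden: Sequence[int] = (512, 256, 128, 64),
          cfg: TrainConfig | None = None,
          state: NetworkState | None = None) -> tuple[NetworkState, TrainTrace]:
    """Run the optimisation loop on the split's training rows.

    Fully reproducible: initialisation and minibatch sampling derive from
    ``cfg.seed`` alone.  An existing ``state`` may be passed to continue
    training; otherwise one is initialised from ``hidden``.
    """
    cfg = cfg or TrainConfig()
    train_rows = np.asarray(split.train_rows, dtype=np.intp)
    if len(train_rows) == 0:
        raise ValueError("empty training split")
    if max(split.train_rows + split.test_rows) >= data.n_samples:
        raise ValueError("split refers to rows outside the dataset")
    Xtr = data.X[train_rows].astype(np.float64)
    Ytr = data.Y[train_rows]
    if state is None:
        state = init_network(data.X.shape[1], data.classes, hidden=hidden, seed=cfg.seed,
                             collection_fingerprint=data.collection.fingerprint)
    rng = np.random.default_rng(cfg.seed)
    trace = TrainTrace()
    batch = min(cfg.batch_size, len(train_rows))

    for _ in range(cfg.max_steps):
        idx = rng.choice(len(train_rows), size=batch, replace=False)
        xb, yb = Xtr[idx], Ytr[idx]
        lr = decayed_learning_rate(cfg.base_lr, cfg.decay_rate, state.global_step,
                                   cfg.decay_steps, cfg.staircase)
        grads = backprop_gradients(state, xb, yb, cfg.l2_weight)
        for lp, (dW, db) in zip(state.layers, grads):
            lp.w -= lr * dW
            lp.b -= lr * db
        state.global_step += 1
        for live, sh in zip(state.layers, state.shadow):
            sh.w = ema_update(sh.w, live.w, cfg.ema_decay)
            sh.b = ema_update(sh.b, live.b, cfg.ema_decay)
        if state.global_step % cfg.loss_log_interval == 0 or state.global_step == 1:
            probs = forward(state, xb)
            data_loss = float(cross_entropy(probs, yb).mean())
            trace.log(state.global_step, lr, data_loss,
                      data_loss + l2_penalty(state, cfg.l2_weight))
    return state, trace


def predict(state: NetworkState, X: np.ndarray,
            collection_fingerprint: str | None = None) -> np.ndarray:
    """Class-probability matrix for ``X`` using the shadow (sliding-average) model."""
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    if X.shape[1] != state.n_inputs:
        raise ValueError(f"input width {X.shape[1]} != model input width {state.n_inputs}")
    if (collection_fingerprint and state.collection_fingerprint
            and collection_fingerprint != state.collection_fingerprint):
        raise ValueError("encoded data was built against a different Mutation Collection "
                         f"({collection_fingerprint} != {state.collection_fingerprint})")
    return forward(state, X, use_shadow=True)


def config_to_yaml(cfg: TrainConfig, path: str | Path) -> None:
    import yaml
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(cfg), fh, sort_keys=False)


def config_from_yaml(path: str | Path) -> TrainConfig:
    import yaml
    with open(path) as fh:
        return TrainConfig(**(yaml.safe_load(fh) or {}))
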