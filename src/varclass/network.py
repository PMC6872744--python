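"""Feed-forward softmax classifier: forward pass, loss and parameters.

The network is a stack of fully connected layers.  Each hidden unit computes
f(Σᵢ wᵢxᵢ + b) with f = ReLU; the output layer is linear and feeds a softmax
layer that turns scores into class probabilities.  Training minimises
cross-entropy H(y, y') = −Σ y'ᵢ log yᵢ (natural log) plus an L2 weight
penalty λ·Σ w² (biases excluded).

Every parameter has a *shadow* copy — an exponentially weighted moving average
maintained by the training loop — used for inference; see ``training``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

EPS = 1e-12  # probability clip before log


@dataclass
class LayerParams:
    """One fully connected layer: weights (inputs × units) and biases (units)."""

    w: np.ndarray
    b: np.ndarray

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=np.float64)
        self.b = np.asarray(self.b, dtype=np.float64)
        if self.w.ndim != 2 or self.b.ndim != 1 or self.w.shape[1] != self.b.shape[0]:
            raise ValueError(f"inconsistent layer shapes w{self.w.shape} b{self.b.shape}")
        if not (np.isfinite(self.w).all() and np.isfinite(self.b).all()):
            raise ValueError("layer parameters must be finite")

    def copy(self) -> "LayerParams":
        return LayerParams(self.w.copy(), self.b.copy())


@dataclass
class NetworkState:
    """Live parameters, their shadow (moving-average) copies and the training clock."""

    layers: list[LayerParams]
    shadow: list[LayerParams]
    global_step: int
    classes: list[str]
    collection_fingerprint: str | None = None

    def __post_init__(self) -> None:
        for a, b in zip(self.layers, self.layers[1:]):
            if a.w.shape[1] != b.w.shape[0]:
                raise ValueError("consecutive layer shapes do not chain")
        if self.layers[-1].w.shape[1] != len(self.classes):
            raise ValueError("output layer width must equal the number of classes")
        for live, sh in zip(self.layers, self.shadow):
            if live.w.shape != sh.w.shape or live.b.shape != sh.b.shape:
                raise ValueError("shadow shapes must mirror live shapes")

    @property
    def n_inputs(self) -> int:
        return self.layers[0].w.shape[0]


def _truncated_normal(rng: np.random.Generator, shape: tuple, std: float) -> np.ndarray:
    """Gaussian(0, std) with draws beyond 2·std resampled."""
    x = rng.normal(0.0, std, size=shape)
    bad = np.abs(x) > 2 * std
    while bad.any():
        x[bad] = rng.normal(0.0, std, size=int(bad.sum()))
        bad = np.abs(x) > 2 * std
    return x


def init_network(n_inputs: int, classes: Sequence[str],
                 hidden: Sequence[int] = (512, 256, 128, 64),
                 seed: int = 0, init_std: float = 0.1, bias_init: float = 0.1,
                 collection_fingerprint: str | None = None) -> NetworkState:
    """Seeded truncated-Gaussian initialisation; shadow starts equal to live."""
    if n_inputs < 1 or any(h < 1 for h in hidden):
        raise ValueError("layer widths must be positive")
    rng = np.random.default_rng(seed)
    widths = [n_inputs, *hidden, len(classes)]
    layers = [
        LayerParams(_truncated_normal(rng, (w_in, w_out), init_std),
                    np.full(w_out, bias_init, dtype=np.float64))
        for w_in, w_out in zip(widths, widths[1:])
    ]
    shadow = [lp.copy() for lp in layers]
    return NetworkState(layers, shadow, 0, list(classes), collection_fingerprint)


def relu(x):
    """Rectified linear unit, elementwise max(x, 0)."""
    return np.maximum(x, 0)


def identity(x):
    return x


def layer_forward(x: np.ndarray, layer: LayerParams,
                  activation: Callable = relu) -> np.ndarray:
    """One layer: activation(x·w + b).  Accepts a vector or a batch matrix."""
    x = np.asarray(x, dtype=np.float64)
    if x.shape[-1] != layer.w.shape[0]:
        raise ValueError(f"input width {x.shape[-1]} != layer input {layer.w.shape[0]}")
    return activation(x @ layer.w + layer.b)


def softmax(y: np.ndarray) -> np.ndarray:
    """Softmax over the last axis, computed with max-subtraction for stability."""
    y = np.asarray(y, dtype=np.float64)
    z = y - y.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy(y: np.ndarray, y_true: np.ndarray) -> np.ndarray:
    """H(y, y') = −Σ y'ᵢ log yᵢ per sample; predictions clipped to [EPS, 1]."""
    y = np.asarray(y, dtype=np.float64)
    y_true = np.asarray(y_true, dtype=np.float64)
    if y.shape != y_true.shape:
        raise ValueError(f"shape mismatch {y.shape} vs {y_true.shape}")
    return -(y_true * np.log(np.clip(y, EPS, 1.0))).sum(axis=-1)


def l2_penalty(layers: "NetworkState | Sequence[LayerParams]", lam: float) -> float:
    """λ · Σ over all weight entries of w²; biases excluded."""
    if lam < 0:
        raise ValueError("regularization weight must be >= 0")
    if isinstance(layers, NetworkState):
        layers = layers.layers
    return lam * float(sum(np.square(lp.w).sum() for lp in layers))


def forward(state: NetworkState, x: np.ndarray, use_shadow: bool = False) -> np.ndarray:
    """Full forward pass to class probabilities.

    Hidden layers use ReLU, the output layer is linear, and softmax converts
    scores to probabilities.  ``use_shadow`` evaluates with the moving-average
    parameters (inference mode); nothing is mutated either way.
    """
    params = state.shadow if use_shadow else state.layers
    a = np.asarray(x, dtype=np.float64)
    for lp in params[:-1]:
        a = layer_forward(a, lp, relu)
    scores = layer_forward(a, params[-1], identity)
    return softmax(scores)


def save_state(state: NetworkState, path: str | Path) -> None:
    """Serialize shapes, live and shadow parameters, step, classes, fingerprint."""
    arrays: dict[str, np.ndarray] = {}
    for i, (live, sh) in enumerate(zip(state.layers, state.shadow)):
        arrays[f"w{i}"] = live.w
        arrays[f"b{i}"] = live.b
        arrays[f"sw{i}"] = sh.w
        arrays[f"sb{i}"] = sh.b
    np.savez(
        path,
        n_layers=np.array(len(state.layers)),
        global_step=np.array(state.global_step),
        classes=np.array(state.classes, dtype=object),
        fingerprint=np.array(state.collection_fingerprint or ""),
        **arrays,
    )


def load_state(path: str | Path) -> NetworkState:
    with np.load(path, allow_pickle=True) as z:
        n = int(z["n_layers"])
        layers = [LayerParams(z[f"w{i}"], z[f"b{i}"]) for i in range(n)]
        shadow = [LayerParams(z[f"sw{i}"], z[f"sb{i}"]) for i in range(n)]
        classes = [str(c) for c in z["classes"]]
        fp = str(z["fingerprint"]) or None
        return NetworkState(layers, shadow, int(z["global_step"]), classes, fp)
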