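"""Minimal numpy neural-network primitives for the patch classifier.

Layers operate on NCHW float32 tensors and implement explicit
forward/backward passes so that stage freezing, the cosine learning-rate
schedule and SGD-with-momentum remain fully inspectable and deterministic
(single-threaded numpy, seeded initialization, no hidden global state).
"""

from __future__ import annotations

import hashlib

import numpy as np


class Layer:
    """Base layer: ``params``/``grads`` are dicts of named arrays."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError


def _im2col(x: np.ndarray, k: int, stride: int) -> np.ndarray:
    """(N, C, H, W) -> (N, C*k*k, L) patch matrix."""
    windows = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(2, 3))
    windows = windows[:, :, ::stride, ::stride]  # (N, C, oh, ow, k, k)
    n, c, oh, ow, _, _ = windows.shape
    cols = windows.transpose(0, 1, 4, 5, 2, 3).reshape(n, c * k * k, oh * ow)
    return np.ascontiguousarray(cols)


class Conv2d(Layer):
    def __init__(self, c_in: int, c_out: int, k: int = 3, stride: int = 2, rng=None) -> None:
        super().__init__()
        rng = rng or np.random.default_rng(0)
        fan_in = c_in * k * k
        self.k, self.stride = k, stride
        self.c_in, self.c_out = c_in, c_out
        self.params = {
            "W": (rng.standard_normal((c_out, fan_in)) * np.sqrt(2.0 / fan_in)).astype(
                np.float32
            ),
            "b": np.zeros(c_out, dtype=np.float32),
        }
        self._cache: tuple | None = None

    def out_hw(self, h: int, w: int) -> tuple[int, int]:
        return (h - self.k) // self.stride + 1, (w - self.k) // self.stride + 1

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, _, h, w = x.shape
        oh, ow = self.out_hw(h, w)
        cols = _im2col(x, self.k, self.stride)
        y = np.einsum("of,nfl->nol", self.params["W"], cols) + self.params["b"][None, :, None]
        self._cache = (x.shape, cols)
        return y.reshape(n, self.c_out, oh, ow)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x_shape, cols = self._cache  # type: ignore[misc]
        n, _, h, w = x_shape
        dyf = dy.reshape(n, self.c_out, -1)
        self.grads["W"] = np.einsum("nol,nfl->of", dyf, cols)
        self.grads["b"] = dyf.sum(axis=(0, 2))
        dcols = np.einsum("of,nol->nfl", self.params["W"], dyf)
        # col2im scatter-add
        k, s = self.k, self.stride
        oh, ow = self.out_hw(h, w)
        dcols = dcols.reshape(n, -1, k, k, oh, ow)
        dx = np.zeros(x_shape, dtype=np.float32)
        for i in range(k):
            for j in range(k):
                dx[:, :, i : i + oh * s : s, j : j + ow * s : s] += dcols[:, :, i, j]
        return dx


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class GlobalAvgPool(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        return np.broadcast_to(dy[:, :, None, None], self._shape).copy() / (h * w)


class Dense(Layer):
    def __init__(self, d_in: int, d_out: int, rng=None) -> None:
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.params = {
            "W": (rng.standard_normal((d_in, d_out)) * np.sqrt(2.0 / d_in)).astype(np.float32),
            "b": np.zeros(d_out, dtype=np.float32),
        }

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.grads["W"] = self._x.T @ dy
        self.grads["b"] = dy.sum(axis=0)
        return dy @ self.params["W"].T


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy_grad(logits: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy loss and its gradient w.r.t. the logits."""
    n = logits.shape[0]
    p = softmax(logits)
    loss = float(-np.log(np.clip(p[np.arange(n), labels], 1e-12, None)).mean())
    grad = p
    grad[np.arange(n), labels] -= 1.0
    return loss, grad / n


class StagedNet:
    """A backbone of ordered stages plus a classification head.

    ``stages`` is a list of layer lists (input to output); ``head`` maps the
    last stage's activations to class logits. Stage indices govern freezing:
    parameters of the first ``frozen_depth`` stages are never updated.
    """

    def __init__(self, stages: list[list[Layer]], head: list[Layer]) -> None:
        self.stages = stages
        self.head = head

    @property
    def n_stages(self) -> int:
        return len(self.stages)

    def _all_layers(self) -> list[tuple[int, Layer]]:
        out = []
        for si, stage in enumerate(self.stages):
            out.extend((si, layer) for layer in stage)
        out.extend((len(self.stages), layer) for layer in self.head)
        return out

    def forward(self, x: np.ndarray) -> np.ndarray:
        for _, layer in self._all_layers():
            x = layer.forward(x)
        return x

    def backward(self, dlogits: np.ndarray, stop_stage: int = 0) -> None:
        """Backpropagate, stopping once all layers below ``stop_stage`` remain."""
        layers = self._all_layers()
        dy = dlogits
        for si, layer in reversed(layers):
            if si < stop_stage:
                break
            dy = layer.backward(dy)

    def trainable_params(self, frozen_depth: int):
        """Yield (layer, name, array) triples of trainable parameters."""
        for si, layer in self._all_layers():
            if si < frozen_depth:
                continue
            for name in layer.params:
                yield layer, name, layer.params[name]

    def stage_checksums(self) -> list[str]:
        """One digest per stage (head appended last) over raw parameter bytes."""
        sums = []
        for stage in [*self.stages, self.head]:
            h = hashlib.sha256()
            for layer in stage:
                for name in sorted(layer.params):
                    h.update(np.ascontiguousarray(layer.params[name]).tobytes())
            sums.append(h.hexdigest())
        return sums


class SGD:
    """SGD with momentum and decoupled-from-nothing classic L2 weight decay."""

    def __init__(self, momentum: float = 0.9, weight_decay: float = 1e-4) -> None:
        self.momentum = momentum
        self.weight_decay = weight_decay
        self._velocity: dict[int, np.ndarray] = {}

    def step(self, net: StagedNet, frozen_depth: int, lr: float) -> None:
        for layer, name, param in net.trainable_params(frozen_depth):
            grad = layer.grads.get(name)
            if grad is None:
                continue
            if name == "W" and self.weight_decay:
                grad = grad + self.weight_decay * param
            key = id(layer) ^ hash(name)
            v = self._velocity.get(key)
            v = -lr * grad if v is None else self.momentum * v - lr * grad
            self._velocity[key] = v
            param += v.astype(param.dtype)
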