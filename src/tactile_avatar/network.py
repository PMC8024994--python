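"""Dual-branch tactile decision network, implemented in numpy.

Architecture (hyperparameters of the study's network): a touch branch of
three 1D convolutions (kernel size 4, ReLU) followed by max pooling (size
4) and flattening; a slide branch of two fully connected ReLU layers (400,
300) on the 500-bin sliding spectrum; a combined trunk of fully connected
ReLU layers (400, 200); and a softmax output with one node per material,
sorted smooth/soft -> rough. Trained by stochastic gradient descent with
momentum 0.9 and learning-rate decay 1e-6, under one of two loss modes:
mean-square error against a human decision histogram (the avatar mode) or
categorical cross-entropy against one-hot labels (the baseline mode).

Channel counts for the conv layers, the learning rate, epochs and batch
size are free choices (documented defaults); everything else is fixed by
the layer table above. The implementation is plain numpy so that training
is exactly reproducible from a seed on a single CPU thread.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["NetworkSpec", "AvatarNetwork", "build_network"]

_LOSS_MODES = ("histogram", "categorical")


@dataclass(frozen=True)
class NetworkSpec:
    """Layer table and optimizer settings for :class:`AvatarNetwork`."""

    n_touch: int = 400
    n_slide: int = 500
    n_outputs: int = 42
    conv_layers: int = 3
    kernel_size: int = 4
    conv_channels: int = 8
    pool_size: int = 4
    slide_hidden: tuple[int, ...] = (400, 300)
    trunk_hidden: tuple[int, ...] = (400, 200)
    loss_mode: str = "histogram"  # "histogram" (MSE) or "categorical" (CE)
    learning_rate: float = 0.01
    momentum: float = 0.9
    decay: float = 1e-6

    def __post_init__(self) -> None:
        if self.loss_mode not in _LOSS_MODES:
            raise ValueError(f"loss_mode must be one of {_LOSS_MODES}")
        if min(self.n_touch, self.n_slide, self.n_outputs) < 1:
            raise ValueError("layer widths must be positive")
        if self.conv_len_after() < 1:
            raise ValueError("touch input too short for the conv/pool stack")

    def conv_len_after(self) -> int:
        """Temporal length after the conv stack and max pooling."""
        length = self.n_touch
        for _ in range(self.conv_layers):
            length -= self.kernel_size - 1
        return length // self.pool_size

    def touch_flat_width(self) -> int:
        return self.conv_len_after() * self.conv_channels


def _relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _conv1d_valid(x: np.ndarray, w: np.ndarray, b: np.ndarray) -> np.ndarray:
    # x (B, L, Cin), w (K, Cin, Cout) -> (B, L-K+1, Cout)
    win = sliding_window_view(x, w.shape[0], axis=1)  # (B, L', Cin, K)
    return np.einsum("blck,kco->blo", win, w, optimize=True) + b


def _conv1d_backward(
    x: np.ndarray, w: np.ndarray, dout: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    k = w.shape[0]
    win = sliding_window_view(x, k, axis=1)
    dw = np.einsum("blck,blo->kco", win, dout, optimize=True)
    db = dout.sum(axis=(0, 1))
    dpad = np.pad(dout, ((0, 0), (k - 1, k - 1), (0, 0)))
    win2 = sliding_window_view(dpad, k, axis=1)  # (B, L, Cout, K)
    wflip = w[::-1]  # (K, Cin, Cout) reversed along K
    dx = np.einsum("blok,kco->blc", win2, wflip, optimize=True)
    return dx, dw, db


class AvatarNetwork:
    """The dual-branch network with seeded weights and SGD training."""

    def __init__(self, spec: NetworkSpec = NetworkSpec(), seed: int = 0):
        self.spec = spec
        self.seed = int(seed)
        rng = np.random.default_rng(seed)
        self.params: dict[str, np.ndarray] = {}
        k, cc = spec.kernel_size, spec.conv_channels
        cin = 1
        for i in range(spec.conv_layers):
            fan_in = k * cin
            self.params[f"conv{i}_w"] = rng.normal(
                0.0, np.sqrt(2.0 / fan_in), size=(k, cin, cc)
            )
            self.params[f"conv{i}_b"] = np.zeros(cc)
            cin = cc
        widths = [spec.n_slide, *spec.slide_hidden]
        for i in range(len(spec.slide_hidden)):
            self._init_dense(rng, f"slide{i}", widths[i], widths[i + 1])
        trunk_in = spec.touch_flat_width() + spec.slide_hidden[-1]
        widths = [trunk_in, *spec.trunk_hidden]
        for i in range(len(spec.trunk_hidden)):
            self._init_dense(rng, f"trunk{i}", widths[i], widths[i + 1])
        self._init_dense(
            rng, "out", spec.trunk_hidden[-1], spec.n_outputs, glorot=True
        )
        self._velocity = {n: np.zeros_like(p) for n, p in self.params.items()}
        self._iterations = 0

    def _init_dense(
        self,
        rng: np.random.Generator,
        name: str,
        n_in: int,
        n_out: int,
        glorot: bool = False,
    ) -> None:
        std = np.sqrt(1.0 / (n_in + n_out)) if glorot else np.sqrt(2.0 / n_in)
        self.params[f"{name}_w"] = rng.normal(0.0, std, size=(n_in, n_out))
        self.params[f"{name}_b"] = np.zeros(n_out)

    # ---------------------------------------------------------------- forward

    def _forward(
        self, touch: np.ndarray, slide: np.ndarray, want_cache: bool
    ) -> tuple[np.ndarray, dict]:
        p, spec = self.params, self.spec
        cache: dict = {}
        x = touch[:, :, None]  # (B, L, 1)
        conv_pre = []
        conv_in = [x]
        for i in range(spec.conv_layers):
            z = _conv1d_valid(x, p[f"conv{i}_w"], p[f"conv{i}_b"])
            conv_pre.append(z)
            x = _relu(z)
            conv_in.append(x)
        b, length, c = x.shape
        lp = length // spec.pool_size
        xp = x[:, : lp * spec.pool_size].reshape(b, lp, spec.pool_size, c)
        pool_arg = xp.argmax(axis=2)
        pooled = np.take_along_axis(xp, pool_arg[:, :, None, :], axis=2)[:, :, 0, :]
        touch_flat = pooled.reshape(b, -1)

        h = slide
        slide_pre, slide_in = [], [h]
        for i in range(len(spec.slide_hidden)):
            z = h @ p[f"slide{i}_w"] + p[f"slide{i}_b"]
            slide_pre.append(z)
            h = _relu(z)
            slide_in.append(h)

        combined = np.concatenate([touch_flat, h], axis=1)
        t = combined
        trunk_pre, trunk_in = [], [t]
        for i in range(len(spec.trunk_hidden)):
            z = t @ p[f"trunk{i}_w"] + p[f"trunk{i}_b"]
            trunk_pre.append(z)
            t = _relu(z)
            trunk_in.append(t)
        logits = t @ p["out_w"] + p["out_b"]
        probs = _softmax(logits)
        if want_cache:
            cache = {
                "conv_pre": conv_pre,
                "conv_in": conv_in,
                "pool_arg": pool_arg,
                "pool_shape": (b, lp, spec.pool_size, c, length),
                "slide_pre": slide_pre,
                "slide_in": slide_in,
                "trunk_pre": trunk_pre,
                "trunk_in": trunk_in,
                "touch_flat_width": touch_flat.shape[1],
                "probs": probs,
            }
        return probs, cache

    def predict_proba(self, touch: np.ndarray, slide: np.ndarray) -> np.ndarray:
        """Forward pass: (B, 400) touch + (B, 500) slide -> (B, M) probabilities."""
        touch = np.atleast_2d(np.asarray(touch, dtype=float))
        slide = np.atleast_2d(np.asarray(slide, dtype=float))
        if touch.shape[1] != self.spec.n_touch or slide.shape[1] != self.spec.n_slide:
            raise ValueError(
                f"expected input widths ({self.spec.n_touch}, {self.spec.n_slide}), "
                f"got ({touch.shape[1]}, {slide.shape[1]})"
            )
        probs, _ = self._forward(touch, slide, want_cache=False)
        return probs

    # --------------------------------------------------------------- backward

    def _backward(self, dlogits: np.ndarray, cache: dict) -> dict[str, np.ndarray]:
        p, spec = self.params, self.spec
        grads: dict[str, np.ndarray] = {}
        t_last = cache["trunk_in"][-1]
        grads["out_w"] = t_last.T @ dlogits
        grads["out_b"] = dlogits.sum(axis=0)
        dt = dlogits @ p["out_w"].T
        for i in reversed(range(len(spec.trunk_hidden))):
            dz = dt * (cache["trunk_pre"][i] > 0)
            grads[f"trunk{i}_w"] = cache["trunk_in"][i].T @ dz
            grads[f"trunk{i}_b"] = dz.sum(axis=0)
            dt = dz @ p[f"trunk{i}_w"].T
        ntf = cache["touch_flat_width"]
        dtouch_flat, dslide_out = dt[:, :ntf], dt[:, ntf:]

        dh = dslide_out
        for i in reversed(range(len(spec.slide_hidden))):
            dz = dh * (cache["slide_pre"][i] > 0)
            grads[f"slide{i}_w"] = cache["slide_in"][i].T @ dz
            grads[f"slide{i}_b"] = dz.sum(axis=0)
            dh = dz @ p[f"slide{i}_w"].T

        b, lp, ps, c, length = cache["pool_shape"]
        dpooled = dtouch_flat.reshape(b, lp, c)
        dxp = np.zeros((b, lp, ps, c))
        np.put_along_axis(dxp, cache["pool_arg"][:, :, None, :], dpooled[:, :, None, :], axis=2)
        dx = np.zeros((b, length, c))
        dx[:, : lp * ps] = dxp.reshape(b, lp * ps, c)
        for i in reversed(range(spec.conv_layers)):
            dz = dx * (cache["conv_pre"][i] > 0)
            dx, dw, db = _conv1d_backward(cache["conv_in"][i], p[f"conv{i}_w"], dz)
            grads[f"conv{i}_w"] = dw
            grads[f"conv{i}_b"] = db
        return grads

    # --------------------------------------------------------------- training

    @staticmethod
    def _check_targets(targets: np.ndarray, mode: str) -> np.ndarray:
        targets = np.asarray(targets, dtype=float)
        if np.any(targets < 0) or not np.allclose(targets.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError(
                "targets must be row-normalized distributions (one-hot rows are "
                "valid degenerate histograms)"
            )
        if mode == "categorical":
            onehot = np.isclose(targets.max(axis=1), 1.0, atol=1e-6)
            if not np.all(onehot):
                raise ValueError("categorical mode requires one-hot targets")
        return targets

    def _loss_and_dlogits(
        self, probs: np.ndarray, targets: np.ndarray, mode: str
    ) -> tuple[float, np.ndarray]:
        b, j = probs.shape
        if mode == "histogram":
            diff = probs - targets
            loss = float(np.mean(diff**2))
            dprobs = 2.0 * diff / (b * j)
            inner = (dprobs * probs).sum(axis=1, keepdims=True)
            dlogits = probs * (dprobs - inner)
        else:
            eps = 1e-12
            loss = float(-np.mean((targets * np.log(probs + eps)).sum(axis=1)))
            dlogits = (probs - targets) / b
        return loss, dlogits

    def train(
        self,
        touch: np.ndarray,
        slide: np.ndarray,
        targets: np.ndarray,
        epochs: int = 60,
        batch_size: int = 32,
        seed: int = 0,
        mode: str | None = None,
        learning_rate: float | None = None,
    ) -> list[float]:
        """SGD training; returns the per-epoch mean loss history.

        ``targets`` are per-sample rank distributions: the paired human's
        per-material decision histogram in ``histogram`` (MSE) mode, or
        one-hot rows in ``categorical`` (cross-entropy) mode. Deterministic
        for a fixed seed.
        """
        mode = self.spec.loss_mode if mode is None else mode
        if mode not in _LOSS_MODES:
            raise ValueError(f"mode must be one of {_LOSS_MODES}")
        touch = np.asarray(touch, dtype=float)
        slide = np.asarray(slide, dtype=float)
        targets = self._check_targets(targets, mode)
        if not (len(touch) == len(slide) == len(targets)):
            raise ValueError("touch, slide and targets must align")
        lr0 = self.spec.learning_rate if learning_rate is None else learning_rate
        rng = np.random.default_rng(seed)
        n = len(touch)
        history: list[float] = []
        for _ in range(epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, batch_size):
                idx = order[start : start + batch_size]
                probs, cache = self._forward(touch[idx], slide[idx], want_cache=True)
                loss, dlogits = self._loss_and_dlogits(probs, targets[idx], mode)
                grads = self._backward(dlogits, cache)
                lr = lr0 / (1.0 + self.spec.decay * self._iterations)
                for name, g in grads.items():
                    v = self._velocity[name]
                    v *= self.spec.momentum
                    v -= lr * g
                    self.params[name] += v
                self._iterations += 1
                epoch_loss += loss * len(idx)
            history.append(epoch_loss / n)
        if not all(np.isfinite(history)):
            raise FloatingPointError("training diverged: non-finite loss")
        return history

    # ------------------------------------------------------------ persistence

    def save(self, path) -> None:
        """Self-describing checkpoint: spec JSON + weights in one .npz."""
        meta = json.dumps(asdict(self.spec))
        np.savez(
            path,
            __spec__=np.frombuffer(meta.encode(), dtype=np.uint8),
            __seed__=np.array([self.seed]),
            **self.params,
        )

    @classmethod
    def load(cls, path) -> "AvatarNetwork":
        with np.load(path) as data:
            meta = json.loads(bytes(data["__spec__"]).decode())
            for key in ("slide_hidden", "trunk_hidden"):
                meta[key] = tuple(meta[key])
            net = cls(NetworkSpec(**meta), seed=int(data["__seed__"][0]))
            for name in net.params:
                net.params[name] = data[name]
        return net


def build_network(spec: NetworkSpec = NetworkSpec(), seed: int = 0) -> AvatarNetwork:
    """Build an initialized network with seeded weights."""
    return AvatarNetwork(spec, seed)
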