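"""Minimal feed-forward / 1D-convolutional neural network in numpy.

Supports exactly what the localization models need: dense layers,
1D valid convolution, max pooling, batch normalization, dropout, ReLU
and sigmoid activations, binary cross-entropy loss, and Adam.  Training
is fully deterministic under a fixed seed (single-threaded numpy, no
backend nondeterminism).

Shapes: dense layers take (N, D); convolutional stacks take (N, L, C)
with C channels, and ``Flatten`` bridges to the dense head.
"""

from __future__ import annotations

import numpy as np


class Layer:
    params: list = []
    grads: list = []

    def forward(self, x, training: bool):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, grad):  # pragma: no cover - interface
        raise NotImplementedError


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        # He-normal init, appropriate for the ReLU stacks used here
        self.W = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out))
        self.b = np.zeros(n_out)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x, training):
        self._x = x
        return x @ self.W + self.b

    def backward(self, grad):
        self.grads[0][...] = self._x.T @ grad
        self.grads[1][...] = grad.sum(axis=0)
        return grad @ self.W.T


class ReLU(Layer):
    def forward(self, x, training):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class Sigmoid(Layer):
    def forward(self, x, training):
        self._y = 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))
        return self._y

    def backward(self, grad):
        return grad * self._y * (1.0 - self._y)


class Dropout(Layer):
    def __init__(self, rate: float, rng: np.random.Generator):
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must be in [0,1), got {rate}")
        self.rate = rate
        self.rng = rng

    def forward(self, x, training):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask


class BatchNorm(Layer):
    """Batch normalization over the sample axis of (N, D) activations."""

    def __init__(self, dim: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = np.ones(dim)
        self.beta = np.zeros(dim)
        self.params = [self.gamma, self.beta]
        self.grads = [np.zeros_like(self.gamma), np.zeros_like(self.beta)]
        self.momentum = momentum
        self.eps = eps
        self.running_mean = np.zeros(dim)
        self.running_var = np.ones(dim)

    def forward(self, x, training):
        if training:
            mean = x.mean(axis=0)
            var = x.var(axis=0)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        self._std = np.sqrt(var + self.eps)
        self._xhat = (x - mean) / self._std
        self._training = training
        return self.gamma * self._xhat + self.beta

    def backward(self, grad):
        self.grads[0][...] = (grad * self._xhat).sum(axis=0)
        self.grads[1][...] = grad.sum(axis=0)
        if not self._training:
            return grad * self.gamma / self._std
        n = grad.shape[0]
        gx = grad * self.gamma
        return (gx - gx.mean(axis=0)
                - self._xhat * (gx * self._xhat).mean(axis=0)) / self._std


class Conv1D(Layer):
    """Valid (no padding) 1D convolution on (N, L, C_in) -> (N, L-k+1, C_out)."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator):
        fan_in = kernel * c_in
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(kernel * c_in, c_out))
        self.b = np.zeros(c_out)
        self.kernel = kernel
        self.c_in = c_in
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def _im2col(self, x):
        # (N, L, C) -> (N, Lout, kernel*C)
        win = np.lib.stride_tricks.sliding_window_view(x, self.kernel, axis=1)
        # win: (N, Lout, C, kernel) -> reorder to (N, Lout, kernel, C)
        return np.ascontiguousarray(win.transpose(0, 1, 3, 2)).reshape(
            x.shape[0], -1, self.kernel * self.c_in)

    def forward(self, x, training):
        self._x_shape = x.shape
        self._cols = self._im2col(x)
        return self._cols @ self.W + self.b

    def backward(self, grad):
        n, lout, _ = grad.shape
        cols2d = self._cols.reshape(-1, self.W.shape[0])
        grad2d = grad.reshape(-1, self.W.shape[1])
        self.grads[0][...] = cols2d.T @ grad2d
        self.grads[1][...] = grad2d.sum(axis=0)
        dcols = (grad2d @ self.W.T).reshape(n, lout, self.kernel, self.c_in)
        dx = np.zeros(self._x_shape)
        for j in range(self.kernel):
            dx[:, j:j + lout, :] += dcols[:, :, j, :]
        return dx


class MaxPool1D(Layer):
    """Max pooling by an integer factor along the length axis; tail truncated."""

    def __init__(self, factor: int):
        self.factor = factor

    def forward(self, x, training):
        n, length, c = x.shape
        lout = length // self.factor
        self._in_len = length
        xr = x[:, :lout * self.factor, :].reshape(n, lout, self.factor, c)
        self._argmax = xr.argmax(axis=2)
        return xr.max(axis=2)

    def backward(self, grad):
        n, lout, c = grad.shape
        dxr = np.zeros((n, lout, self.factor, c))
        ni, li, ci = np.ogrid[:n, :lout, :c]
        dxr[ni, li, self._argmax, ci] = grad
        dx = np.zeros((n, self._in_len, c))
        dx[:, :lout * self.factor, :] = dxr.reshape(n, lout * self.factor, c)
        return dx


class Flatten(Layer):
    def forward(self, x, training):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Reshape(Layer):
    """(N, D) -> (N, D, channels) entry into a convolutional stack."""

    def __init__(self, channels: int = 1):
        self.channels = channels

    def forward(self, x, training):
        return x.reshape(x.shape[0], -1, self.channels)

    def backward(self, grad):
        return grad.reshape(grad.shape[0], -1)


class Adam:
    def __init__(self, layers, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.layers = [l for l in layers if l.params]
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [[np.zeros_like(p) for p in l.params] for l in self.layers]
        self.v = [[np.zeros_like(p) for p in l.params] for l in self.layers]
        self.t = 0

    def step(self):
        self.t += 1
        for li, layer in enumerate(self.layers):
            for pi, (p, g) in enumerate(zip(layer.params, layer.grads)):
                m = self.m[li][pi]
                v = self.v[li][pi]
                m[...] = self.beta1 * m + (1 - self.beta1) * g
                v[...] = self.beta2 * v + (1 - self.beta2) * g * g
                mhat = m / (1 - self.beta1**self.t)
                vhat = v / (1 - self.beta2**self.t)
                p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def bce_loss(y_hat: np.ndarray, y: np.ndarray,
             sample_weight: np.ndarray | None = None) -> float:
    eps = 1e-12
    terms = -(y * np.log(y_hat + eps) + (1 - y) * np.log(1 - y_hat + eps))
    if sample_weight is not None:
        terms = terms * sample_weight.reshape(-1, *([1] * (terms.ndim - 1)))
    return float(terms.mean())


class Network:
    """A sequential stack with BCE training via Adam.

    The final layer is expected to be a :class:`Sigmoid` so the combined
    sigmoid + cross-entropy gradient (y_hat - y)/N can be used; the
    sigmoid's own backward is bypassed for stability.
    """

    def __init__(self, layers: list[Layer]):
        if not isinstance(layers[-1], Sigmoid):
            raise ValueError("Network expects a Sigmoid output layer")
        self.layers = layers

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def _backward_from_logits_grad(self, grad):
        for layer in reversed(self.layers[:-1]):
            grad = layer.backward(grad)

    def fit(self, X: np.ndarray, Y: np.ndarray, *, epochs: int = 50,
            batch_size: int = 32, lr: float = 1e-3, seed: int = 0,
            sample_weight: np.ndarray | None = None,
            validation_fraction: float = 0.0, patience: int = 10,
            shuffle: bool = True) -> list[float]:
        """Train with minibatch Adam; returns the per-epoch training loss.

        With ``validation_fraction`` > 0, a tail split is held out and
        training stops once its loss has not improved for ``patience``
        epochs (the usual early-stopping rule).
        """
        rng = np.random.default_rng(seed)
        X = np.asarray(X, dtype=float)
        Y = np.asarray(Y, dtype=float)
        if Y.ndim == 1:
            Y = Y[:, None]
        n = X.shape[0]
        n_val = int(round(validation_fraction * n))
        if n_val > 0:
            perm = rng.permutation(n)
            val_idx, tr_idx = perm[:n_val], perm[n_val:]
            Xv, Yv = X[val_idx], Y[val_idx]
            X, Y = X[tr_idx], Y[tr_idx]
            if sample_weight is not None:
                sample_weight = sample_weight[tr_idx]
            n = X.shape[0]
        opt = Adam(self.layers, lr=lr)
        history: list[float] = []
        best_val, stale = np.inf, 0
        for _ in range(epochs):
            order = rng.permutation(n) if shuffle else np.arange(n)
            epoch_loss = 0.0
            for start in range(0, n, batch_size):
                idx = order[start:start + batch_size]
                xb, yb = X[idx], Y[idx]
                y_hat = self.forward(xb, training=True)
                wb = None if sample_weight is None else sample_weight[idx]
                epoch_loss += bce_loss(y_hat, yb, wb) * len(idx)
                grad = (y_hat - yb) / len(idx)
                if wb is not None:
                    grad = grad * wb.reshape(-1, *([1] * (grad.ndim - 1)))
                self._backward_from_logits_grad(grad)
                opt.step()
            history.append(epoch_loss / n)
            if n_val > 0:
                val_loss = bce_loss(self.forward(Xv), Yv)
                if val_loss < best_val - 1e-6:
                    best_val, stale = val_loss, 0
                else:
                    stale += 1
                    if stale >= patience:
                        break
        return history
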