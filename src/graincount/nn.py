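"""Minimal NumPy neural-network layers for density-map regression.

Implements exactly the pieces the two counting architectures need —
same-padded 2-D convolution, ReLU, 2x2 max-pooling, stride-2 2x2
transposed convolution — with hand-written reverse-mode gradients and a
momentum-SGD optimizer. Everything runs in float32 and tensors are laid
out channels-last, NHWC (batch, height, width, channels): convolutions
then reduce to im2col + one BLAS matmul with no layout transposes, which
is what makes CPU training of the encoder–decoder networks tractable.

Gradient notes: ReLU uses the standard subgradient ReLU'(0) = 0; max-pool
routes the gradient to the first maximum on ties.
"""

from __future__ import annotations

import numpy as np

F32 = np.float32


def orthogonal_init(rows: int, cols: int, rng: np.random.Generator) -> np.ndarray:
    """Orthogonal (rows x cols) float32 matrix, deterministic for a given rng."""
    a = rng.standard_normal((max(rows, cols), min(rows, cols)))
    q, r = np.linalg.qr(a)
    # sign correction makes the QR decomposition unique -> reproducible
    q *= np.sign(np.diag(r))
    q = q.T if rows < cols else q
    return np.ascontiguousarray(q[:rows, :cols], dtype=F32)


class Layer:
    """Base class: forward caches what backward needs; params/grads paired."""

    def params_grads(self) -> list[tuple[np.ndarray, np.ndarray]]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError


class Conv2d(Layer):
    """k x k same-padded convolution, stride 1, NHWC.

    The weight is stored as a (k*k*cin, cout) matrix whose row index is
    (di*k + dj)*cin + c, i.e. a flattened (k, k, cin, cout) kernel. Bias
    starts at zero; weights are orthogonally initialized.
    """

    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator):
        if k % 2 != 1 or k < 1:
            raise ValueError(f"kernel size must be odd and >= 1, got {k}")
        self.cin, self.cout, self.k = cin, cout, k
        self.w = np.ascontiguousarray(orthogonal_init(cout, k * k * cin, rng).T)
        self.b = np.zeros(cout, dtype=F32)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self._cols: np.ndarray | None = None
        self._xshape: tuple[int, ...] | None = None

    def params_grads(self):
        return [(self.w, self.dw), (self.b, self.db)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, h, w, c = x.shape
        if c != self.cin:
            raise ValueError(f"expected {self.cin} input channels, got {c}")
        self._xshape = x.shape
        k, p = self.k, self.k // 2
        if k == 1:
            cols = x.reshape(n * h * w, c)
        else:
            xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
            cols = np.empty((n, h, w, k * k, c), dtype=F32)
            for di in range(k):
                for dj in range(k):
                    cols[:, :, :, di * k + dj, :] = xp[:, di : di + h, dj : dj + w, :]
            cols = cols.reshape(n * h * w, k * k * c)
        self._cols = cols
        y = cols @ self.w
        y += self.b
        return y.reshape(n, h, w, self.cout)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, h, w, c = self._xshape
        k, p = self.k, self.k // 2
        dyf = dy.reshape(n * h * w, self.cout)
        self.db[...] = dyf.sum(axis=0)
        self.dw[...] = self._cols.T @ dyf
        dcols = dyf @ self.w.T
        self._cols = None
        if k == 1:
            return dcols.reshape(n, h, w, c)
        dcols = dcols.reshape(n, h, w, k * k, c)
        dxp = np.zeros((n, h + 2 * p, w + 2 * p, c), dtype=F32)
        for di in range(k):
            for dj in range(k):
                dxp[:, di : di + h, dj : dj + w, :] += dcols[:, :, :, di * k + dj, :]
        return np.ascontiguousarray(dxp[:, p : p + h, p : p + w, :])


class ReLU(Layer):
    def __init__(self):
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, F32(0.0))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dy, F32(0.0))


class MaxPool2(Layer):
    """2x2 max pooling, stride 2, NHWC. Spatial dims must be even."""

    def __init__(self):
        self._idx: np.ndarray | None = None
        self._xshape: tuple[int, ...] | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, h, w, c = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"max-pool needs even spatial dims, got {h}x{w}")
        self._xshape = x.shape
        xr = x.reshape(n, h // 2, 2, w // 2, 2, c).transpose(0, 1, 3, 2, 4, 5)
        xr = np.ascontiguousarray(xr).reshape(n, h // 2, w // 2, 4, c)
        self._idx = xr.argmax(axis=3)
        return np.take_along_axis(xr, self._idx[:, :, :, None, :], axis=3)[:, :, :, 0, :]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, h, w, c = self._xshape
        dxr = np.zeros((n, h // 2, w // 2, 4, c), dtype=F32)
        np.put_along_axis(dxr, self._idx[:, :, :, None, :], dy[:, :, :, None, :], axis=3)
        dxr = dxr.reshape(n, h // 2, w // 2, 2, 2, c).transpose(0, 1, 3, 2, 4, 5)
        return np.ascontiguousarray(dxr).reshape(n, h, w, c)


class ConvTranspose2x2(Layer):
    """2x2 transposed convolution with stride 2 (exact x2 upsampling), NHWC.

    Kernel and stride coincide so output patches do not overlap:
    y[2i+di, 2j+dj, co] = sum_ci w[ci, (di*2+dj)*cout+co] * x[i, j, ci] + b.
    """

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        self.cin, self.cout = cin, cout
        self.w = orthogonal_init(cin, 4 * cout, rng)
        self.b = np.zeros(cout, dtype=F32)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self._xf: np.ndarray | None = None

    def params_grads(self):
        return [(self.w, self.dw), (self.b, self.db)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, h, w, c = x.shape
        if c != self.cin:
            raise ValueError(f"expected {self.cin} input channels, got {c}")
        xf = x.reshape(n * h * w, c)
        self._xf = xf
        y = (xf @ self.w).reshape(n, h, w, 2, 2, self.cout)
        y = np.ascontiguousarray(y.transpose(0, 1, 3, 2, 4, 5)).reshape(
            n, 2 * h, 2 * w, self.cout
        )
        y += self.b
        self._hw = (h, w)
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        h, w = self._hw
        n = dy.shape[0]
        self.db[...] = dy.sum(axis=(0, 1, 2))
        dyr = dy.reshape(n, h, 2, w, 2, self.cout).transpose(0, 1, 3, 2, 4, 5)
        dyf = np.ascontiguousarray(dyr).reshape(n * h * w, 4 * self.cout)
        self.dw[...] = self._xf.T @ dyf
        dx = (dyf @ self.w.T).reshape(n, h, w, self.cin)
        self._xf = None
        return dx


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def params_grads(self):
        out = []
        for lyr in self.layers:
            out.extend(lyr.params_grads())
        return out

    def forward(self, x: np.ndarray) -> np.ndarray:
        for lyr in self.layers:
            x = lyr.forward(x)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for lyr in reversed(self.layers):
            dy = lyr.backward(dy)
        return dy


class SGD:
    """Momentum SGD with L2 weight decay:

    g <- grad + weight_decay * w;  v <- momentum * v + g;  w <- w - lr * v
    """

    def __init__(self, params_grads, momentum: float = 0.0, weight_decay: float = 0.0):
        self.params_grads = params_grads
        self.momentum = F32(momentum)
        self.weight_decay = F32(weight_decay)
        self.velocity = [np.zeros_like(p) for p, _ in params_grads]

    def step(self, lr: float) -> None:
        lr = F32(lr)
        for (p, g), v in zip(self.params_grads, self.velocity):
            gg = g if self.weight_decay == 0 else g + self.weight_decay * p
            v *= self.momentum
            v += gg
            p -= lr * v

    def zero_grad(self) -> None:
        for _, g in self.params_grads:
            g[...] = 0


def mse_loss(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean squared error over all elements and its gradient w.r.t. pred."""
    diff = pred - target
    loss = float(np.mean(diff.astype(np.float64) ** 2))
    grad = (F32(2.0 / diff.size) * diff).astype(F32)
    return loss, grad
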