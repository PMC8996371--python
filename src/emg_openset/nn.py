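"""A compact NumPy neural-network core.

The electrode-grid images here are tiny (12 x 8 x 3), so the convolutional
classifier and the dense autoencoders are implemented directly in NumPy:
2-D cross-correlation layers (the forward pass O_{x,y} = f(sum_ij W_ij *
I_{x+i,y+j} + b)), dense layers, ReLU, inverted dropout, a fused
softmax/cross-entropy head, and the AdaDelta and plain-SGD optimizers.
Everything is float32, seeded and single-threaded deterministic.

Layers follow a minimal protocol: ``forward(x, train, rng)``, ``backward(g)``
returning the gradient w.r.t. the input, and ``params`` / ``grads`` lists of
matching arrays.
"""

from __future__ import annotations

import numpy as np

EPS_LOG = 1e-12


# ---------------------------------------------------------------------------
# reference-style public op
# ---------------------------------------------------------------------------

def conv2d_forward(image, filt, bias: float = 0.0, activation=None, padding: str = "valid"):
    """Single-channel 2-D convolution (cross-correlation) with optional activation.

    ``O[x, y] = f(sum_i sum_j W[i, j] * I[x + i, y + j] + b)`` over the chosen
    padding regime ("valid" or zero-padded "same").
    """
    image = np.asarray(image, dtype=float)
    filt = np.asarray(filt, dtype=float)
    kh, kw = filt.shape
    if padding == "same":
        ph, pw = (kh - 1) // 2, (kw - 1) // 2
        image = np.pad(image, ((ph, kh - 1 - ph), (pw, kw - 1 - pw)))
    elif padding != "valid":
        raise ValueError("padding must be 'valid' or 'same'")
    h, w = image.shape
    if kh > h or kw > w:
        raise ValueError("filter larger than (padded) input")
    out = np.empty((h - kh + 1, w - kw + 1))
    for i in range(kh):
        for j in range(kw):
            block = image[i : i + out.shape[0], j : j + out.shape[1]]
            out = out + filt[i, j] * block if (i or j) else filt[i, j] * block.copy()
    out = out + bias
    return activation(out) if activation is not None else out


def relu(x):
    return np.maximum(x, 0)


def softmax(z):
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy(p, y_onehot) -> float:
    """Multiclass cross-entropy, natural log; zero probabilities clipped."""
    p = np.asarray(p, dtype=float)
    y = np.asarray(y_onehot, dtype=float)
    return float(-np.sum(y * np.log(np.clip(p, EPS_LOG, None))))


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------

def he_uniform(shape, fan_in: int, rng: np.random.Generator) -> np.ndarray:
    limit = np.sqrt(6.0 / fan_in)
    return rng.uniform(-limit, limit, size=shape).astype(np.float32)


class Layer:
    params: list = []
    grads: list = []

    def forward(self, x, train: bool = False, rng: np.random.Generator | None = None):
        raise NotImplementedError

    def backward(self, grad):
        raise NotImplementedError


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.W = he_uniform((n_in, n_out), n_in, rng)
        self.b = np.zeros(n_out, dtype=np.float32)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x, train=False, rng=None):
        self._x = x
        return x @ self.W + self.b

    def backward(self, grad):
        self.grads[0][...] = self._x.T @ grad
        self.grads[1][...] = grad.sum(axis=0)
        return grad @ self.W.T


class Conv2DSame(Layer):
    """3x3 (or kxk) cross-correlation with zero 'same' padding, NHWC layout."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        self.k = k
        self.W = he_uniform((k, k, c_in, c_out), k * k * c_in, rng)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def _pad(self, x):
        p0 = (self.k - 1) // 2
        p1 = self.k - 1 - p0
        return np.pad(x, ((0, 0), (p0, p1), (p0, p1), (0, 0)))

    def forward(self, x, train=False, rng=None):
        self._xpad = self._pad(x)
        n, h, w, _ = x.shape
        out = np.zeros((n, h, w, self.W.shape[-1]), dtype=np.float32)
        for i in range(self.k):
            for j in range(self.k):
                out += self._xpad[:, i : i + h, j : j + w, :] @ self.W[i, j]
        return out + self.b

    def backward(self, grad):
        n, h, w, _ = grad.shape
        gxpad = np.zeros_like(self._xpad)
        gW, gb = self.grads
        gW[...] = 0.0
        for i in range(self.k):
            for j in range(self.k):
                patch = self._xpad[:, i : i + h, j : j + w, :]
                gW[i, j] = np.einsum("nhwc,nhwo->co", patch, grad)
                gxpad[:, i : i + h, j : j + w, :] += grad @ self.W[i, j].T
        gb[...] = grad.sum(axis=(0, 1, 2))
        p0 = (self.k - 1) // 2
        return gxpad[:, p0 : p0 + h, p0 : p0 + w, :]


class ReLU(Layer):
    def forward(self, x, train=False, rng=None):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class Flatten(Layer):
    def forward(self, x, train=False, rng=None):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Dropout(Layer):
    """Inverted dropout; ``p_drop`` is the probability of zeroing a unit."""

    def __init__(self, p_drop: float):
        if not 0.0 <= p_drop < 1.0:
            raise ValueError("drop probability must be in [0, 1)")
        self.p_drop = p_drop

    def forward(self, x, train=False, rng=None):
        if not train or self.p_drop == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.p_drop
        self._mask = (rng.random(x.shape) < keep).astype(np.float32) / keep
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask


class Sequential:
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x, train: bool = False, rng: np.random.Generator | None = None):
        for layer in self.layers:
            x = layer.forward(x, train=train, rng=rng)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    @property
    def params(self):
        return [p for layer in self.layers for p in layer.params]

    @property
    def grads(self):
        return [g for layer in self.layers for g in layer.grads]


# ---------------------------------------------------------------------------
# loss heads
# ---------------------------------------------------------------------------

class SoftmaxCrossEntropy:
    """Fused softmax + mean cross-entropy; gradient w.r.t. logits."""

    def loss_and_grad(self, logits, y_index):
        p = softmax(logits.astype(np.float64))
        n = logits.shape[0]
        ll = -np.log(np.clip(p[np.arange(n), y_index], EPS_LOG, None))
        grad = p
        grad[np.arange(n), y_index] -= 1.0
        return float(ll.mean()), (grad / n).astype(np.float32)


class MeanSquaredError:
    def loss_and_grad(self, yhat, y):
        diff = yhat - y
        n = diff.size
        return float(np.mean(diff.astype(np.float64) ** 2)), (2.0 * diff / n).astype(np.float32)


# ---------------------------------------------------------------------------
# optimizers
# ---------------------------------------------------------------------------

class SGD:
    def __init__(self, lr: float):
        self.lr = lr

    def step(self, params, grads):
        for p, g in zip(params, grads):
            p -= self.lr * g


class AdaDelta:
    """AdaDelta with a learning-rate multiplier (Keras convention).

    Running averages of squared gradients and squared updates with decay
    ``rho``; only the learning rate is externally prescribed.
    """

    def __init__(self, lr: float = 0.05, rho: float = 0.95, eps: float = 1e-6):
        self.lr, self.rho, self.eps = lr, rho, eps
        self._acc_g: list | None = None
        self._acc_dx: list | None = None

    def step(self, params, grads):
        if self._acc_g is None:
            self._acc_g = [np.zeros_like(p) for p in params]
            self._acc_dx = [np.zeros_like(p) for p in params]
        for p, g, ag, ad in zip(params, grads, self._acc_g, self._acc_dx):
            ag *= self.rho
            ag += (1.0 - self.rho) * g * g
            dx = np.sqrt(ad + self.eps) / np.sqrt(ag + self.eps) * g
            ad *= self.rho
            ad += (1.0 - self.rho) * dx * dx
            p -= self.lr * dx


def minibatches(n: int, batch_size: int, rng: np.random.Generator):
    """Seeded shuffled mini-batch index generator for one epoch."""
    order = rng.permutation(n)
    for start in range(0, n, batch_size):
        yield order[start : start + batch_size]
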