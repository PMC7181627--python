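"""A small numpy engine for convolutional encoder-decoder networks.

Implements exactly the pieces the segmentation model needs — 2-D
convolution (stride 1, zero padding), transposed convolution with arbitrary
stride and an explicit output size, 2x max pooling, ReLU, inverted dropout,
per-pixel softmax cross-entropy, and Adam — with hand-written backward
passes. Everything is deterministic given the seeds of the generators
passed in; layers hold their forward caches, so a layer instance handles
one forward/backward pair at a time.

Convolutions use an im2col/matmul formulation (``sliding_window_view`` plus
one GEMM), which is fast enough for desk-scale networks on a CPU. The
transposed convolution is realized as zero-interleaving (stride) followed
by a valid correlation, padded so the requested output size is met exactly;
its backward pass reuses the convolution machinery.
"""

from __future__ import annotations

from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Param:
    """A trainable tensor with an accumulated gradient."""

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)

    def zero_grad(self) -> None:
        self.grad.fill(0.0)


def he_normal(rng: np.random.Generator, shape: Tuple[int, ...], fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


# ---------------------------------------------------------------------------
# functional core: valid cross-correlation on a pre-padded input


def _corr_valid(xp: np.ndarray, W: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Valid cross-correlation. xp: (N,C,Hp,Wp), W: (O,C,k,k) -> (N,O,Ho,Wo).

    Returns (out, cols); cols is reused by the weight-gradient computation.
    """
    N, C, Hp, Wp = xp.shape
    O, _, k, _ = W.shape
    win = sliding_window_view(xp, (k, k), axis=(2, 3))  # N,C,Ho,Wo,k,k
    Ho, Wo = win.shape[2], win.shape[3]
    cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
        N * Ho * Wo, C * k * k
    )
    out = cols @ W.reshape(O, -1).T  # (N*Ho*Wo, O)
    return out.reshape(N, Ho, Wo, O).transpose(0, 3, 1, 2), cols


def _corr_valid_backward(
    dout: np.ndarray, cols: np.ndarray, W: np.ndarray, xp_shape: Tuple[int, ...]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Gradients of the valid correlation: (dW, db, dxp)."""
    N, O, Ho, Wo = dout.shape
    _, C, Hp, Wp = xp_shape
    k = W.shape[2]
    dmat = np.ascontiguousarray(dout.transpose(0, 2, 3, 1)).reshape(-1, O)
    dW = (dmat.T @ cols).reshape(W.shape)
    db = dmat.sum(axis=0)
    dcols = dmat @ W.reshape(O, -1)  # (N*Ho*Wo, C*k*k)
    dc6 = dcols.reshape(N, Ho, Wo, C, k, k)
    dxp = np.zeros(xp_shape, dtype=np.float64)
    for i in range(k):
        for j in range(k):
            dxp[:, :, i : i + Ho, j : j + Wo] += dc6[:, :, :, :, i, j].transpose(
                0, 3, 1, 2
            )
    return dW, db, dxp


# ---------------------------------------------------------------------------
# layers


class Conv2d:
    """3x3 (or kxk) stride-1 convolution with symmetric 'same'-style padding."""

    def __init__(
        self,
        cin: int,
        cout: int,
        k: int = 3,
        pad: Optional[int] = None,
        rng: Optional[np.random.Generator] = None,
    ):
        rng = rng if rng is not None else np.random.default_rng(0)
        self.k = k
        self.pad = (k - 1) // 2 if pad is None else pad
        self.W = Param(he_normal(rng, (cout, cin, k, k), cin * k * k))
        self.b = Param(np.zeros(cout))
        self._cache = None

    def parameters(self) -> List[Param]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        p = self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        out, cols = _corr_valid(xp, self.W.value)
        out += self.b.value[None, :, None, None]
        self._cache = (cols, xp.shape)
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        cols, xp_shape = self._cache
        dW, db, dxp = _corr_valid_backward(dout, cols, self.W.value, xp_shape)
        self.W.grad += dW
        self.b.grad += db
        p = self.pad
        if p:
            return dxp[:, :, p:-p, p:-p]
        return dxp


class ConvTranspose2d:
    """Transposed convolution with stride and an explicit output size.

    Forward = zero-interleave the input at ``stride``, pad so a valid kxk
    correlation produces exactly ``out_hw``, then correlate.
    """

    def __init__(
        self,
        cin: int,
        cout: int,
        k: int = 3,
        stride: int = 2,
        rng: Optional[np.random.Generator] = None,
    ):
        rng = rng if rng is not None else np.random.default_rng(0)
        self.k = k
        self.stride = stride
        self.W = Param(he_normal(rng, (cout, cin, k, k), cin * k * k))
        self.b = Param(np.zeros(cout))
        self._cache = None

    def parameters(self) -> List[Param]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray, out_hw: Tuple[int, int]) -> np.ndarray:
        N, C, H, W = x.shape
        s, k = self.stride, self.k
        Hu, Wu = (H - 1) * s + 1, (W - 1) * s + 1
        ph, pw = out_hw[0] + k - 1 - Hu, out_hw[1] + k - 1 - Wu
        if ph < 0 or pw < 0:
            raise ValueError(
                f"requested output {out_hw} too small for stride {s} from input "
                f"({H},{W}) with kernel {k}"
            )
        pt, pl = ph // 2, pw // 2
        up = np.zeros((N, C, Hu + ph, Wu + pw), dtype=np.float64)
        up[:, :, pt : pt + Hu : s, pl : pl + Wu : s] = x
        out, cols = _corr_valid(up, self.W.value)
        out += self.b.value[None, :, None, None]
        self._cache = (cols, up.shape, (pt, pl, Hu, Wu), x.shape)
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        cols, up_shape, (pt, pl, Hu, Wu), x_shape = self._cache
        dW, db, dup = _corr_valid_backward(dout, cols, self.W.value, up_shape)
        self.W.grad += dW
        self.b.grad += db
        s = self.stride
        return dup[:, :, pt : pt + Hu : s, pl : pl + Wu : s].reshape(x_shape)


class ReLU:
    def __init__(self):
        self._mask = None

    def parameters(self) -> List[Param]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dout, 0.0)


class MaxPool2d:
    """2x2 max pooling, stride 2; odd trailing rows/cols are dropped."""

    def __init__(self):
        self._cache = None

    def parameters(self) -> List[Param]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        N, C, H, W = x.shape
        Ho, Wo = H // 2, W // 2
        xc = x[:, :, : Ho * 2, : Wo * 2]
        r = xc.reshape(N, C, Ho, 2, Wo, 2).transpose(0, 1, 2, 4, 3, 5).reshape(
            N, C, Ho, Wo, 4
        )
        idx = r.argmax(axis=-1)
        out = np.take_along_axis(r, idx[..., None], axis=-1)[..., 0]
        self._cache = (idx, x.shape)
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        idx, x_shape = self._cache
        N, C, H, W = x_shape
        Ho, Wo = H // 2, W // 2
        dr = np.zeros((N, C, Ho, Wo, 4), dtype=np.float64)
        np.put_along_axis(dr, idx[..., None], dout[..., None], axis=-1)
        dx = np.zeros(x_shape, dtype=np.float64)
        dx[:, :, : Ho * 2, : Wo * 2] = (
            dr.reshape(N, C, Ho, Wo, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(
                N, C, Ho * 2, Wo * 2
            )
        )
        return dx


class Dropout:
    """Inverted dropout; identity in eval mode. RNG is supplied per forward."""

    def __init__(self, p: float):
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout probability must be in [0, 1)")
        self.p = p
        self._mask = None

    def parameters(self) -> List[Param]:
        return []

    def forward(
        self, x: np.ndarray, train: bool = False, rng: Optional[np.random.Generator] = None
    ) -> np.ndarray:
        if not train or self.p == 0.0:
            self._mask = None
            return x
        if rng is None:
            raise ValueError("training-mode dropout needs an rng")
        self._mask = (rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return dout
        return dout * self._mask


# ---------------------------------------------------------------------------
# loss and optimizer


def softmax(scores: np.ndarray, axis: int = 1) -> np.ndarray:
    z = scores - scores.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def softmax_cross_entropy(
    scores: np.ndarray, labels: np.ndarray
) -> tuple[float, np.ndarray]:
    """Mean per-pixel cross-entropy. scores (N,K,H,W), labels (N,H,W) int.

    Returns (loss, dscores).
    """
    N, K, H, W = scores.shape
    p = softmax(scores, axis=1)
    flat = p.transpose(0, 2, 3, 1).reshape(-1, K)
    lab = labels.reshape(-1)
    n = lab.size
    eps = 1e-12
    loss = -np.log(flat[np.arange(n), lab] + eps).mean()
    dflat = flat.copy()
    dflat[np.arange(n), lab] -= 1.0
    dflat /= n
    dscores = dflat.reshape(N, H, W, K).transpose(0, 3, 1, 2)
    return float(loss), dscores


class Adam:
    def __init__(
        self,
        params: Sequence[Param],
        lr: float = 1e-3,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1.0 - self.b1) * p.grad
            v *= self.b2
            v += (1.0 - self.b2) * p.grad**2
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()
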