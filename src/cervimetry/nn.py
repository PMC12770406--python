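"""Minimal numpy neural-network engine for 3D segmentation.

Implements exactly the pieces a 3D UNet needs — 3D convolution, batch
normalisation, ReLU, dropout, 2x max-pooling, nearest-neighbour upsampling,
channel concatenation — each as a layer object with explicit ``forward`` /
``backward`` passes, plus the AdamW optimiser and the combined soft-Dice +
cross-entropy loss.  Convolutions are evaluated as tensor contractions over
``sliding_window_view`` windows, which routes the heavy lifting through
BLAS.  Everything is float32 and deterministic given the seed.

Tensors are channel-first: (C, D, H, W), batch size 1 throughout.
"""

from __future__ import annotations

import numba as nb
import numpy as np


@nb.njit(fastmath=True, boundscheck=False, cache=True)
def _conv3x3_fwd(xp, w, out):  # pragma: no cover - exercised via Conv3d
    """out[o] += sum_c correlate(xp[c], w[o,c]); xp pre-padded by 1.

    The nine in-plane taps are fused into one vectorised row pass so each
    input row is loaded once per (d, o, c, i) tuple.
    """
    C, Dp, Hp, Wp = xp.shape
    O = w.shape[0]
    D, H, W = Dp - 2, Hp - 2, Wp - 2
    for d in range(D):
        for o in range(O):
            for h in range(H):
                orow = out[o, d, h]
                for c in range(C):
                    for i in range(3):
                        x0 = xp[c, d + i, h]
                        x1 = xp[c, d + i, h + 1]
                        x2 = xp[c, d + i, h + 2]
                        a0 = w[o, c, i, 0, 0]; a1 = w[o, c, i, 0, 1]; a2 = w[o, c, i, 0, 2]
                        b0 = w[o, c, i, 1, 0]; b1 = w[o, c, i, 1, 1]; b2 = w[o, c, i, 1, 2]
                        c0 = w[o, c, i, 2, 0]; c1 = w[o, c, i, 2, 1]; c2 = w[o, c, i, 2, 2]
                        for t in range(W):
                            orow[t] += (
                                a0 * x0[t] + a1 * x0[t + 1] + a2 * x0[t + 2]
                                + b0 * x1[t] + b1 * x1[t + 1] + b2 * x1[t + 2]
                                + c0 * x2[t] + c1 * x2[t + 1] + c2 * x2[t + 2]
                            )


@nb.njit(fastmath=True, boundscheck=False, cache=True)
def _bn_fwd(x, gamma, beta, out, xhat, mu, inv, eps):  # pragma: no cover
    C = x.shape[0]
    N = x[0].size
    xf = x.reshape(C, N)
    of = out.reshape(C, N)
    hf = xhat.reshape(C, N)
    for c in range(C):
        s = 0.0
        ss = 0.0
        row = xf[c]
        for t in range(N):
            v = row[t]
            s += v
            ss += v * v
        m = np.float32(s / N)
        var = np.float32(max(ss / N - m * m, 0.0))
        mu[c] = m
        iv = np.float32(1.0) / np.sqrt(var + eps)
        inv[c] = iv
        gc = gamma[c]
        bc = beta[c]
        hrow = hf[c]
        orow = of[c]
        for t in range(N):
            h = (row[t] - m) * iv
            hrow[t] = h
            orow[t] = gc * h + bc


@nb.njit(fastmath=True, boundscheck=False, cache=True)
def _bn_bwd(g, xhat, gamma, inv, dgamma, dbeta, gx):  # pragma: no cover
    C = g.shape[0]
    N = g[0].size
    gf = g.reshape(C, N)
    hf = xhat.reshape(C, N)
    xf = gx.reshape(C, N)
    for c in range(C):
        sg = 0.0
        sgh = 0.0
        grow = gf[c]
        hrow = hf[c]
        for t in range(N):
            gv = grow[t]
            sg += gv
            sgh += gv * hrow[t]
        dgamma[c] += np.float32(sgh)
        dbeta[c] += np.float32(sg)
        gc = gamma[c]
        iv = inv[c]
        a = gc * iv
        b1 = np.float32(gc * iv * sg / N)
        b2 = np.float32(gc * iv * sgh / N)
        xrow = xf[c]
        for t in range(N):
            xrow[t] = a * grow[t] - b1 - b2 * hrow[t]


@nb.njit(fastmath=True, boundscheck=False, cache=True)
def _conv3x3_dw(xp, g, dw, db):  # pragma: no cover - exercised via Conv3d
    """dw[o,c,i,j,k] += sum_dhw g[o,dhw] * xp[c, d+i, h+j, w+k]; db[o] += sum g[o]."""
    C = xp.shape[0]
    O, D, H, W = g.shape
    for d in range(D):
        for o in range(O):
            for h in range(H):
                grow = g[o, d, h]
                s = np.float32(0.0)
                for t in range(W):
                    s += grow[t]
                db[o] += s
            for c in range(C):
                for i in range(3):
                    s00 = np.float32(0.0); s01 = np.float32(0.0); s02 = np.float32(0.0)
                    s10 = np.float32(0.0); s11 = np.float32(0.0); s12 = np.float32(0.0)
                    s20 = np.float32(0.0); s21 = np.float32(0.0); s22 = np.float32(0.0)
                    for h in range(H):
                        grow = g[o, d, h]
                        x0 = xp[c, d + i, h]
                        x1 = xp[c, d + i, h + 1]
                        x2 = xp[c, d + i, h + 2]
                        for t in range(W):
                            gv = grow[t]
                            s00 += gv * x0[t]; s01 += gv * x0[t + 1]; s02 += gv * x0[t + 2]
                            s10 += gv * x1[t]; s11 += gv * x1[t + 1]; s12 += gv * x1[t + 2]
                            s20 += gv * x2[t]; s21 += gv * x2[t + 1]; s22 += gv * x2[t + 2]
                    dw[o, c, i, 0, 0] += s00; dw[o, c, i, 0, 1] += s01; dw[o, c, i, 0, 2] += s02
                    dw[o, c, i, 1, 0] += s10; dw[o, c, i, 1, 1] += s11; dw[o, c, i, 1, 2] += s12
                    dw[o, c, i, 2, 0] += s20; dw[o, c, i, 2, 1] += s21; dw[o, c, i, 2, 2] += s22

__all__ = [
    "Conv3d",
    "BatchNorm3d",
    "ReLU",
    "Dropout",
    "MaxPool2",
    "Upsample2",
    "AdamW",
    "dice_ce_loss_and_grad",
]


class Layer:
    """Base layer: trainable ``params``/``grads`` are parallel lists."""

    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params = []
        self.grads = []
        self.training = True

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, g: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv3d(Layer):
    """3D convolution, kernel k, 'same' zero padding, stride 1."""

    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator):
        super().__init__()
        if k not in (1, 3):
            raise ValueError("kernel size must be 1 or 3")
        self.cin, self.cout, self.k = cin, cout, k
        fan_in = cin * k**3
        # He initialisation for ReLU networks
        w = rng.standard_normal((cout, cin, k, k, k)) * np.sqrt(2.0 / fan_in)
        self.params = [w.astype(np.float32), np.zeros(cout, dtype=np.float32)]
        self.grads = [np.zeros_like(p) for p in self.params]

    def forward(self, x: np.ndarray) -> np.ndarray:
        w, b = self.params
        if self.k == 1:
            self._x = x
            y = np.matmul(
                w[:, :, 0, 0, 0], x.reshape(self.cin, -1)
            ).reshape(self.cout, *x.shape[1:])
            return (y + b[:, None, None, None]).astype(np.float32, copy=False)
        xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (1, 1)))
        self._xp = xp
        out = np.zeros((self.cout, *x.shape[1:]), dtype=np.float32)
        _conv3x3_fwd(xp, w, out)
        out += b[:, None, None, None]
        return out

    def backward(self, g: np.ndarray) -> np.ndarray:
        w, _ = self.params
        g = np.ascontiguousarray(g, dtype=np.float32)
        if self.k == 1:
            self.grads[1] += g.sum(axis=(1, 2, 3))
            w2 = w[:, :, 0, 0, 0]
            gf = g.reshape(self.cout, -1)
            self.grads[0] += (gf @ self._x.reshape(self.cin, -1).T)[
                :, :, None, None, None
            ]
            gx = (w2.T @ gf).reshape(self.cin, *g.shape[1:])
            self._x = None
            return gx.astype(np.float32, copy=False)
        _conv3x3_dw(self._xp, g, self.grads[0], self.grads[1])
        gp = np.pad(g, ((0, 0), (1, 1), (1, 1), (1, 1)))
        wflip = np.ascontiguousarray(
            w[:, :, ::-1, ::-1, ::-1].transpose(1, 0, 2, 3, 4)
        )
        gx = np.zeros((self.cin, *g.shape[1:]), dtype=np.float32)
        _conv3x3_fwd(gp, wflip, gx)
        self._xp = None
        return gx


class BatchNorm3d(Layer):
    """Per-channel normalisation over the spatial dimensions (batch of 1)."""

    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.params = [np.ones(c, dtype=np.float32), np.zeros(c, dtype=np.float32)]
        self.grads = [np.zeros_like(p) for p in self.params]
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x: np.ndarray) -> np.ndarray:
        gamma, beta = self.params
        x = np.ascontiguousarray(x, dtype=np.float32)
        if self.training:
            out = np.empty_like(x)
            xhat = np.empty_like(x)
            mu = np.empty_like(self.running_mean)
            inv = np.empty_like(self.running_mean)
            _bn_fwd(x, gamma, beta, out, xhat, mu, inv, np.float32(self.eps))
            var = 1.0 / inv**2 - self.eps
            self.running_mean += self.momentum * (mu - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
            self._cache = (xhat, inv)
            return out
        mu, var = self.running_mean, self.running_var
        inv = (1.0 / np.sqrt(var + self.eps)).astype(np.float32)
        xhat = (x - mu[:, None, None, None]) * inv[:, None, None, None]
        self._cache = (xhat.astype(np.float32), inv)
        return (gamma[:, None, None, None] * xhat + beta[:, None, None, None]).astype(
            np.float32, copy=False
        )

    def backward(self, g: np.ndarray) -> np.ndarray:
        gamma, _ = self.params
        xhat, inv = self._cache
        g = np.ascontiguousarray(g, dtype=np.float32)
        gx = np.empty_like(g)
        _bn_bwd(g, xhat, gamma, np.asarray(inv, dtype=np.float32),
                self.grads[0], self.grads[1], gx)
        self._cache = None
        return gx


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        out = np.maximum(x, 0.0, out=x)  # in place: callers do not reuse x
        self._out = out
        return out

    def backward(self, g: np.ndarray) -> np.ndarray:
        g *= self._out > 0
        self._out = None
        return g


class Dropout(Layer):
    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        self.p = p
        self.rng = rng

    def forward(self, x: np.ndarray) -> np.ndarray:
        if not self.training or self.p == 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p).astype(np.float32) / (
            1.0 - self.p
        )
        return x * self._mask

    def backward(self, g: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return g
        out = g * self._mask
        self._mask = None
        return out


class MaxPool2(Layer):
    """2x2x2 max pooling, stride 2."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        c, d, h, w = x.shape
        r = x.reshape(c, d // 2, 2, h // 2, 2, w // 2, 2)
        r = np.moveaxis(r, (2, 4, 6), (4, 5, 6)).reshape(
            c, d // 2, h // 2, w // 2, 8
        )
        self._arg = r.argmax(axis=-1)
        self._shape = x.shape
        return r.max(axis=-1)

    def backward(self, g: np.ndarray) -> np.ndarray:
        c, d2, h2, w2 = g.shape
        out = np.zeros((c, d2, h2, w2, 8), dtype=np.float32)
        np.put_along_axis(out, self._arg[..., None], g[..., None], axis=-1)
        out = out.reshape(c, d2, h2, w2, 2, 2, 2)
        out = np.moveaxis(out, (4, 5, 6), (2, 4, 6)).reshape(self._shape)
        self._arg = None
        return out


class Upsample2(Layer):
    """Nearest-neighbour 2x upsampling."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        return x.repeat(2, axis=1).repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, g: np.ndarray) -> np.ndarray:
        c, d, h, w = g.shape
        r = g.reshape(c, d // 2, 2, h // 2, 2, w // 2, 2)
        return r.sum(axis=(2, 4, 6)).astype(np.float32, copy=False)


class AdamW:
    """AdamW with decoupled weight decay and a per-step learning rate."""

    def __init__(
        self,
        params: list[np.ndarray],
        grads: list[np.ndarray],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        weight_decay: float = 1e-5,
    ):
        self.params, self.grads = params, grads
        self.lr, self.betas, self.eps, self.wd = lr, betas, eps, weight_decay
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, lr: float | None = None) -> None:
        lr = self.lr if lr is None else lr
        b1, b2 = self.betas
        self.t += 1
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for p, g, m, v in zip(self.params, self.grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p -= lr * self.wd * p
            p -= lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)

    def zero_grad(self) -> None:
        for g in self.grads:
            g[...] = 0.0


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=0, keepdims=True)
    e = np.exp(z, dtype=np.float32)
    return e / e.sum(axis=0, keepdims=True)


def dice_ce_loss_and_grad(
    logits: np.ndarray, target: np.ndarray, num_classes: int, eps: float = 1e-5,
    present_only: bool = True,
) -> tuple[float, np.ndarray]:
    """Equal-weight soft-Dice + cross-entropy loss and its logit gradient.

    ``logits`` is (K, D, H, W); ``target`` an integer label grid.  With
    ``present_only`` (the default) the Dice term averages the per-class soft
    Dice over the classes present in the target: a class absent from both
    target and prediction contributes a meaningless near-zero Dice whose
    gradient is pure noise on small training batches.
    """
    K = num_classes
    p = softmax(logits)
    pf = p.reshape(K, -1)
    t = target.reshape(-1)
    n = t.size
    onehot = np.zeros_like(pf)
    onehot[t, np.arange(n)] = 1.0
    # cross entropy
    ce = float(-np.log(pf[t, np.arange(n)] + 1e-12).mean())
    g_ce = (pf - onehot) / n
    # soft dice over the included classes
    target_count = onehot.sum(axis=1)
    if present_only:
        include = (target_count > 0).astype(pf.dtype)
    else:
        include = np.ones(K, dtype=pf.dtype)
    k_inc = float(include.sum())
    inter = (pf * onehot).sum(axis=1)
    sums = pf.sum(axis=1) + target_count
    dice = (2 * inter + eps) / (sums + eps)
    loss_dice = float(1.0 - (dice * include).sum() / k_inc)
    g_dice = -include[:, None] * (
        2 * onehot * (sums + eps)[:, None] - (2 * inter + eps)[:, None]
    ) / ((sums + eps) ** 2)[:, None] / k_inc
    # chain rule through softmax for the dice part (CE grad is already wrt logits)
    gp = g_dice
    dot = (gp * pf).sum(axis=0, keepdims=True)
    g_dice_logit = pf * (gp - dot)
    g = (g_ce + g_dice_logit).reshape(logits.shape).astype(np.float32)
    return ce + loss_dice, g
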