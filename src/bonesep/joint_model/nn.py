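"""Minimal reverse-mode autodiff for small 3D convolutional networks.

A deliberately small engine (float32, batch-of-one, ``(C, D, H, W)``
layout) sufficient to train the joint-space U-Net on CPU without an
external framework.  Convolutions use *edge-replication* padding so that a
constant input produces a constant output — this is what makes independent
per-tile inference seam-free when tiles are stitched.

Every primitive has a plain-array forward (used for no-grad inference) and
a taped variant; gradients are verified against finite differences in the
test suite.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True, fastmath=True)
def _corr3_core(xp: np.ndarray, w: np.ndarray, out: np.ndarray) -> None:  # pragma: no cover
    """Fused 3x3x3 correlation; ``xp`` is the input padded by 1 voxel."""
    d, h, ww = out.shape
    for z in range(d):
        for y in range(h):
            for x in range(ww):
                acc = np.float32(0.0)
                for a in range(3):
                    for b in range(3):
                        for c in range(3):
                            acc += w[a, b, c] * xp[z + a, y + b, x + c]
                out[z, y, x] += acc

# ---------------------------------------------------------------------------
# array-level primitives (shared by taped and no-grad paths)


def _offsets(k: int):
    r = k // 2
    return [(dz, dy, dx) for dz in range(k) for dy in range(k) for dx in range(k)], r


def conv3d_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray) -> np.ndarray:
    """'Same' 3D convolution (cross-correlation) with edge padding.

    x: (Cin,D,H,W), w: (Cout,Cin,k,k,k).  For few channels a per-pair
    ``ndimage.correlate`` pass is faster than the 27-offset tensordot loop
    (mode='nearest' is exactly edge-replication padding).
    """
    cout, cin, k = w.shape[0], w.shape[1], w.shape[2]
    if k == 3 and cin * cout <= 16:
        out = np.zeros((cout,) + x.shape[1:], dtype=np.float32)
        w32 = np.asarray(w, dtype=np.float32)
        for ci in range(cin):
            xp = np.pad(np.asarray(x[ci], dtype=np.float32), 1, mode="edge")
            for co in range(cout):
                _corr3_core(xp, w32[co, ci], out[co])
        return out + b.astype(np.float32)[:, None, None, None]
    offs, r = _offsets(k)
    if r:
        xp = np.pad(x, ((0, 0), (r, r), (r, r), (r, r)), mode="edge")
    else:
        xp = x
    _, d, h, wd = x.shape
    out = np.zeros((cout, d, h, wd), dtype=np.float32)
    for dz, dy, dx in offs:
        patch = xp[:, dz : dz + d, dy : dy + h, dx : dx + wd]
        out += np.tensordot(w[:, :, dz, dy, dx], patch, axes=(1, 0))
    return out + b[:, None, None, None]


def _fold_edge_padding(g: np.ndarray, r: int) -> np.ndarray:
    """Adjoint of edge-replication padding on the three spatial axes."""
    if r == 0:
        return g
    for ax in (1, 2, 3):
        idx = lambda s: tuple(s if i == ax else slice(None) for i in range(g.ndim))
        n = g.shape[ax] - 2 * r
        core = np.ascontiguousarray(g[idx(slice(r, r + n))])
        core[idx(slice(0, 1))] += g[idx(slice(0, r))].sum(axis=ax, keepdims=True)
        core[idx(slice(n - 1, n))] += g[idx(slice(r + n, None))].sum(axis=ax, keepdims=True)
        g = core
    return g


def conv3d_backward(
    x: np.ndarray, w: np.ndarray, gout: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    k = w.shape[2]
    offs, r = _offsets(k)
    _, d, h, wd = x.shape
    if r:
        xp = np.pad(x, ((0, 0), (r, r), (r, r), (r, r)), mode="edge")
    else:
        xp = x
    gxp = np.zeros_like(xp)
    gw = np.zeros_like(w)
    for dz, dy, dx in offs:
        patch = xp[:, dz : dz + d, dy : dy + h, dx : dx + wd]
        gw[:, :, dz, dy, dx] = np.tensordot(gout, patch, axes=([1, 2, 3], [1, 2, 3]))
        gxp[:, dz : dz + d, dy : dy + h, dx : dx + wd] += np.tensordot(
            w[:, :, dz, dy, dx].T, gout, axes=(1, 0)
        )
    gx = _fold_edge_padding(gxp, r)
    gb = gout.sum(axis=(1, 2, 3))
    return gx, gw, gb


def down2_forward(x: np.ndarray) -> np.ndarray:
    return np.ascontiguousarray(x[:, ::2, ::2, ::2])


def down2_backward(x_shape, gout: np.ndarray) -> np.ndarray:
    g = np.zeros(x_shape, dtype=np.float32)
    g[:, ::2, ::2, ::2] = gout
    return g


def up2_forward(x: np.ndarray) -> np.ndarray:
    return np.repeat(np.repeat(np.repeat(x, 2, axis=1), 2, axis=2), 2, axis=3)


def up2_backward(gout: np.ndarray) -> np.ndarray:
    c, d, h, w = gout.shape
    return (
        gout.reshape(c, d // 2, 2, h // 2, 2, w // 2, 2)
        .sum(axis=(2, 4, 6))
        .astype(np.float32)
    )


# ---------------------------------------------------------------------------
# tape


class Tensor:
    """A node in the backward graph; ``data``/``grad`` are float32 arrays."""

    __slots__ = ("data", "grad", "_parents", "_backward", "name")

    def __init__(self, data, parents=(), backward=None, name=""):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad = None
        self._parents = tuple(parents)
        self._backward = backward
        self.name = name

    @property
    def shape(self):
        return self.data.shape

    def backward(self) -> None:
        """Backpropagate from this (scalar) tensor through the tape."""
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: Tensor) -> None:
            stack = [(t, iter(t._parents))]
            seen.add(id(t))
            while stack:
                node, it = stack[-1]
                advanced = False
                for p in it:
                    if id(p) not in seen:
                        seen.add(id(p))
                        stack.append((p, iter(p._parents)))
                        advanced = True
                        break
                if not advanced:
                    topo.append(node)
                    stack.pop()

        visit(self)
        for t in topo:
            t.grad = np.zeros_like(t.data)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None:
                t._backward(t.grad)


def conv3d(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    out_data = conv3d_forward(x.data, w.data, b.data)

    def backward(gout):
        gx, gw, gb = conv3d_backward(x.data, w.data, gout)
        x.grad += gx
        w.grad += gw
        b.grad += gb

    return Tensor(out_data, (x, w, b), backward, "conv3d")


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    out = Tensor(np.where(mask, x.data, 0.0), (x,), None, "relu")
    out._backward = lambda gout: x.grad.__iadd__(gout * mask)
    return out


def add(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data + b.data, (a, b), None, "add")

    def backward(gout):
        a.grad += gout
        b.grad += gout

    out._backward = backward
    return out


def concat(a: Tensor, b: Tensor) -> Tensor:
    ca = a.data.shape[0]
    out = Tensor(np.concatenate([a.data, b.data], axis=0), (a, b), None, "concat")

    def backward(gout):
        a.grad += gout[:ca]
        b.grad += gout[ca:]

    out._backward = backward
    return out


def down2(x: Tensor) -> Tensor:
    out = Tensor(down2_forward(x.data), (x,), None, "down2")
    out._backward = lambda gout: x.grad.__iadd__(down2_backward(x.data.shape, gout))
    return out


def up2(x: Tensor) -> Tensor:
    out = Tensor(up2_forward(x.data), (x,), None, "up2")
    out._backward = lambda gout: x.grad.__iadd__(up2_backward(gout))
    return out


def channel_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    """Per-channel normalization over the spatial axes with a learned affine.

    The batch-of-one stand-in for the reference architecture's batch norm;
    keeps activation scales bounded so the sigmoid head cannot saturate.
    A spatially constant channel normalizes to zero, so constant inputs
    still propagate to constant outputs (seam-free tiling).
    """
    mu = x.data.mean(axis=(1, 2, 3), keepdims=True)
    var = x.data.var(axis=(1, 2, 3), keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv
    g = gamma.data[:, None, None, None]
    out = Tensor(g * xhat + beta.data[:, None, None, None], (x, gamma, beta), None, "cnorm")

    def backward(gout):
        gamma.grad += (gout * xhat).sum(axis=(1, 2, 3))
        beta.grad += gout.sum(axis=(1, 2, 3))
        gy = gout * g
        m = gy.mean(axis=(1, 2, 3), keepdims=True)
        mxh = (gy * xhat).mean(axis=(1, 2, 3), keepdims=True)
        x.grad += (inv * (gy - m - xhat * mxh)).astype(np.float32)

    out._backward = backward
    return out


def channel_norm_forward(
    x: np.ndarray, gamma: np.ndarray, beta: np.ndarray, eps: float = 1e-5
) -> np.ndarray:
    mu = x.mean(axis=(1, 2, 3), keepdims=True)
    var = x.var(axis=(1, 2, 3), keepdims=True)
    xhat = (x - mu) / np.sqrt(var + eps)
    return gamma[:, None, None, None] * xhat + beta[:, None, None, None]


def sigmoid(x: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-np.clip(x.data, -60, 60)))
    out = Tensor(s, (x,), None, "sigmoid")
    out._backward = lambda gout: x.grad.__iadd__(gout * s * (1.0 - s))
    return out


def dice_loss(pred: Tensor, target: np.ndarray, eps: float = 1.0) -> Tensor:
    """Soft Dice loss, 1 - (2|P∩T| + eps) / (|P| + |T| + eps)."""
    t = np.asarray(target, dtype=np.float32)
    inter = float((pred.data * t).sum())
    psum = float(pred.data.sum())
    tsum = float(t.sum())
    denom = psum + tsum + eps
    num = 2.0 * inter + eps
    loss = 1.0 - num / denom

    def backward(gout):
        g = float(gout)
        # d/dp of -(2*inter+eps)/(psum+tsum+eps)
        pred.grad += g * (-(2.0 * t * denom - num) / denom**2).astype(np.float32)

    return Tensor(np.float32(loss), (pred,), backward, "dice")


def dice_coefficient(pred: np.ndarray, target: np.ndarray, eps: float = 1.0) -> float:
    pred = np.asarray(pred, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    return (2.0 * (pred * target).sum() + eps) / (pred.sum() + target.sum() + eps)


def iou(pred: np.ndarray, target: np.ndarray) -> float:
    """Intersection over union of two binary masks (1.0 when both empty)."""
    pred = np.asarray(pred, dtype=bool)
    target = np.asarray(target, dtype=bool)
    union = (pred | target).sum()
    if union == 0:
        return 1.0
    return float((pred & target).sum() / union)


# ---------------------------------------------------------------------------
# optimizer


class Adam:
    """Standard Adam over a list of parameter Tensors."""

    def __init__(self, params: list[Tensor], lr: float = 1e-4, betas=(0.9, 0.999), eps=1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            g = p.grad
            if g is None:
                continue
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(np.float32)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = np.zeros_like(p.data)
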