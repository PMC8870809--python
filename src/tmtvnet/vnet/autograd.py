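"""Minimal reverse-mode automatic differentiation for 3D convolutional nets.

Implements exactly the operator set a V-NET needs — 3D convolution
(stride 1, odd kernels), 2x2x2 stride-2 down-convolution, nearest-neighbor
upsampling, channel concatenation, residual addition, leaky-ReLU, sigmoid
and the soft dice loss — on float32 ``numpy`` arrays laid out
``(channels, x, y, z)``.  Convolutions are lowered to a single BLAS matmul
via im2col (``sliding_window_view``), which keeps CPU training of
desk-scale volumes fast.

Gradients are propagated by topological traversal of the recorded tape.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Tensor",
    "conv3d",
    "down_conv",
    "upsample_nn",
    "concat_channels",
    "add",
    "leaky_relu",
    "sigmoid",
    "soft_dice",
]


class Tensor:
    """A node of the computation tape: float32 data plus, after
    :meth:`backward`, the gradient of the loss with respect to it."""

    __slots__ = ("data", "grad", "parents", "backward_fn", "requires_grad")

    def __init__(
        self,
        data: np.ndarray,
        parents: Sequence["Tensor"] = (),
        backward_fn: Callable[[np.ndarray], Sequence[np.ndarray | None]] | None = None,
        requires_grad: bool = False,
    ):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.parents = tuple(parents)
        self.backward_fn = backward_fn
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self) -> None:
        """Accumulate gradients into every upstream tensor that needs one."""
        order: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS: graphs are deep for big volumes
            node, processed = stack.pop()
            if processed:
                order.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node.parents:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))

        self.grad = np.ones_like(self.data)
        for node in reversed(order):
            if node.backward_fn is None or node.grad is None:
                continue
            for parent, g in zip(node.parents, node.backward_fn(node.grad)):
                if g is None or not parent.requires_grad:
                    continue
                if parent.grad is None:
                    parent.grad = g.astype(np.float32, copy=True)
                else:
                    parent.grad += g


def _f32(a: np.ndarray) -> np.ndarray:
    return np.ascontiguousarray(a, dtype=np.float32)


# ---------------------------------------------------------------------------
# convolutions

def _im2col(x: np.ndarray, k: int, pad: int) -> np.ndarray:
    """(C, D, H, W) -> (D*H*W, C*k^3) patch matrix (stride 1)."""
    if pad:
        x = np.pad(x, ((0, 0), (pad, pad), (pad, pad), (pad, pad)))
    win = sliding_window_view(x, (k, k, k), axis=(1, 2, 3))
    c = x.shape[0]
    d, h, w = win.shape[1:4]
    return win.transpose(1, 2, 3, 0, 4, 5, 6).reshape(d * h * w, c * k**3)


def conv3d(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """'Same' 3D convolution, stride 1, odd kernel; bias per out-channel.

    x: (Ci, D, H, W); w: (Co, Ci, k, k, k); b: (Co,).
    """
    co, ci, k = w.data.shape[:3]
    pad = (k - 1) // 2
    d, h, wd = x.data.shape[1:]
    col = _im2col(x.data, k, pad)
    wm = w.data.reshape(co, ci * k**3)
    y = col @ wm.T + b.data
    out_data = _f32(y.T.reshape(co, d, h, wd))

    def backward(g: np.ndarray):
        gn = g.reshape(co, -1).T  # (N, Co)
        dw = (gn.T @ col).reshape(w.data.shape)
        db = gn.sum(axis=0)
        dx = None
        if x.requires_grad:
            # full correlation of the output grad with spatially flipped
            # kernels, channels swapped; pad k-1-pad keeps 'same' geometry
            wf = np.flip(w.data, axis=(2, 3, 4)).transpose(1, 0, 2, 3, 4)
            colg = _im2col(g, k, k - 1 - pad)
            dx = (colg @ wf.reshape(ci, co * k**3).T).T.reshape(x.data.shape)
        return dx, dw, db

    return Tensor(out_data, parents=(x, w, b), backward_fn=backward)


def down_conv(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """2x2x2 convolution with stride 2 (the V-NET down-transition).

    x: (Ci, D, H, W) with even spatial dims; w: (Co, Ci, 2, 2, 2).
    """
    co, ci = w.data.shape[:2]
    d, h, wd = x.data.shape[1:]
    if d % 2 or h % 2 or wd % 2:
        raise ValueError(f"spatial shape {(d, h, wd)} not divisible by 2")
    view = x.data.reshape(ci, d // 2, 2, h // 2, 2, wd // 2, 2)
    col = view.transpose(1, 3, 5, 0, 2, 4, 6).reshape(-1, ci * 8)
    wm = w.data.reshape(co, ci * 8)
    y = col @ wm.T + b.data
    out_data = _f32(y.T.reshape(co, d // 2, h // 2, wd // 2))

    def backward(g: np.ndarray):
        gn = g.reshape(co, -1).T
        dw = (gn.T @ col).reshape(w.data.shape)
        db = gn.sum(axis=0)
        dx = None
        if x.requires_grad:
            dcol = gn @ wm  # windows are disjoint: scatter is a reshape
            dx = (
                dcol.reshape(d // 2, h // 2, wd // 2, ci, 2, 2, 2)
                .transpose(3, 0, 4, 1, 5, 2, 6)
                .reshape(x.data.shape)
            )
        return dx, dw, db

    return Tensor(out_data, parents=(x, w, b), backward_fn=backward)


def upsample_nn(x: Tensor) -> Tensor:
    """Nearest-neighbor x2 upsampling of each spatial axis."""
    out_data = x.data.repeat(2, axis=1).repeat(2, axis=2).repeat(2, axis=3)

    def backward(g: np.ndarray):
        c, d, h, w = x.data.shape
        return (g.reshape(c, d, 2, h, 2, w, 2).sum(axis=(2, 4, 6)),)

    return Tensor(out_data, parents=(x,), backward_fn=backward)


# ---------------------------------------------------------------------------
# pointwise / structural ops

def concat_channels(a: Tensor, b: Tensor) -> Tensor:
    na = a.data.shape[0]
    out_data = np.concatenate([a.data, b.data], axis=0)

    def backward(g: np.ndarray):
        return g[:na], g[na:]

    return Tensor(out_data, parents=(a, b), backward_fn=backward)


def add(a: Tensor, b: Tensor) -> Tensor:
    if a.data.shape != b.data.shape:
        raise ValueError(f"shape mismatch {a.data.shape} vs {b.data.shape}")
    out_data = a.data + b.data

    def backward(g: np.ndarray):
        return g, g

    return Tensor(out_data, parents=(a, b), backward_fn=backward)


def leaky_relu(x: Tensor, alpha: float = 0.1) -> Tensor:
    mask = x.data > 0
    out_data = np.where(mask, x.data, alpha * x.data)

    def backward(g: np.ndarray):
        return (np.where(mask, g, alpha * g),)

    return Tensor(out_data, parents=(x,), backward_fn=backward)


def sigmoid(x: Tensor) -> Tensor:
    z = np.clip(x.data, -30.0, 30.0)
    s = 1.0 / (1.0 + np.exp(-z))

    def backward(g: np.ndarray):
        return (g * s * (1.0 - s),)

    return Tensor(_f32(s), parents=(x,), backward_fn=backward)


def soft_dice(pred: Tensor, target: np.ndarray, eps: float = 1e-6) -> Tensor:
    """Soft dice loss 1 - (2*sum(p*t)+eps)/(sum(p)+sum(t)+eps) as a scalar
    tape node with its analytic gradient."""
    t = np.asarray(target, dtype=np.float32)
    if t.shape != pred.data.shape:
        raise ValueError(f"pred shape {pred.data.shape} != target shape {t.shape}")
    num = 2.0 * float((pred.data * t).sum()) + eps
    den = float(pred.data.sum()) + float(t.sum()) + eps
    loss = 1.0 - num / den

    def backward(g: np.ndarray):
        # d/dp_i [num/den] = (2 t_i * den - num) / den^2
        return (-float(g) * (2.0 * t * den - num) / den**2,)

    return Tensor(np.float32(loss), parents=(pred,), backward_fn=backward)
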