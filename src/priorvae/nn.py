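"""Minimal reverse-mode automatic differentiation over numpy arrays.

A :class:`Tensor` records the operations that produced it; calling
``backward()`` on a scalar walks the tape in reverse topological order and
accumulates gradients into every tensor created with ``requires_grad=True``.
The op set is exactly what the prior-fusion VAE needs — affine maps, ReLU,
sigmoid, row softmax, batch/layer normalization, concatenation and
reductions — plus an Adam optimizer.  All arithmetic is float64 and fully
deterministic, which keeps training runs bit-reproducible from a seed.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "Parameter",
    "matmul",
    "add",
    "sub",
    "mul",
    "scale",
    "relu",
    "sigmoid",
    "log",
    "softmax_rows",
    "layer_norm",
    "concat",
    "sum_all",
    "mean_all",
    "Linear",
    "BatchNorm1d",
    "LayerNorm",
    "Adam",
]

_EPS = 1e-5  # normalization epsilon


class Tensor:
    """A node in the computation graph wrapping a float64 ndarray."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(
        self,
        data: np.ndarray | float,
        requires_grad: bool = False,
        parents: tuple["Tensor", ...] = (),
        backward: Callable[[np.ndarray], None] | None = None,
    ):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents
        self._backward = backward

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def backward(self) -> None:
        """Accumulate d(self)/d(leaf) into every requires_grad leaf. Scalar only."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS: graphs can be deep at many epochs
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def zero_grad(self) -> None:
        self.grad = None


class Parameter(Tensor):
    """A trainable leaf tensor."""

    def __init__(self, data: np.ndarray):
        super().__init__(data, requires_grad=True)


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reduce a broadcast gradient back to ``shape``."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


def matmul(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data @ b.data, parents=(a, b))

    def bw(g: np.ndarray) -> None:
        if a.requires_grad:
            a.accumulate(g @ b.data.T)
        if b.requires_grad:
            b.accumulate(a.data.T @ g)

    out._backward = bw
    return out


def add(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data + b.data, parents=(a, b))

    def bw(g: np.ndarray) -> None:
        if a.requires_grad:
            a.accumulate(_unbroadcast(g, a.data.shape))
        if b.requires_grad:
            b.accumulate(_unbroadcast(g, b.data.shape))

    out._backward = bw
    return out


def sub(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data - b.data, parents=(a, b))

    def bw(g: np.ndarray) -> None:
        if a.requires_grad:
            a.accumulate(_unbroadcast(g, a.data.shape))
        if b.requires_grad:
            b.accumulate(_unbroadcast(-g, b.data.shape))

    out._backward = bw
    return out


def mul(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data * b.data, parents=(a, b))

    def bw(g: np.ndarray) -> None:
        if a.requires_grad:
            a.accumulate(_unbroadcast(g * b.data, a.data.shape))
        if b.requires_grad:
            b.accumulate(_unbroadcast(g * a.data, b.data.shape))

    out._backward = bw
    return out


def scale(a: Tensor, c: float) -> Tensor:
    out = Tensor(a.data * c, parents=(a,))
    out._backward = lambda g: a.accumulate(g * c)
    return out


def relu(a: Tensor) -> Tensor:
    mask = a.data > 0
    out = Tensor(a.data * mask, parents=(a,))
    out._backward = lambda g: a.accumulate(g * mask)
    return out


def sigmoid(a: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-a.data))
    out = Tensor(s, parents=(a,))
    out._backward = lambda g: a.accumulate(g * s * (1.0 - s))
    return out


def log(a: Tensor) -> Tensor:
    out = Tensor(np.log(a.data), parents=(a,))
    out._backward = lambda g: a.accumulate(g / a.data)
    return out


def softmax_rows(a: Tensor) -> Tensor:
    """Softmax along the last axis."""
    shifted = a.data - a.data.max(axis=-1, keepdims=True)
    e = np.exp(shifted)
    s = e / e.sum(axis=-1, keepdims=True)
    out = Tensor(s, parents=(a,))

    def bw(g: np.ndarray) -> None:
        a.accumulate((g - (g * s).sum(axis=-1, keepdims=True)) * s)

    out._backward = bw
    return out


def layer_norm(a: Tensor, gamma: Tensor, beta: Tensor) -> Tensor:
    """Row-wise normalization over the last axis, then affine."""
    mean = a.data.mean(axis=-1, keepdims=True)
    var = a.data.var(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + _EPS)
    xhat = (a.data - mean) * inv
    out = Tensor(xhat * gamma.data + beta.data, parents=(a, gamma, beta))

    def bw(g: np.ndarray) -> None:
        if gamma.requires_grad:
            gamma.accumulate(_unbroadcast(g * xhat, gamma.data.shape))
        if beta.requires_grad:
            beta.accumulate(_unbroadcast(g, beta.data.shape))
        if a.requires_grad:
            gx = g * gamma.data
            a.accumulate(
                inv
                * (
                    gx
                    - gx.mean(axis=-1, keepdims=True)
                    - xhat * (gx * xhat).mean(axis=-1, keepdims=True)
                )
            )

    out._backward = bw
    return out


def concat(tensors: Sequence[Tensor], axis: int = 1) -> Tensor:
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), parents=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g: np.ndarray) -> None:
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                t.accumulate(np.take(g, range(lo, hi), axis=axis))

    out._backward = bw
    return out


def sum_all(a: Tensor) -> Tensor:
    out = Tensor(a.data.sum(), parents=(a,))
    out._backward = lambda g: a.accumulate(np.broadcast_to(g, a.data.shape).copy())
    return out


def mean_all(a: Tensor) -> Tensor:
    return scale(sum_all(a), 1.0 / a.data.size)


# ---------------------------------------------------------------------------
# layers


class Module:
    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        for v in vars(self).values():
            if isinstance(v, Parameter):
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
                    elif isinstance(item, Parameter):
                        params.append(item)
        return params


class Linear(Module):
    """Affine map with fan-in uniform initialization U(-1/sqrt(in), 1/sqrt(in))."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        bound = 1.0 / np.sqrt(n_in)
        self.weight = Parameter(rng.uniform(-bound, bound, size=(n_in, n_out)))
        self.bias = Parameter(rng.uniform(-bound, bound, size=(n_out,)))

    def __call__(self, x: Tensor) -> Tensor:
        return add(matmul(x, self.weight), self.bias)


class BatchNorm1d(Module):
    """Batch normalization with running statistics (momentum 0.1).

    Training mode normalizes by batch statistics (and needs B >= 2);
    evaluation mode applies the running-statistics affine map, which makes
    inference a deterministic pointwise function of the input.
    """

    def __init__(self, n: int, momentum: float = 0.1):
        self.gamma = Parameter(np.ones(n))
        self.beta = Parameter(np.zeros(n))
        self.running_mean = np.zeros(n)
        self.running_var = np.ones(n)
        self.momentum = momentum
        self.training = True

    def __call__(self, x: Tensor) -> Tensor:
        if self.training:
            if x.data.shape[0] < 2:
                raise ValueError("batch normalization needs batch size >= 2 in training")
            mean = x.data.mean(axis=0)
            var = x.data.var(axis=0)
            n = x.data.shape[0]
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            # running variance uses the unbiased estimate, batch normalization the biased one
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var * n / max(n - 1, 1)
            inv = 1.0 / np.sqrt(var + _EPS)
            xhat = (x.data - mean) * inv
            out = Tensor(xhat * self.gamma.data + self.beta.data, parents=(x, self.gamma, self.beta))
            gamma, beta = self.gamma, self.beta

            def bw(g: np.ndarray) -> None:
                gamma.accumulate((g * xhat).sum(axis=0))
                beta.accumulate(g.sum(axis=0))
                if x.requires_grad:
                    gx = g * gamma.data
                    x.accumulate(
                        inv * (gx - gx.mean(axis=0) - xhat * (gx * xhat).mean(axis=0))
                    )

            out._backward = bw
            return out
        inv = 1.0 / np.sqrt(self.running_var + _EPS)
        w = Tensor(self.gamma.data * inv, parents=(self.gamma,))
        gamma = self.gamma
        w._backward = lambda g: gamma.accumulate(g * inv)
        shift = Tensor(self.beta.data - self.running_mean * self.gamma.data * inv,
                       parents=(self.beta, self.gamma))
        beta, rm = self.beta, self.running_mean

        def shift_bw(g: np.ndarray) -> None:
            beta.accumulate(g)
            gamma.accumulate(-g * rm * inv)

        shift._backward = shift_bw
        return add(mul(x, w), shift)


class LayerNorm(Module):
    def __init__(self, n: int):
        self.gamma = Parameter(np.ones(n))
        self.beta = Parameter(np.zeros(n))

    def __call__(self, x: Tensor) -> Tensor:
        return layer_norm(x, self.gamma, self.beta)


class Adam:
    """Adam optimizer (beta1=0.9, beta2=0.999, eps=1e-8)."""

    def __init__(self, params: Iterable[Parameter], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
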