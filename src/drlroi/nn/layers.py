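"""Layer modules with cached forward passes and explicit backward passes.

Conventions
-----------
* Arrays are ``float64`` throughout; image tensors are ``(B, C, H, W)``.
* ``forward`` caches whatever the matching ``backward`` needs; ``backward``
  receives the gradient of the scalar loss w.r.t. the layer output, returns
  the gradient w.r.t. the layer input, and accumulates parameter gradients
  in ``Parameter.grad``.
* ``train()`` / ``eval()`` toggle batch-statistics behaviour (batch norm).
"""

from __future__ import annotations

import numpy as np


class Parameter:
    """A learnable array together with its accumulated gradient."""

    __slots__ = ("data", "grad")

    def __init__(self, data: np.ndarray):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = np.zeros_like(self.data)

    @property
    def shape(self):
        return self.data.shape


class Module:
    """Base class: parameter traversal, mode switching, state (de)serialisation."""

    def __init__(self):
        self.training = True

    # -- traversal --------------------------------------------------------
    def named_parameters(self, prefix: str = ""):
        for name, value in vars(self).items():
            if isinstance(value, Parameter):
                yield f"{prefix}{name}", value
            elif isinstance(value, Module):
                yield from value.named_parameters(f"{prefix}{name}.")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{prefix}{name}.{i}.")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def zero_grad(self):
        for p in self.parameters():
            p.grad[...] = 0.0

    def _child_modules(self):
        for value in vars(self).values():
            if isinstance(value, Module):
                yield value
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        yield item

    def train(self):
        self.training = True
        for m in self._child_modules():
            m.train()
        return self

    def eval(self):
        self.training = False
        for m in self._child_modules():
            m.eval()
        return self

    # -- state ------------------------------------------------------------
    def _named_buffers(self, prefix: str = ""):
        for name, value in vars(self).items():
            if isinstance(value, Module):
                yield from value._named_buffers(f"{prefix}{name}.")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item._named_buffers(f"{prefix}{name}.{i}.")
            elif name in getattr(self, "_buffers", ()):
                yield f"{prefix}{name}", value

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        for name, buf in self._named_buffers():
            state[f"buffer:{name}"] = np.asarray(buf).copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        for name, value in state.items():
            if name.startswith("buffer:"):
                self._set_buffer(name[len("buffer:"):], value)
            else:
                if name not in params:
                    raise KeyError(f"unknown parameter {name!r}")
                if params[name].data.shape != value.shape:
                    raise ValueError(f"shape mismatch for {name!r}")
                params[name].data[...] = value

    def _set_buffer(self, dotted: str, value: np.ndarray) -> None:
        obj: Module = self
        parts = dotted.split(".")
        for part in parts[:-1]:
            attr = getattr(obj, part) if not part.isdigit() else obj[int(part)]  # type: ignore[index]
            obj = attr
        setattr(obj, parts[-1], np.asarray(value).copy())

    def checksum(self) -> float:
        """Order-stable sum over all parameters; used by freeze-contract tests."""
        return float(sum(np.sum(p.data) for _, p in sorted(self.named_parameters())))


class Linear(Module):
    """Affine map ``y = x @ W + b`` with Kaiming-uniform initialisation."""

    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator,
                 zero_init: bool = False):
        super().__init__()
        if zero_init:
            w = np.zeros((in_features, out_features))
        else:
            bound = np.sqrt(6.0 / in_features)
            w = rng.uniform(-bound, bound, size=(in_features, out_features))
        self.W = Parameter(w)
        self.b = Parameter(np.zeros(out_features))
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W.data + self.b.data

    def backward(self, grad: np.ndarray) -> np.ndarray:
        x = self._x
        self.W.grad += x.reshape(-1, x.shape[-1]).T @ grad.reshape(-1, grad.shape[-1])
        self.b.grad += grad.reshape(-1, grad.shape[-1]).sum(axis=0)
        return grad @ self.W.data.T


class ReLU(Module):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._mask


class LeakyReLU(Module):
    def __init__(self, negative_slope: float = 0.01):
        super().__init__()
        self.negative_slope = negative_slope

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, self.negative_slope * x)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return np.where(self._mask, grad, self.negative_slope * grad)


class Tanh(Module):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._y = np.tanh(x)
        return self._y

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * (1.0 - self._y ** 2)


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad


def _im2col(x: np.ndarray, k: int, stride: int, pad: int):
    """(B, C, H, W) -> column matrix (B, C*k*k, OH*OW) plus geometry.

    Channel-major column layout: filling by kernel offset keeps every copy
    contiguous along the output width, and the final reshape is free.
    """
    B, C, H, W = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    Hp, Wp = x.shape[2], x.shape[3]
    OH = (Hp - k) // stride + 1
    OW = (Wp - k) // stride + 1
    cols = np.empty((B, C, k, k, OH, OW), dtype=x.dtype)
    for i in range(k):
        for j in range(k):
            cols[:, :, i, j] = x[:, :, i:i + stride * OH:stride,
                                 j:j + stride * OW:stride]
    return cols.reshape(B, C * k * k, OH * OW), (Hp, Wp, OH, OW)


def _col2im(dcols: np.ndarray, x_shape, k: int, stride: int, pad: int, geom):
    """Scatter column gradients back onto the (padded) input image."""
    B, C, H, W = x_shape
    Hp, Wp, OH, OW = geom
    dxp = np.zeros((B, C, Hp, Wp))
    d = dcols.reshape(B, C, k, k, OH, OW)
    for i in range(k):
        for j in range(k):
            dxp[:, :, i:i + stride * OH:stride, j:j + stride * OW:stride] += d[:, :, i, j]
    if pad:
        return dxp[:, :, pad:-pad, pad:-pad]
    return dxp


class Conv2d(Module):
    """2-D convolution (cross-correlation) via im2col and BLAS matmul."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator, stride: int = 1, padding: int | None = None,
                 bias: bool = True):
        super().__init__()
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.stride = stride
        self.padding = kernel_size // 2 if padding is None else padding
        fan_in = in_channels * kernel_size * kernel_size
        bound = np.sqrt(2.0 / fan_in)
        self.W = Parameter(rng.normal(0.0, bound, size=(out_channels, fan_in)))
        self.b = Parameter(np.zeros(out_channels)) if bias else None
        self._cache = None

    def named_parameters(self, prefix: str = ""):
        yield f"{prefix}W", self.W
        if self.b is not None:
            yield f"{prefix}b", self.b

    def forward(self, x: np.ndarray) -> np.ndarray:
        cols, geom = _im2col(x, self.kernel_size, self.stride, self.padding)
        self._cache = (cols, x.shape, geom)
        out = np.matmul(self.W.data, cols)              # (B, Cout, OH*OW)
        if self.b is not None:
            out += self.b.data[None, :, None]
        B = x.shape[0]
        _, _, OH, OW = geom
        return out.reshape(B, self.out_channels, OH, OW)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        cols, x_shape, geom = self._cache
        B, Cout, OH, OW = grad.shape
        g = grad.reshape(B, Cout, OH * OW)
        self.W.grad += np.matmul(g, cols.transpose(0, 2, 1)).sum(axis=0)
        if self.b is not None:
            self.b.grad += g.sum(axis=(0, 2))
        dcols = np.matmul(self.W.data.T, g)             # (B, C*k*k, OH*OW)
        return _col2im(dcols, x_shape, self.kernel_size, self.stride, self.padding, geom)


class BatchNorm2d(Module):
    """Batch normalisation over (B, H, W) per channel, with running statistics."""

    def __init__(self, num_features: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.gamma = Parameter(np.ones(num_features))
        self.beta = Parameter(np.zeros(num_features))
        self.running_mean = np.zeros(num_features)
        self.running_var = np.ones(num_features)
        self._buffers = ("running_mean", "running_var")
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        if self.training:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv_std[None, :, None, None]
        self._cache = (xhat, inv_std, x.shape)
        return self.gamma.data[None, :, None, None] * xhat + self.beta.data[None, :, None, None]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xhat, inv_std, shape = self._cache
        B, C, H, W = shape
        n = B * H * W
        self.gamma.grad += np.sum(grad * xhat, axis=(0, 2, 3))
        self.beta.grad += np.sum(grad, axis=(0, 2, 3))
        g = grad * self.gamma.data[None, :, None, None]
        if not self.training:
            return g * inv_std[None, :, None, None]
        sum_g = g.sum(axis=(0, 2, 3), keepdims=True)
        sum_gx = (g * xhat).sum(axis=(0, 2, 3), keepdims=True)
        return (inv_std[None, :, None, None] / n) * (n * g - sum_g - xhat * sum_gx)


class GlobalAvgPool2d(Module):
    """(B, C, H, W) -> (B, C) spatial mean."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, grad: np.ndarray) -> np.ndarray:
        B, C, H, W = self._shape
        return np.broadcast_to(grad[:, :, None, None], self._shape) / (H * W)
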