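"""Neural-network layers on top of the autodiff engine.

Conventions follow common deep-learning practice: NCDHW tensor layout,
He fan-in initialisation for convolutions, batch normalisation with
running statistics, bias-free convolutions (a BatchNorm always follows).
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, conv3d

_F32 = np.float32


class Module:
    """Base class: recursive parameter discovery and state (de)serialisation."""

    def named_parameters(self, prefix=""):
        for name, value in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(value, Tensor) and value.requires_grad:
                yield key, value
            elif isinstance(value, Module):
                yield from value.named_parameters(f"{key}.")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{key}.{i}.")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def _named_modules(self, prefix=""):
        yield prefix.rstrip("."), self
        for name, value in vars(self).items():
            if isinstance(value, Module):
                yield from value._named_modules(f"{prefix}{name}.")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item._named_modules(f"{prefix}{name}.{i}.")

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        for mname, mod in self._named_modules():
            if isinstance(mod, BatchNorm):
                state[f"{mname}.running_mean"] = mod.running_mean.copy()
                state[f"{mname}.running_var"] = mod.running_var.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for name, p in self.named_parameters():
            p.data = np.asarray(state[name], dtype=_F32).copy()
        for mname, mod in self._named_modules():
            if isinstance(mod, BatchNorm):
                mod.running_mean = np.asarray(state[f"{mname}.running_mean"], _F32).copy()
                mod.running_var = np.asarray(state[f"{mname}.running_var"], _F32).copy()

    def param_hash(self) -> str:
        import hashlib

        h = hashlib.sha256()
        for name, arr in sorted(self.state_dict().items()):
            h.update(name.encode())
            h.update(np.ascontiguousarray(arr).tobytes())
        return h.hexdigest()


class Conv(Module):
    """Bias-free 3D convolution (2D is the unit-depth-kernel case)."""

    def __init__(self, c_in, c_out, kernel, stride=(1, 1, 1), rng=None):
        self.kernel = tuple(kernel)
        self.stride = tuple(stride)
        self.pad = tuple(k // 2 for k in self.kernel)
        fan_in = c_in * int(np.prod(self.kernel))
        std = np.sqrt(2.0 / fan_in)
        rng = rng or np.random.default_rng()
        self.weight = Tensor(
            rng.normal(0.0, std, size=(c_out, c_in, *self.kernel)), requires_grad=True
        )

    def __call__(self, x: Tensor) -> Tensor:
        return conv3d(x, self.weight, stride=self.stride, pad=self.pad)


class BatchNorm(Module):
    """Batch normalisation over (batch, depth, height, width) per channel."""

    def __init__(self, channels, eps=1e-5, momentum=0.1):
        self.gamma = Tensor(np.ones(channels), requires_grad=True)
        self.beta = Tensor(np.zeros(channels), requires_grad=True)
        self.running_mean = np.zeros(channels, dtype=_F32)
        self.running_var = np.ones(channels, dtype=_F32)
        self.eps = eps
        self.momentum = momentum

    def __call__(self, x: Tensor, training: bool) -> Tensor:
        axes = (0, 2, 3, 4)
        if training:
            mu = x.data.mean(axis=axes)
            var = x.data.var(axis=axes)
            m = self.momentum
            dt = mu.dtype
            self.running_mean = ((1 - m) * self.running_mean.astype(dt) + m * mu)
            self.running_var = ((1 - m) * self.running_var.astype(dt) + m * var)
        else:
            mu = self.running_mean.astype(x.data.dtype)
            var = self.running_var.astype(x.data.dtype)
        invstd = (1.0 / np.sqrt(var + self.eps)).astype(x.data.dtype)
        br = (1, -1, 1, 1, 1)
        xhat = (x.data - mu.reshape(br)) * invstd.reshape(br)
        gamma, beta = self.gamma, self.beta
        out = gamma.data.reshape(br) * xhat + beta.data.reshape(br)
        n = x.data.size // x.shape[1]

        def bwd(g):
            dgamma = (g * xhat).sum(axis=axes)
            dbeta = g.sum(axis=axes)
            scale = (gamma.data * invstd).reshape(br)
            if training:
                dx = scale / n * (
                    n * g - dbeta.reshape(br) - xhat * dgamma.reshape(br)
                )
            else:
                dx = g * scale
            return dx, dgamma, dbeta

        return Tensor(out, parents=(x, gamma, beta), bwd=bwd)


class Linear(Module):
    def __init__(self, n_in, n_out, rng=None):
        rng = rng or np.random.default_rng()
        std = np.sqrt(2.0 / n_in)
        self.weight = Tensor(rng.normal(0.0, std, size=(n_in, n_out)), requires_grad=True)
        self.bias = Tensor(np.zeros(n_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return (x @ self.weight) + self.bias


class Adam:
    """Adam optimiser with mutable learning rate (for plateau schedules)."""

    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / b1t
            vhat = self.v[i] / b2t
            p.data = (p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(p.data.dtype)

    def zero_grad(self):
        for p in self.params:
            p.grad = None
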