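"""Module/parameter containers and the basic layers used by all models."""

from __future__ import annotations

import numpy as np

from .autograd import Tensor

_init_rng = np.random.default_rng(0)


def manual_seed(seed: int) -> None:
    """Seed the global parameter-initialization RNG."""
    global _init_rng
    _init_rng = np.random.default_rng(seed)


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    def __init__(self):
        self.training = True

    @staticmethod
    def _flatten(value):
        """Yield (relpath, leaf) pairs through arbitrarily nested lists."""
        if isinstance(value, (list, tuple)):
            for i, item in enumerate(value):
                for sub, leaf in Module._flatten(item):
                    yield (f"{i}.{sub}" if sub else str(i)), leaf
        elif isinstance(value, (Parameter, Module)):
            yield "", value

    def parameters(self):
        params = []
        for value in self.__dict__.values():
            for _, leaf in Module._flatten(value):
                if isinstance(leaf, Parameter):
                    params.append(leaf)
                else:
                    params.extend(leaf.parameters())
        return params

    def modules(self):
        mods = [self]
        for value in self.__dict__.values():
            for _, leaf in Module._flatten(value):
                if isinstance(leaf, Module):
                    mods.extend(leaf.modules())
        return mods

    def train(self):
        for m in self.modules():
            m.training = True
        return self

    def eval(self):
        for m in self.modules():
            m.training = False
        return self

    def num_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict:
        """Flat dict of parameter and buffer arrays, keyed by path."""
        out = {}
        self._collect_state("", out)
        return out

    def _collect_state(self, prefix, out):
        for name, value in self.__dict__.items():
            key = f"{prefix}{name}"
            if isinstance(value, np.ndarray) and name.startswith("running_"):
                out[key] = value
                continue
            for rel, leaf in Module._flatten(value):
                sub = f"{key}.{rel}" if rel else key
                if isinstance(leaf, Parameter):
                    out[sub] = leaf.data
                else:
                    leaf._collect_state(sub + ".", out)

    def load_state_dict(self, state: dict):
        own = {}
        self._collect_refs("", own)
        missing = set(own) - set(state)
        if missing:
            raise KeyError(f"missing keys in state dict: {sorted(missing)[:5]}")
        for key, ref in own.items():
            arr = np.asarray(state[key], dtype=np.float32)
            if isinstance(ref, Parameter):
                ref.data = arr.reshape(ref.data.shape)
            else:  # (module, attr) buffer reference
                mod, attr = ref
                setattr(mod, attr, arr.reshape(getattr(mod, attr).shape))
        return self

    def _collect_refs(self, prefix, out):
        for name, value in self.__dict__.items():
            key = f"{prefix}{name}"
            if isinstance(value, np.ndarray) and name.startswith("running_"):
                out[key] = (self, name)
                continue
            for rel, leaf in Module._flatten(value):
                sub = f"{key}.{rel}" if rel else key
                if isinstance(leaf, Parameter):
                    out[sub] = leaf
                else:
                    leaf._collect_refs(sub + ".", out)

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Linear(Module):
    """Affine map on the last axis: y = x @ W + b, W of shape (in, out)."""

    def __init__(self, in_features: int, out_features: int, bias: bool = True):
        super().__init__()
        bound = 1.0 / np.sqrt(in_features)
        self.weight = Parameter(
            _init_rng.uniform(-bound, bound, (in_features, out_features)))
        self.bias = Parameter(
            _init_rng.uniform(-bound, bound, out_features)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        shape = x.shape
        if x.ndim > 2:  # one big GEMM beats numpy's stacked matmul
            x = x.reshape(-1, shape[-1])
        y = x @ self.weight
        if self.bias is not None:
            y = y + self.bias
        if len(shape) > 2:
            y = y.reshape(*shape[:-1], self.weight.shape[1])
        return y


class BatchNorm(Module):
    """Normalize channels-last input over all leading axes.

    Works for (n, C) point features and (n, k, C) edge features alike.
    """

    def __init__(self, num_features: int, eps: float = 1e-5,
                 momentum: float = 0.1):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.weight = Parameter(np.ones(num_features))
        self.bias = Parameter(np.zeros(num_features))
        self.running_mean = np.zeros(num_features, dtype=np.float32)
        self.running_var = np.ones(num_features, dtype=np.float32)

    def forward(self, x: Tensor) -> Tensor:
        axes = tuple(range(x.ndim - 1))
        if self.training:
            m = self.momentum
            self.running_mean = ((1 - m) * self.running_mean
                                 + m * x.data.mean(axis=axes))
            self.running_var = ((1 - m) * self.running_var
                                + m * x.data.var(axis=axes))
            # batch statistics stay inside the graph (full BN backward)
            mu = x.mean(axis=axes, keepdims=True)
            xc = x - mu
            var = (xc * xc).mean(axis=axes, keepdims=True)
            xn = xc * ((var + self.eps) ** -0.5)
        else:
            xn = (x - Tensor(self.running_mean)) * Tensor(
                1.0 / np.sqrt(self.running_var + self.eps))
        return xn * self.weight + self.bias


class Sequential(Module):
    def __init__(self, *layers):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x


class ReLU(Module):
    def forward(self, x):
        return x.relu()


class LeakyReLU(Module):
    def __init__(self, slope: float = 0.2):
        super().__init__()
        self.slope = slope

    def forward(self, x):
        return x.leaky_relu(self.slope)


def mlp(widths, act="leaky_relu", bn=True, final_act=True):
    """Shared per-point MLP: [Linear(+BN)(+act)] chain over channels-last."""
    layers = []
    n = len(widths) - 1
    for i in range(n):
        layers.append(Linear(widths[i], widths[i + 1], bias=not bn))
        last = i == n - 1
        if bn:
            layers.append(BatchNorm(widths[i + 1]))
        if final_act or not last:
            layers.append(LeakyReLU(0.2) if act == "leaky_relu" else ReLU())
    return Sequential(*layers)
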