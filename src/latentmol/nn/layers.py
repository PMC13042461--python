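"""Neural-network building blocks on top of the autodiff tensor."""

from __future__ import annotations

import numpy as np

from .tensor import Tensor, concat

__all__ = [
    "Module", "Parameter", "Linear", "BatchNorm1d", "LayerNorm", "Dropout",
    "Embedding", "kaiming_uniform", "xavier_uniform",
]


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def kaiming_uniform(rng: np.random.Generator, fan_in: int, shape) -> np.ndarray:
    """He fan-in uniform init, the standard choice ahead of ReLU-family units."""
    bound = np.sqrt(6.0 / fan_in)
    return rng.uniform(-bound, bound, size=shape)


def xavier_uniform(rng: np.random.Generator, fan_in: int, fan_out: int, shape) -> np.ndarray:
    """Glorot uniform init, the standard choice ahead of sigmoid/tanh units."""
    bound = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-bound, bound, size=shape)


class Module:
    """Minimal module container: parameter registry plus train/eval mode."""

    def __init__(self):
        self._params: dict[str, Parameter] = {}
        self._children: dict[str, "Module"] = {}
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self.__dict__.setdefault("_params", {})[name] = value
        elif isinstance(value, Module):
            self.__dict__.setdefault("_children", {})[name] = value
        elif isinstance(value, (list, tuple)) and value and all(
            isinstance(v, Module) for v in value
        ):
            for i, v in enumerate(value):
                self.__dict__.setdefault("_children", {})[f"{name}.{i}"] = v
        object.__setattr__(self, name, value)

    def parameters(self) -> list[Parameter]:
        out = list(self._params.values())
        for child in self._children.values():
            out.extend(child.parameters())
        return out

    def named_parameters(self, prefix: str = "") -> dict[str, Parameter]:
        out = {prefix + name: p for name, p in self._params.items()}
        for cname, child in self._children.items():
            out.update(child.named_parameters(prefix + cname + "."))
        return out

    def modules(self) -> list["Module"]:
        out = [self]
        for child in self._children.values():
            out.extend(child.modules())
        return out

    def train(self):
        for m in self.modules():
            m.training = True
        return self

    def eval(self):
        for m in self.modules():
            m.training = False
        return self

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    # flat (name -> array) serialization; buffers handled by subclasses
    def state_dict(self) -> dict[str, np.ndarray]:
        out = {k: p.data.copy() for k, p in self.named_parameters().items()}
        for i, m in enumerate(self.modules()):
            for bname, buf in getattr(m, "_buffers", {}).items():
                out[f"__buf{i}.{bname}"] = np.asarray(buf).copy()
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]):
        named = self.named_parameters()
        for k, p in named.items():
            p.data = np.asarray(state[k], dtype=np.float64).copy()
        for i, m in enumerate(self.modules()):
            bufs = getattr(m, "_buffers", None)
            if bufs:
                for bname in bufs:
                    key = f"__buf{i}.{bname}"
                    if key in state:
                        bufs[bname] = np.asarray(state[key], dtype=np.float64).copy()


class Linear(Module):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator,
                 bias: bool = True, init: str = "kaiming"):
        super().__init__()
        if init == "kaiming":
            w = kaiming_uniform(rng, in_dim, (in_dim, out_dim))
        else:
            w = xavier_uniform(rng, in_dim, out_dim, (in_dim, out_dim))
        self.weight = Parameter(w)
        self.bias = Parameter(np.zeros(out_dim)) if bias else None
        self.in_dim, self.out_dim = in_dim, out_dim

    def __call__(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class BatchNorm1d(Module):
    """Batch normalisation over the leading axis with running statistics.

    Evaluation mode uses the running statistics only, so inference outputs are
    independent of batch composition.
    """

    def __init__(self, dim: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.gamma = Parameter(np.ones(dim))
        self.beta = Parameter(np.zeros(dim))
        self.momentum, self.eps = momentum, eps
        self._buffers = {
            "running_mean": np.zeros(dim),
            "running_var": np.ones(dim),
        }

    def __call__(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=0, keepdims=True)
            var = ((x - mu) ** 2.0).mean(axis=0, keepdims=True)
            m = self.momentum
            self._buffers["running_mean"] = (
                (1 - m) * self._buffers["running_mean"] + m * mu.data.ravel()
            )
            self._buffers["running_var"] = (
                (1 - m) * self._buffers["running_var"] + m * var.data.ravel()
            )
            xhat = (x - mu) * (var + self.eps) ** -0.5
        else:
            mu = self._buffers["running_mean"]
            var = self._buffers["running_var"]
            xhat = (x - mu) * ((var + self.eps) ** -0.5)
        return xhat * self.gamma + self.beta


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.gamma = Parameter(np.ones(dim))
        self.beta = Parameter(np.zeros(dim))
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        var = ((x - mu) ** 2.0).mean(axis=-1, keepdims=True)
        return (x - mu) * (var + self.eps) ** -0.5 * self.gamma + self.beta


class Dropout(Module):
    """Inverted dropout; identity in evaluation mode."""

    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        self.p = p
        self.rng = rng

    def __call__(self, x: Tensor) -> Tensor:
        if not self.training or self.p == 0.0:
            return x
        mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * Tensor(mask)


class Embedding(Module):
    def __init__(self, num_embeddings: int, dim: int, rng: np.random.Generator):
        super().__init__()
        self.weight = Parameter(rng.normal(0.0, 0.02, size=(num_embeddings, dim)))

    def __call__(self, indices: np.ndarray) -> Tensor:
        from .tensor import gather_rows

        idx = np.asarray(indices, dtype=np.intp)
        flat = gather_rows(self.weight, idx.ravel())
        return flat.reshape(*idx.shape, self.weight.data.shape[1])
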