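"""Neural-network building blocks on top of the autodiff tensor.

Parameter initialization follows the usual fan-in scaled uniform scheme.
Every module draws its initial weights from an explicit ``numpy`` Generator
so that a fixed seed reproduces the whole model bit-for-bit.
"""

from __future__ import annotations

import numpy as np

from .tensor import Tensor, concat, stack

__all__ = ["Module", "Linear", "GRU", "BatchNorm", "MLP"]


class Module:
    """Base class: recursively collects trainable parameters."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for v in self.__dict__.values():
            if isinstance(v, Tensor) and v.requires_grad:
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
                    elif isinstance(item, Tensor) and item.requires_grad:
                        params.append(item)
        return params

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def train(self) -> "Module":
        self._set_mode(True)
        return self

    def eval(self) -> "Module":
        self._set_mode(False)
        return self

    def _set_mode(self, training: bool) -> None:
        for v in self.__dict__.values():
            if isinstance(v, Module):
                v._set_mode(training)
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        item._set_mode(training)
        if hasattr(self, "training"):
            self.training = training

    def state_dict(self) -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        self._collect_state("", out)
        return out

    def _collect_state(self, prefix: str, out: dict) -> None:
        for k, v in self.__dict__.items():
            name = f"{prefix}{k}"
            if isinstance(v, Tensor):
                out[name] = v.data.copy()
            elif isinstance(v, np.ndarray):
                out[name] = v.copy()
            elif isinstance(v, Module):
                v._collect_state(name + ".", out)
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        item._collect_state(f"{name}.{i}.", out)
                    elif isinstance(item, Tensor):
                        out[f"{name}.{i}"] = item.data.copy()

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        self._load_state("", state)

    def _load_state(self, prefix: str, state: dict) -> None:
        for k, v in self.__dict__.items():
            name = f"{prefix}{k}"
            if isinstance(v, Tensor) and name in state:
                v.data = state[name].copy()
            elif isinstance(v, np.ndarray) and name in state:
                self.__dict__[k] = state[name].copy()
            elif isinstance(v, Module):
                v._load_state(name + ".", state)
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        item._load_state(f"{name}.{i}.", state)
                    elif isinstance(item, Tensor) and f"{name}.{i}" in state:
                        item.data = state[f"{name}.{i}"].copy()


def _uniform(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    bound = 1.0 / np.sqrt(max(fan_in, 1))
    return rng.uniform(-bound, bound, size=shape)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        self.W = Tensor(_uniform(rng, (in_features, out_features), in_features), requires_grad=True)
        self.b = Tensor(np.zeros(out_features), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b


class GRU(Module):
    """Single-layer gated recurrent unit over a (batch, T, F) sequence.

    Returns per-step hidden states (batch, T, H) and the final hidden state
    (batch, H).  ``h0`` defaults to zeros; a decoder passes the encoder state.
    """

    def __init__(self, input_size: int, hidden_size: int, rng: np.random.Generator):
        self.hidden_size = hidden_size
        f = input_size + hidden_size
        self.Wz = Tensor(_uniform(rng, (f, hidden_size), f), requires_grad=True)
        self.bz = Tensor(np.zeros(hidden_size), requires_grad=True)
        self.Wr = Tensor(_uniform(rng, (f, hidden_size), f), requires_grad=True)
        self.br = Tensor(np.zeros(hidden_size), requires_grad=True)
        self.Wh = Tensor(_uniform(rng, (f, hidden_size), f), requires_grad=True)
        self.bh = Tensor(np.zeros(hidden_size), requires_grad=True)

    def __call__(self, x: Tensor, h0: Tensor | None = None) -> tuple[Tensor, Tensor]:
        batch, T = x.shape[0], x.shape[1]
        h = h0 if h0 is not None else Tensor(np.zeros((batch, self.hidden_size)))
        states = []
        for t in range(T):
            xt = x[:, t, :]
            xh = concat([xt, h], axis=1)
            z = (xh @ self.Wz + self.bz).sigmoid()
            r = (xh @ self.Wr + self.br).sigmoid()
            xrh = concat([xt, r * h], axis=1)
            h_tilde = (xrh @ self.Wh + self.bh).tanh()
            h = (1.0 - z) * h + z * h_tilde
            states.append(h)
        return stack(states, axis=1), h


class BatchNorm(Module):
    """Batch normalization over the last axis (features).

    Leading axes (batch, and for graph features the channel axis) are pooled
    when computing batch statistics.  Running estimates are used in eval
    mode.
    """

    def __init__(self, num_features: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(num_features), requires_grad=True)
        self.beta = Tensor(np.zeros(num_features), requires_grad=True)
        self.running_mean = np.zeros(num_features)
        self.running_var = np.ones(num_features)
        self.momentum = momentum
        self.eps = eps
        self.training = True

    def __call__(self, x: Tensor) -> Tensor:
        axes = tuple(range(x.ndim - 1))
        if self.training:
            mu = x.mean(axis=axes, keepdims=True)
            var = ((x - mu) ** 2).mean(axis=axes, keepdims=True)
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mu.data.reshape(-1)
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var.data.reshape(-1)
            x_hat = (x - mu) / ((var + self.eps) ** 0.5)
        else:
            x_hat = (x - Tensor(self.running_mean)) / Tensor(np.sqrt(self.running_var + self.eps))
        return x_hat * self.gamma + self.beta


class MLP(Module):
    """Two-layer perceptron with ReLU, used for the subject discriminator."""

    def __init__(self, in_features: int, hidden: int, out_features: int, rng: np.random.Generator):
        self.fc1 = Linear(in_features, hidden, rng)
        self.fc2 = Linear(hidden, out_features, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.fc2(self.fc1(x).relu())
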