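"""Minimal CPU tensor-network core.

Layers store their forward cache and implement an explicit backward pass;
there is no general autodiff.  All arrays are float32 numpy.  A layer is
used in a strict forward-then-backward cycle per step, so a single cache
per layer suffices; weight-shared branches (Siamese encoders, MIL instance
encoders) are evaluated by concatenating the branches along the batch axis
into one forward pass.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32


class Param:
    """A trainable tensor with an accumulated gradient."""

    __slots__ = ("data", "grad", "trainable")

    def __init__(self, data: np.ndarray, trainable: bool = True):
        self.data = np.ascontiguousarray(data, dtype=DTYPE)
        self.grad = np.zeros_like(self.data)
        self.trainable = trainable

    @property
    def size(self) -> int:
        return self.data.size


class Module:
    """Base class: tracks child modules, params and (non-trainable) buffers."""

    def __init__(self):
        self._params: dict[str, Param] = {}
        self._modules: dict[str, "Module"] = {}
        self._buffers: dict[str, np.ndarray] = {}
        self.training = True

    # -- registration ------------------------------------------------
    def __setattr__(self, name, value):
        if isinstance(value, Param):
            self.__dict__.setdefault("_params", {})[name] = value
        elif isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[name] = value
        object.__setattr__(self, name, value)

    def register_buffer(self, name: str, value: np.ndarray):
        self._buffers[name] = value
        object.__setattr__(self, name, value)

    # -- traversal ---------------------------------------------------
    def modules(self):
        yield self
        for m in self._modules.values():
            yield from m.modules()

    def parameters(self):
        for m in self.modules():
            yield from m._params.values()

    def trainable_parameters(self):
        return (p for p in self.parameters() if p.trainable)

    def num_parameters(self, trainable_only: bool = True) -> int:
        ps = self.trainable_parameters() if trainable_only else self.parameters()
        return int(sum(p.size for p in ps))

    # -- modes -------------------------------------------------------
    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def freeze(self):
        """Mark every parameter non-trainable (frozen-encoder contract)."""
        for p in self.parameters():
            p.trainable = False
        return self

    @property
    def frozen(self) -> bool:
        return all(not p.trainable for p in self.parameters())

    def zero_grad(self):
        for p in self.parameters():
            p.grad[...] = 0.0

    # -- state snapshot (weights + buffers, for best-epoch restore) --
    def state(self) -> list[np.ndarray]:
        out = [p.data.copy() for p in self.parameters()]
        for m in self.modules():
            out.extend(b.copy() for b in m._buffers.values())
        return out

    def load_state(self, state: list[np.ndarray]):
        it = iter(state)
        for p in self.parameters():
            p.data[...] = next(it)
        for m in self.modules():
            for name in m._buffers:
                m._buffers[name][...] = next(it)

    def checksum(self) -> float:
        """Sum of all parameter values; cheap change detector for freeze tests."""
        return float(sum(float(p.data.sum()) for p in self.parameters()))

    # -- compute -----------------------------------------------------
    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)
        for i, l in enumerate(layers):
            self._modules[f"layer{i}"] = l

    def append(self, layer: Module):
        self.layers.append(layer)
        self._modules[f"layer{len(self.layers) - 1}"] = layer

    def forward(self, x):
        for l in self.layers:
            x = l(x)
        return x

    def backward(self, grad):
        for l in reversed(self.layers):
            grad = l.backward(grad)
            if grad is None:
                break
        return grad
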