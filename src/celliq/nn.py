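"""Small neural-network building blocks on the autodiff engine.

Two-hidden-layer MLPs with SiLU activations, fan-in scaled Gaussian
initialization, and optional zero-initialized final layers (used so that
untrained readouts predict exactly zero).
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad

__all__ = ["MLP", "ParamStore"]


class ParamStore:
    """Flat name -> Tensor parameter registry shared by model components."""

    def __init__(self):
        self._params: dict[str, ad.Tensor] = {}

    def add(self, name: str, value: np.ndarray) -> ad.Tensor:
        if name in self._params:
            raise KeyError(f"duplicate parameter name {name!r}")
        t = ad.parameter(np.asarray(value, dtype=np.float64))
        self._params[name] = t
        return t

    def __getitem__(self, name: str) -> ad.Tensor:
        return self._params[name]

    def __contains__(self, name):
        return name in self._params

    def items(self):
        return self._params.items()

    def names(self):
        return list(self._params)

    def tensors(self):
        return list(self._params.values())

    def state_dict(self) -> dict:
        return {k: v.data.copy() for k, v in self._params.items()}

    def load_state_dict(self, state: dict):
        missing = set(self._params) ^ set(state)
        if missing:
            raise KeyError(f"parameter name mismatch: {sorted(missing)}")
        for k, v in state.items():
            arr = np.asarray(v, dtype=np.float64)
            if arr.shape != self._params[k].data.shape:
                raise ValueError(f"shape mismatch for {k!r}")
            self._params[k].data = arr.copy()


class MLP:
    """features -> hidden -> hidden -> out with SiLU; linear final layer."""

    def __init__(self, store: ParamStore, name: str, dims: list[int],
                 rng: np.random.Generator, zero_init_last: bool = False):
        self.weights = []
        self.biases = []
        for k in range(len(dims) - 1):
            fan_in = dims[k]
            w = rng.normal(scale=1.0 / np.sqrt(fan_in), size=(dims[k], dims[k + 1]))
            b = np.zeros(dims[k + 1])
            if zero_init_last and k == len(dims) - 2:
                w = np.zeros_like(w)
            self.weights.append(store.add(f"{name}.w{k}", w))
            self.biases.append(store.add(f"{name}.b{k}", b))

    def __call__(self, x: ad.Tensor) -> ad.Tensor:
        h = x
        last = len(self.weights) - 1
        for k, (w, b) in enumerate(zip(self.weights, self.biases)):
            h = ad.linear(h, w, b)
            if k != last:
                h = ad.silu(h)
        return h
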