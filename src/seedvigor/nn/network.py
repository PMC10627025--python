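"""Sequential container with activation capture for saliency and style mixing."""

from __future__ import annotations

import copy

import numpy as np

from .layers import Layer, Param

__all__ = ["Sequential"]


class Sequential:
    def __init__(self, layers: list[Layer]):
        self.layers = list(layers)
        self._acts: list[np.ndarray] | None = None

    # -- forward ---------------------------------------------------------
    def forward(self, x: np.ndarray, training: bool = False,
                rng: np.random.Generator | None = None,
                keep_acts: bool = False) -> np.ndarray:
        acts = [x] if keep_acts else None
        for layer in self.layers:
            x = layer.forward(x, training=training, rng=rng)
            if keep_acts:
                acts.append(x)
        self._acts = acts
        return x

    def __call__(self, x, **kw):
        return self.forward(x, **kw)

    def activation(self, index: int) -> np.ndarray:
        """Output of ``layers[index]`` from the last ``keep_acts`` forward."""
        if self._acts is None:
            raise RuntimeError("forward(..., keep_acts=True) has not been run")
        return self._acts[index + 1]

    # -- backward --------------------------------------------------------
    def backward(self, grad_out: np.ndarray, from_layer: int = 0) -> np.ndarray:
        """Backpropagate through ``layers[from_layer:]`` (gradients accumulate)."""
        for layer in reversed(self.layers[from_layer:]):
            grad_out = layer.backward(grad_out)
        return grad_out

    # -- parameter plumbing ---------------------------------------------
    def params(self, trainable_only: bool = False) -> list[Param]:
        out: list[Param] = []
        for layer in self.layers:
            if trainable_only and not layer.trainable:
                continue
            out.extend(layer.params())
        return out

    def zero_grad(self) -> None:
        for p in self.params():
            p.zero_grad()

    def n_params(self) -> int:
        return sum(p.value.size for p in self.params())

    def set_trainable(self, flag: bool) -> None:
        for layer in self.layers:
            layer.trainable = flag

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {p.name: p.value.copy() for p in self.params()}
        for layer in self.layers:
            for k, v in layer.buffers().items():
                state[k] = v.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for p in self.params():
            p.value[...] = state[p.name]
        for layer in self.layers:
            for k, v in layer.buffers().items():
                v[...] = state[k]

    def copy(self) -> "Sequential":
        dup = copy.deepcopy(self)
        dup._acts = None
        return dup
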