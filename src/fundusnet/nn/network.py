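"""Stage-sequential network with named tap points for saliency mapping."""

from __future__ import annotations

import numpy as np

from .layers import Layer


def stable_softmax(logits: np.ndarray) -> np.ndarray:
    """Row-wise softmax with max subtraction for numerical stability."""
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


class Network:
    """An ordered list of named stages (layers or blocks) ending in logits.

    The output of any stage can be tapped after a forward pass, gradients of
    a logit with respect to a tapped activation can be obtained by a partial
    backward pass, and the forward pass can be re-entered from a tap with a
    perturbed activation — the three capabilities Grad-CAM needs.
    """

    def __init__(self, stages: list[tuple[str, Layer]]):
        self.stages = list(stages)
        self._index = {name: i for i, (name, _) in enumerate(self.stages)}
        self._outputs: dict[str, np.ndarray] | None = None

    # ---- parameter access -------------------------------------------------
    def parameters(self) -> list[tuple[str, object]]:
        out = []
        for _, layer in self.stages:
            out.extend(layer.params())
        return out

    def zero_grads(self) -> None:
        for name, layer in self.stages:
            layer.zero_grads()

    def get_weights(self) -> dict[str, np.ndarray]:
        return {name: p.value.copy() for name, p in self.parameters()}

    def set_weights(self, weights: dict[str, np.ndarray]) -> None:
        for name, p in self.parameters():
            p.value[...] = weights[name]

    # ---- forward / backward ----------------------------------------------
    def forward(self, x: np.ndarray, training: bool = False, rng=None) -> np.ndarray:
        """Run all stages; returns logits and records every stage output."""
        outputs = {}
        for name, layer in self.stages:
            x = layer.forward(x, training=training, rng=rng)
            outputs[name] = x
        self._outputs = outputs
        return x

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return stable_softmax(self.forward(x, training=False))

    def stage_output(self, name: str) -> np.ndarray:
        if self._outputs is None:
            raise RuntimeError("no forward pass has been run")
        if name not in self._index:
            raise KeyError(f"unknown stage {name!r}")
        return self._outputs[name]

    def backward(self, dlogits: np.ndarray, stop_after: str | None = None) -> np.ndarray:
        """Backpropagate from the logits.

        With ``stop_after=name`` the pass stops once it has produced the
        gradient with respect to that stage's *output* (parameter gradients
        are accumulated only for the stages traversed). Without it, the pass
        reaches the input and returns its gradient.
        """
        stop_index = -1 if stop_after is None else self._index[stop_after]
        d = dlogits
        for i in range(len(self.stages) - 1, stop_index, -1):
            d = self.stages[i][1].backward(d)
        return d

    def forward_from(self, after_stage: str, value: np.ndarray) -> np.ndarray:
        """Recompute logits from a (possibly perturbed) tap activation,
        running only the stages downstream of ``after_stage`` in inference
        mode."""
        start = self._index[after_stage] + 1
        x = value
        for name, layer in self.stages[start:]:
            x = layer.forward(x, training=False)
        return x

    def stage_names(self) -> list[str]:
        return [name for name, _ in self.stages]
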