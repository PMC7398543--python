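"""Runnable U-net built from the declarative layer table.

:class:`UNet` walks the :func:`~patchunet.arch.layer_table` records to
execute forward and backward passes, so the instantiated network and the
closed-form architecture summary can never drift apart — the test suite
asserts exact integer equality between each weight array's size and the
table's ``n_params`` column.

Checkpoints are NumPy ``.npz`` archives with the :class:`ModelSpec` embedded
as JSON, so a saved model is self-describing.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from . import nnops
from .arch import LayerRecord, ModelSpec, layer_table
from .errors import ValidationError


class UNet:
    """Patch-wise multi-class U-net with explicit NumPy forward/backward.

    Parameters
    ----------
    spec
        Architecture hyperparameters (patch size, base filters, depth,
        classes).
    seed
        Seed for weight initialization.
    init
        ``"he_normal"`` (default, suited to ReLU stacks) or
        ``"glorot_uniform"``.
    dtype
        Parameter/activation dtype.  float32 is the training default;
        float64 is used by the numeric gradient checks.
    """

    def __init__(self, spec: ModelSpec | None = None, seed: int = 0,
                 init: str = "he_normal", dtype=np.float32):
        self.spec = spec or ModelSpec()
        self.records: list[LayerRecord] = layer_table(self.spec)
        self.dtype = dtype
        self.init = init
        self.params: dict[str, dict[str, np.ndarray]] = {}
        rng = np.random.default_rng(seed)
        for rec in self.records:
            if rec.type == "conv":
                kh, kw = rec.kernel
                shape = (kh, kw, rec.in_channels, rec.out_channels)
                self.params[rec.name] = {
                    "W": nnops.init_weights(shape, init, rng, dtype=dtype),
                    "b": np.zeros(rec.out_channels, dtype=dtype),
                }
        self._cache: dict[str, dict] = {}

    # ------------------------------------------------------------------ #

    @property
    def n_parameters(self) -> int:
        """Total trainable scalar count summed over the actual weight arrays."""
        return sum(int(p["W"].size + p["b"].size) for p in self.params.values())

    def layer_parameter_count(self, name: str) -> int:
        """Weight-array element count of one layer (0 for parameter-free layers)."""
        if name in self.params:
            p = self.params[name]
            return int(p["W"].size + p["b"].size)
        if any(rec.name == name for rec in self.records):
            return 0
        raise KeyError(f"no layer named {name!r}")

    # ------------------------------------------------------------------ #

    def forward(self, x: np.ndarray, cache: bool = False) -> np.ndarray:
        """Run a batch through the network.

        ``x`` is ``(N, P, P)`` or ``(N, P, P, 1)``; the result is
        ``(N, P, P, C)`` softmax class scores summing to 1 per pixel.
        """
        x = np.asarray(x, dtype=self.dtype)
        if x.ndim == 3:
            x = x[..., None]
        p = self.spec.patch_size
        if x.shape[1:] != (p, p, self.spec.in_channels):
            raise ValidationError(
                f"expected input (N, {p}, {p}, {self.spec.in_channels}), "
                f"got {x.shape}"
            )
        outputs: dict[str, np.ndarray] = {}
        self._cache = {}
        for rec in self.records:
            if rec.type == "input":
                outputs[rec.name] = x
                continue
            parent = outputs[rec.connected_to[0]]
            if rec.type == "conv":
                pad = nnops.same_padding(*rec.kernel)
                z = nnops.conv2d_forward(
                    parent, self.params[rec.name]["W"],
                    self.params[rec.name]["b"], pad,
                )
                if rec.activation == "relu":
                    out = np.maximum(z, 0)
                elif rec.activation == "softmax":
                    out = nnops.softmax(z)
                else:
                    out = z
                if cache:
                    self._cache[rec.name] = {"x": parent, "z": z}
            elif rec.type == "maxpool":
                out, idx = nnops.maxpool2_forward(parent)
                if cache:
                    self._cache[rec.name] = {"idx": idx}
            elif rec.type == "upsample":
                out = nnops.upsample2_forward(parent)
            elif rec.type == "concat":
                left = outputs[rec.connected_to[0]]
                right = outputs[rec.connected_to[1]]
                out = np.concatenate([left, right], axis=-1)
                if cache:
                    self._cache[rec.name] = {"split": left.shape[-1]}
            else:  # pragma: no cover - table types are closed
                raise ValidationError(f"unknown layer type {rec.type}")
            outputs[rec.name] = out
        self._outputs = outputs if cache else {}
        return outputs[self.records[-1].name]

    def backward(self, dlogits: np.ndarray) -> dict[str, dict[str, np.ndarray]]:
        """Backpropagate from the head's pre-softmax logits gradient.

        The softmax + cross-entropy derivative is folded into ``dlogits``
        by the caller (``(probs - targets) / n_pixels``), the standard
        simplification.  Requires a preceding ``forward(..., cache=True)``.
        """
        if not self._cache:
            raise ValidationError("backward requires forward(..., cache=True)")
        grads: dict[str, dict[str, np.ndarray]] = {}
        dacc: dict[str, np.ndarray] = {self.records[-1].name: dlogits}
        for rec in reversed(self.records):
            if rec.type == "input" or rec.name not in dacc:
                continue
            d = dacc.pop(rec.name)
            if rec.type == "conv":
                c = self._cache[rec.name]
                if rec.activation == "relu":
                    d = d * (c["z"] > 0)
                # softmax head: d already wrt logits
                pad = nnops.same_padding(*rec.kernel)
                dx, dw, db = nnops.conv2d_backward(
                    d, c["x"], self.params[rec.name]["W"], pad
                )
                grads[rec.name] = {"W": dw, "b": db}
            elif rec.type == "maxpool":
                dx = nnops.maxpool2_backward(d, self._cache[rec.name]["idx"])
            elif rec.type == "upsample":
                dx = nnops.upsample2_backward(d)
            elif rec.type == "concat":
                split = self._cache[rec.name]["split"]
                left_name, right_name = rec.connected_to
                _accumulate(dacc, left_name, d[..., :split])
                _accumulate(dacc, right_name, d[..., split:])
                continue
            _accumulate(dacc, rec.connected_to[0], dx)
        return grads

    # ------------------------------------------------------------------ #

    def save(self, path: str | Path) -> None:
        arrays = {"__spec__": np.frombuffer(
            json.dumps(dataclasses.asdict(self.spec)).encode(), dtype=np.uint8
        )}
        for name, p in self.params.items():
            arrays[f"{name}.W"] = p["W"]
            arrays[f"{name}.b"] = p["b"]
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "UNet":
        with np.load(path) as data:
            spec = ModelSpec(**json.loads(bytes(data["__spec__"]).decode()))
            net = cls(spec)
            for name in net.params:
                net.params[name]["W"] = data[f"{name}.W"]
                net.params[name]["b"] = data[f"{name}.b"]
        return net


def _accumulate(dacc: dict[str, np.ndarray], name: str, grad: np.ndarray) -> None:
    if name in dacc:
        dacc[name] = dacc[name] + grad
    else:
        dacc[name] = grad
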