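"""Declarative U-net architecture: layer table and closed-form parameter counts.

The network is described first as a list of :class:`LayerRecord` entries —
name, type, kernel, channels, output shape, parameter count, connectivity —
from which both the runnable network and an architecture summary are
produced.  Parameter counts follow the closed form
``(kh*kw*c_in + 1) * c_out`` (bias in every convolution), so the table can
be verified against the instantiated network's weight arrays with exact
integer equality.

At the default configuration (128-pixel patches, 64 base filters, depth 3,
4 classes) the table has 28 rows: 1 input, 18 convolutions, 3 max-pooling,
3 up-sampling and 3 concatenation layers, named ``conv2d_1`` ..
``conv2d_18``, ``max_pooling2d_k``, ``up_sampling2d_k``, ``concatenated_k``.

The decoder's "up-convolution" is a x2 nearest-neighbor upsample followed by
a 2x2 same-padding convolution that halves the channel count; this is the
only reading consistent with the published per-layer counts (e.g.
524544 = (2*2*512 + 1) * 256), as opposed to a strided transpose
convolution.
"""

from __future__ import annotations

import dataclasses
import io
import json
from dataclasses import dataclass, field

import yaml

from .errors import ValidationError


@dataclass(frozen=True)
class ModelSpec:
    """Hyperparameters that determine the whole architecture.

    ``patch_size`` must be divisible by ``2**depth`` so the bottleneck
    resolution ``patch_size / 2**depth`` is integral (16x16 at defaults).
    Filter counts double at each pooling stage: F, 2F, ..., F*2**depth at
    the bottleneck (512 at defaults).
    """

    patch_size: int = 128
    in_channels: int = 1
    base_filters: int = 64
    depth: int = 3
    n_classes: int = 4
    kernel: int = 3
    upconv_kernel: int = 2

    def __post_init__(self) -> None:
        if self.patch_size % (2**self.depth):
            raise ValidationError(
                f"patch_size {self.patch_size} not divisible by 2^depth={2**self.depth}"
            )
        if min(self.patch_size, self.base_filters, self.depth, self.n_classes) < 1:
            raise ValidationError("all ModelSpec dimensions must be >= 1")

    @property
    def bottleneck_filters(self) -> int:
        return self.base_filters * 2**self.depth

    @property
    def bottleneck_size(self) -> int:
        return self.patch_size // 2**self.depth

    def to_yaml(self) -> str:
        return yaml.safe_dump(dataclasses.asdict(self), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "ModelSpec":
        data = yaml.safe_load(text) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(data) - known
        if bad:
            raise ValidationError(f"unknown ModelSpec keys: {sorted(bad)}")
        return cls(**data)


@dataclass(frozen=True)
class LayerRecord:
    """One row of the architecture table."""

    name: str
    type: str  # input | conv | maxpool | upsample | concat
    kernel: tuple[int, int] | None
    in_channels: int
    out_channels: int
    output_shape: tuple[int, int, int]  # (H, W, C)
    n_params: int
    connected_to: tuple[str, ...]
    activation: str | None = None  # relu | softmax | None


def _conv_params(kh: int, kw: int, c_in: int, c_out: int) -> int:
    return (kh * kw * c_in + 1) * c_out


def layer_table(spec: ModelSpec) -> list[LayerRecord]:
    """Enumerate every layer of the U-net for ``spec``, in execution order."""
    records: list[LayerRecord] = []
    k = spec.kernel
    uk = spec.upconv_kernel
    size = spec.patch_size
    conv_i = 0

    def conv(prev: str, c_in: int, c_out: int, kh: int, kw: int, size: int,
             activation: str = "relu") -> str:
        nonlocal conv_i
        conv_i += 1
        name = f"conv2d_{conv_i}"
        records.append(
            LayerRecord(
                name=name,
                type="conv",
                kernel=(kh, kw),
                in_channels=c_in,
                out_channels=c_out,
                output_shape=(size, size, c_out),
                n_params=_conv_params(kh, kw, c_in, c_out),
                connected_to=(prev,),
                activation=activation,
            )
        )
        return name

    records.append(
        LayerRecord(
            name="input_1",
            type="input",
            kernel=None,
            in_channels=0,
            out_channels=spec.in_channels,
            output_shape=(size, size, spec.in_channels),
            n_params=0,
            connected_to=(),
        )
    )
    prev = "input_1"
    channels = spec.in_channels
    skips: list[tuple[str, int]] = []  # (layer name, channels) per encoder stage

    # contracting path: depth stages of [conv, conv, pool], doubling filters
    for stage in range(spec.depth):
        c_out = spec.base_filters * 2**stage
        prev = conv(prev, channels, c_out, k, k, size)
        prev = conv(prev, c_out, c_out, k, k, size)
        skips.append((prev, c_out))
        channels = c_out
        size //= 2
        pool = f"max_pooling2d_{stage + 1}"
        records.append(
            LayerRecord(
                name=pool,
                type="maxpool",
                kernel=(2, 2),
                in_channels=channels,
                out_channels=channels,
                output_shape=(size, size, channels),
                n_params=0,
                connected_to=(prev,),
            )
        )
        prev = pool

    # bottleneck: two convs at F * 2^depth
    c_out = spec.bottleneck_filters
    prev = conv(prev, channels, c_out, k, k, size)
    prev = conv(prev, c_out, c_out, k, k, size)
    channels = c_out

    # expansive path: upsample, 2x2 conv halving channels, skip concat, two convs
    for stage in range(spec.depth):
        size *= 2
        up = f"up_sampling2d_{stage + 1}"
        records.append(
            LayerRecord(
                name=up,
                type="upsample",
                kernel=(2, 2),
                in_channels=channels,
                out_channels=channels,
                output_shape=(size, size, channels),
                n_params=0,
                connected_to=(prev,),
            )
        )
        c_out = channels // 2
        upconv = conv(up, channels, c_out, uk, uk, size)
        skip_name, skip_c = skips[spec.depth - 1 - stage]
        concat = f"concatenated_{stage + 1}"
        records.append(
            LayerRecord(
                name=concat,
                type="concat",
                kernel=None,
                in_channels=skip_c + c_out,
                out_channels=skip_c + c_out,
                output_shape=(size, size, skip_c + c_out),
                n_params=0,
                connected_to=(skip_name, upconv),
            )
        )
        prev = conv(concat, skip_c + c_out, c_out, k, k, size)
        prev = conv(prev, c_out, c_out, k, k, size)
        channels = c_out

    # 1x1 classification head with per-pixel softmax
    conv(prev, channels, spec.n_classes, 1, 1, size, activation="softmax")
    return records


def count_parameters(records: list[LayerRecord], layer: str | None = None) -> int:
    """Total closed-form parameter count, or a single named layer's count."""
    if layer is not None:
        for rec in records:
            if rec.name == layer:
                return rec.n_params
        raise KeyError(f"no layer named {layer!r}")
    return sum(rec.n_params for rec in records)


def summarize_architecture(records: list[LayerRecord], fmt: str = "text") -> str:
    """Render the layer table as an aligned text table or JSON.

    JSON output round-trips losslessly through ``json.loads``/``dumps``.
    """
    if fmt == "json":
        rows = [
            {
                "name": r.name,
                "type": r.type,
                "kernel": list(r.kernel) if r.kernel else None,
                "in_channels": r.in_channels,
                "out_channels": r.out_channels,
                "output_shape": list(r.output_shape),
                "n_params": r.n_params,
                "connected_to": list(r.connected_to),
                "activation": r.activation,
            }
            for r in records
        ]
        return json.dumps({"layers": rows, "total_params": count_parameters(records)},
                          indent=2, sort_keys=True)
    if fmt != "text":
        raise ValidationError(f"unknown summary format {fmt!r}")
    type_names = {
        "input": "Image",
        "conv": "2D Convolution",
        "maxpool": "Max Pooling 2D",
        "upsample": "Up Sampling 2D",
        "concat": "Concatenate",
    }
    buf = io.StringIO()
    header = f"{'No':>3}  {'Layer name':<18}{'Type':<16}{'Output Shape':<14}{'Params':>10}  Connected to"
    buf.write(header + "\n")
    buf.write("-" * len(header) + "\n")
    for i, r in enumerate(records, start=1):
        shape = "x".join(str(d) for d in r.output_shape)
        conn = ", ".join(r.connected_to) if r.connected_to else "-"
        buf.write(
            f"{i:>3}  {r.name:<18}{type_names[r.type]:<16}{shape:<14}{r.n_params:>10}  {conn}\n"
        )
    buf.write(f"Total trainable parameters: {count_parameters(records)}\n")
    return buf.getvalue()
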