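"""Reference architectures and shape propagation.

An :class:`ArchitectureSpec` is an ordered list of layer descriptors
ending in exactly one output head.  Shapes are propagated symbolically
at build time so an input too short for the convolution/pooling stack
fails with the offending layer named, before any weights exist.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

__all__ = [
    "LayerSpec", "ArchitectureSpec", "ShapeError",
    "build_hdi_model", "build_risk_model", "build_mlp", "build_lstm",
]


class ShapeError(ValueError):
    """Raised when a layer stack cannot fit the input length."""


@dataclass(frozen=True)
class LayerSpec:
    kind: str  # conv | maxpool | batchnorm | global_average_pool | dense |
               # dropout | relu | flatten | lstm | output
    params: dict[str, Any] = field(default_factory=dict)


@dataclass(frozen=True)
class ArchitectureSpec:
    """Layer list plus the 1-D input length the model is built for."""

    input_length: int
    layers: tuple[LayerSpec, ...]
    name: str = "model"

    def __post_init__(self) -> None:
        outputs = [l for l in self.layers if l.kind == "output"]
        if len(outputs) != 1 or self.layers[-1].kind != "output":
            raise ValueError("spec must end in exactly one output layer")
        self.shapes()  # validate at construction

    @property
    def head(self) -> str:
        return self.layers[-1].params["head"]

    @property
    def n_classes(self) -> int:
        return self.layers[-1].params.get("n_classes", 1)

    def shapes(self) -> list[tuple[str, tuple[int, ...]]]:
        """Per-layer output shapes (excluding the batch axis)."""
        shape: tuple[int, ...] = (self.input_length, 1)
        report: list[tuple[str, tuple[int, ...]]] = [("input", shape)]
        for spec in self.layers:
            k = spec.kind
            p = spec.params
            if k == "conv":
                if len(shape) != 2:
                    raise ShapeError(f"conv after flat tensor (at {k})")
                length = shape[0] - p["kernel"] + 1
                if length < 1:
                    raise ShapeError(
                        f"conv kernel {p['kernel']} does not fit length {shape[0]}"
                    )
                shape = (length, p["filters"])
            elif k == "maxpool":
                w, s = p.get("window", 2), p.get("stride", 2)
                length = (shape[0] - w) // s + 1
                if length < 1:
                    raise ShapeError(f"maxpool window {w} does not fit length {shape[0]}")
                shape = (length, shape[1])
            elif k == "batchnorm":
                pass
            elif k == "global_average_pool":
                shape = (shape[1],)
            elif k == "flatten":
                n = 1
                for d in shape:
                    n *= d
                shape = (n,)
            elif k == "lstm":
                shape = (p["units"],)
            elif k == "dense":
                if len(shape) != 1:
                    raise ShapeError("dense requires a flat tensor; add a pooling/flatten layer")
                shape = (p["units"],)
            elif k in {"dropout", "relu"}:
                pass
            elif k == "output":
                if len(shape) != 1:
                    raise ShapeError("output head requires a flat tensor")
                shape = (p.get("n_classes", 1),)
            else:
                raise ValueError(f"unknown layer kind {k!r}")
            report.append((k, shape))
        return report


def _conv(filters: int, kernel: int = 3) -> LayerSpec:
    return LayerSpec("conv", {"filters": filters, "kernel": kernel, "activation": "relu"})


def build_hdi_model(input_length: int, dropout: float = 0.5) -> ArchitectureSpec:
    """Binary interaction CNN.

    Four kernel-3 valid convolutions (64, 64, 128, 1024 filters) with two
    window-2/stride-2 max-pools, global average pooling, dense(256),
    dropout, four dense(128) layers and a sigmoid output.
    """
    layers = (
        _conv(64), _conv(64),
        LayerSpec("maxpool", {"window": 2, "stride": 2}),
        _conv(128), _conv(1024),
        LayerSpec("maxpool", {"window": 2, "stride": 2}),
        LayerSpec("global_average_pool"),
        LayerSpec("dense", {"units": 256, "activation": "relu"}),
        LayerSpec("dropout", {"rate": dropout}),
        LayerSpec("dense", {"units": 128, "activation": "relu"}),
        LayerSpec("dense", {"units": 128, "activation": "relu"}),
        LayerSpec("dense", {"units": 128, "activation": "relu"}),
        LayerSpec("dense", {"units": 128, "activation": "relu"}),
        LayerSpec("output", {"head": "sigmoid"}),
    )
    return ArchitectureSpec(input_length, layers, name="hdi_cnn")


def build_risk_model(input_length: int, n_classes: int = 3,
                     dropout: float = 0.5) -> ArchitectureSpec:
    """Risk-level CNN: same trunk with batch normalization after conv
    blocks 2 and 4, an extra activation layer, five dense layers and a
    softmax head."""
    layers = (
        _conv(64), _conv(64),
        LayerSpec("batchnorm"),
        LayerSpec("maxpool", {"window": 2, "stride": 2}),
        _conv(128), _conv(1024),
        LayerSpec("batchnorm"),
        LayerSpec("maxpool", {"window": 2, "stride": 2}),
        LayerSpec("relu"),
        LayerSpec("global_average_pool"),
        LayerSpec("dense", {"units": 256, "activation": "relu"}),
        LayerSpec("dropout", {"rate": dropout}),
        LayerSpec("dense", {"units": 128, "activation": "relu"}),
        LayerSpec("dense", {"units": 128, "activation": "relu"}),
        LayerSpec("dense", {"units": 128, "activation": "relu"}),
        LayerSpec("dense", {"units": 128, "activation": "relu"}),
        LayerSpec("output", {"head": "softmax", "n_classes": n_classes}),
    )
    return ArchitectureSpec(input_length, layers, name="risk_cnn")


def build_mlp(input_length: int, n_classes: int = 1,
              hidden: tuple[int, ...] = (256, 256, 256)) -> ArchitectureSpec:
    """Multilayer-perceptron baseline: three ReLU dense layers."""
    layers: list[LayerSpec] = [LayerSpec("flatten")]
    for units in hidden:
        layers.append(LayerSpec("dense", {"units": units, "activation": "relu"}))
    head = {"head": "sigmoid"} if n_classes == 1 else {"head": "softmax", "n_classes": n_classes}
    layers.append(LayerSpec("output", head))
    return ArchitectureSpec(input_length, tuple(layers), name="mlp")


def build_lstm(input_length: int, n_classes: int = 1, units: int = 128) -> ArchitectureSpec:
    """LSTM baseline: the feature vector read as a (length, 1) sequence,
    one recurrent layer, then a dense head."""
    head = {"head": "sigmoid"} if n_classes == 1 else {"head": "softmax", "n_classes": n_classes}
    layers = (
        LayerSpec("lstm", {"units": units}),
        LayerSpec("dense", {"units": 64, "activation": "relu"}),
        LayerSpec("output", head),
    )
    return ArchitectureSpec(input_length, layers, name="lstm")
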