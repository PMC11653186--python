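"""Backend-neutral network descriptions built from chromosomes.

Two templates are produced.  The evolved CNN stacks, per chromosome layer,
a convolution (filters and square kernel from the genome) followed by batch
normalization and a rectifier, with a 2x2/stride-2 max-pool after every
second conv block, then flatten and a single sigmoid output unit.  The
frozen-backbone variant is a flatten/dropout/dense head whose dense widths
come from a :class:`~evocnn.genome.DenseHeadGenome`; it attaches to a fixed
feature extractor whose weights are never trained.

Convolutions use zero ('same') padding, so spatial size changes only at the
pooling layers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

from .genome import ConvGenome, DenseHeadGenome

__all__ = ["Layer", "ArchitectureSpec", "ShapeError", "build_cnn_spec",
           "build_head_spec", "count_params"]


class ShapeError(ValueError):
    """Input too small for the pooling schedule, or unresolved shapes."""


@dataclass(frozen=True)
class Layer:
    kind: str  # conv | batch_norm | max_pool | flatten | dropout | dense | output
    params: dict = field(default_factory=dict)

    def summary(self) -> str:
        inner = ", ".join(f"{k}={v}" for k, v in sorted(self.params.items()))
        return f"{self.kind}({inner})"


@dataclass(frozen=True)
class ArchitectureSpec:
    """Ordered layer descriptors plus the input shape (H, W, C)."""

    layers: tuple[Layer, ...]
    input_shape: tuple[int, int, int]
    frozen_backbone: bool = False
    feature_dim: int | None = None  # flattened input size when frozen_backbone

    def kinds(self) -> list[str]:
        return [l.kind for l in self.layers]

    def count_kind(self, kind: str) -> int:
        return sum(1 for l in self.layers if l.kind == kind)

    def to_json(self) -> str:
        return json.dumps(
            {
                "input_shape": list(self.input_shape),
                "frozen_backbone": self.frozen_backbone,
                "feature_dim": self.feature_dim,
                "layers": [{"kind": l.kind, "params": l.params} for l in self.layers],
            }
        )

    def summary(self) -> str:
        """One line per layer, for run logs."""
        head = f"input {self.input_shape}" + (
            " (frozen backbone features)" if self.frozen_backbone else ""
        )
        return "\n".join([head] + [l.summary() for l in self.layers])


def build_cnn_spec(
    genome: ConvGenome, input_shape: tuple[int, int, int]
) -> ArchitectureSpec:
    """Evolved-CNN template: per genome layer conv+batch_norm (+relu), a
    2x2 max-pool after every second conv block, then flatten and a
    1-unit sigmoid output.

    Raises :class:`ShapeError` if pooling would drive a spatial dimension
    below 1, naming the offending pool.
    """
    h, w, c = input_shape
    if h < 1 or w < 1 or c < 1:
        raise ShapeError(f"invalid input shape {input_shape}")
    n_pools = len(genome) // 2
    if min(h, w) < 2 ** n_pools:
        raise ShapeError(
            f"input {h}x{w} too small for {n_pools} pooling layers "
            f"(needs at least {2 ** n_pools} pixels per side)"
        )
    layers: list[Layer] = []
    for i, (filters, kernel) in enumerate(genome.layers, start=1):
        layers.append(Layer("conv", {"filters": filters, "kernel": kernel,
                                     "padding": "same", "activation": "relu"}))
        layers.append(Layer("batch_norm", {}))
        if i % 2 == 0:
            if h < 2 or w < 2:
                raise ShapeError(
                    f"max_pool after conv block {i} would reduce a {h}x{w} map below 1x1"
                )
            h, w = h // 2, w // 2
            layers.append(Layer("max_pool", {"size": 2, "stride": 2}))
    layers.append(Layer("flatten", {}))
    layers.append(Layer("output", {"units": 1, "activation": "sigmoid"}))
    return ArchitectureSpec(tuple(layers), input_shape)


def build_head_spec(
    head: DenseHeadGenome, dropout_rate: float = 0.5, feature_dim: int = 512
) -> ArchitectureSpec:
    """Frozen-backbone head: flatten -> dropout -> dense(width_1) -> ... ->
    1-unit sigmoid output, over a feature vector of ``feature_dim``."""
    if len(head.widths) == 0:
        raise ValueError("head genome has no dense layers")
    if feature_dim < 1:
        raise ShapeError(f"feature_dim must be >= 1, got {feature_dim}")
    if not 0.0 <= dropout_rate < 1.0:
        raise ValueError(f"dropout_rate must be in [0, 1), got {dropout_rate}")
    layers = [Layer("flatten", {}), Layer("dropout", {"rate": dropout_rate})]
    for width in head.widths:
        layers.append(Layer("dense", {"units": width, "activation": "relu"}))
    layers.append(Layer("output", {"units": 1, "activation": "sigmoid"}))
    return ArchitectureSpec(
        tuple(layers),
        input_shape=(1, 1, feature_dim),
        frozen_backbone=True,
        feature_dim=feature_dim,
    )


def count_params(spec: ArchitectureSpec) -> int:
    """Exact trainable-parameter count.

    conv: k*k*C_in*F + F; batch_norm: 2 per channel (scale, shift); dense
    and output: in*out + out.  Frozen-backbone features contribute nothing.
    """
    h, w, c = spec.input_shape
    if spec.frozen_backbone:
        c = spec.feature_dim
        h = w = 1
    flat: int | None = None
    total = 0
    for layer in spec.layers:
        if layer.kind == "conv":
            f, k = layer.params["filters"], layer.params["kernel"]
            total += k * k * c * f + f
            c = f
        elif layer.kind == "batch_norm":
            total += 2 * c
        elif layer.kind == "max_pool":
            h, w = h // 2, w // 2
            if h < 1 or w < 1:
                raise ShapeError("pooling reduced a spatial dimension below 1")
        elif layer.kind == "flatten":
            flat = h * w * c
        elif layer.kind in ("dense", "output"):
            if flat is None:
                raise ShapeError(f"{layer.kind} layer before flatten")
            units = layer.params["units"]
            total += flat * units + units
            flat = units
        elif layer.kind == "dropout":
            pass
        else:
            raise ValueError(f"unknown layer kind {layer.kind!r}")
    return total
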