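"""Assembly of the GGENet classifier family from a declarative spec.

The teacher (GGENet-T, base width 32) and the student (GGENet-S, base
width 16) share one fixed stage plan and differ only in width; smaller
base widths give toy variants for testing. The plan, downstream of the
stem, is

    2 x module | down | ATTN | 2 x module | down | 2 x module | down |
    ATTN | 3 x module | down | 3 x module | down | ATTN | 3 x module

followed by global average pooling and a biased linear head. The three
attention-module outputs (shallow -> deep) are the attention maps used
for distillation; on a 224 input they sit at 56x56, 14x14 and 3x3 with
2x, 8x and 32x the base width.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .attention import AttentionModule
from .autodiff import Module, Parameter, Tensor
from .blocks import Downsample, GGEConvModule, Stem

__all__ = ["ModelSpec", "GGENet", "build_model", "forward_with_attention",
           "count_parameters", "closed_form_param_count",
           "save_checkpoint", "load_checkpoint",
           "TEACHER_PARAM_COUNT", "STUDENT_PARAM_COUNT"]

# stage plan tokens: m = GRN-GELU Conv module, d = downsample, a = attention
STAGE_PLAN = ("m", "m", "d", "a", "m", "m", "d", "m", "m", "d",
              "a", "m", "m", "m", "d", "m", "m", "m", "d", "a", "m", "m", "m")

TEACHER_PARAM_COUNT = 7_190_092   # base width 32, 6 classes
STUDENT_PARAM_COUNT = 1_818_940   # base width 16, 6 classes, no adapters


@dataclass
class ModelSpec:
    """Width/attention recipe; teacher = base_width 32, student = 16."""

    base_width: int = 32
    n_classes: int = 6
    attention_r: int = 16
    spatial_k: int = 7
    input_size: int = 224
    sequential_attention: bool = True

    def __post_init__(self):
        if self.base_width < 1:
            raise ValueError("base_width must be >= 1")
        for mult in (2, 8, 32):
            c = self.base_width * mult
            if c % self.attention_r != 0:
                raise ValueError(
                    f"attention reduction {self.attention_r} does not divide the "
                    f"attention width {c} (base_width {self.base_width})")

    @classmethod
    def teacher(cls, **kw) -> "ModelSpec":
        return cls(base_width=32, **kw)

    @classmethod
    def student(cls, **kw) -> "ModelSpec":
        return cls(base_width=16, **kw)

    def attention_channels(self) -> tuple:
        return tuple(self.base_width * m for m in (2, 8, 32))

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        return cls(**d)


class _ClassifierHead(Module):
    # zero-initialized: the network starts at the uniform prediction, which
    # keeps the first optimizer steps small and the early training stable
    def __init__(self, channels: int, n_classes: int, rng, dtype):
        self.weight = Parameter(np.zeros((n_classes, channels)), dtype=dtype)
        self.bias = Parameter(np.zeros(n_classes), dtype=dtype)

    def forward(self, x: Tensor) -> Tensor:
        pooled = x.mean(axis=(2, 3))             # global average pool to 1x1
        return pooled @ self.weight.transpose2d() + self.bias


class GGENet(Module):
    """The assembled network; see the module docstring for the stage plan."""

    def __init__(self, spec: ModelSpec, seed: int = 0, dtype=np.float64):
        rng = np.random.default_rng(seed)
        self.spec = spec
        self.stem = Stem(spec.base_width, rng=rng, dtype=dtype)
        layers = []
        c = spec.base_width
        for token in STAGE_PLAN:
            if token == "m":
                layers.append(GGEConvModule(c, rng=rng, dtype=dtype))
            elif token == "d":
                layers.append(Downsample(c, rng=rng, dtype=dtype))
                c *= 2
            elif token == "a":
                layers.append(AttentionModule(
                    c, reduction=spec.attention_r, kernel_size=spec.spatial_k,
                    sequential=spec.sequential_attention, rng=rng, dtype=dtype))
        self.layers = layers
        self.head = _ClassifierHead(c, spec.n_classes, rng, dtype)

    def forward(self, x, capture_attention: bool = False):
        if not isinstance(x, Tensor):
            x = Tensor(np.asarray(x))
        h = self.stem(x)
        maps = []
        for layer in self.layers:
            h = layer(h)
            if isinstance(layer, AttentionModule):
                maps.append(h)
        logits = self.head(h)
        if capture_attention:
            return logits, maps
        return logits


def build_model(spec: ModelSpec, seed: int = 0, dtype=np.float64) -> GGENet:
    return GGENet(spec, seed=seed, dtype=dtype)


def forward_with_attention(net: GGENet, x):
    """Logits plus the ordered triple of attention-module outputs."""
    return net.forward(x, capture_attention=True)


def count_parameters(net: Module) -> int:
    """Number of trainable scalars in the network."""
    return net.n_parameters()


def closed_form_param_count(base_width: int, n_classes: int = 6,
                            attention_r: int = 16, spatial_k: int = 7) -> int:
    """Layerwise audit of the trainable-parameter total.

    stem 27*C0 + 2*C0; module C^2 + 13C; downsample 8C^2 + 2C;
    attention C^2/r * 2 ... i.e. 2*C*(C/r) MLP + 2*k^2 conv; head 32*C0*K + K.
    """
    c0 = base_width
    total = 27 * c0 + 2 * c0
    c = c0
    for token in STAGE_PLAN:
        if token == "m":
            total += c * c + 13 * c
        elif token == "d":
            total += 8 * c * c + 2 * c
            c *= 2
        elif token == "a":
            total += 2 * c * (c // attention_r) + 2 * spatial_k * spatial_k
    total += c * n_classes + n_classes
    return total


# ----------------------------------------------------------------- checkpoints
def save_checkpoint(net: GGENet, path) -> None:
    """Weights as an .npz plus a JSON sidecar holding the ModelSpec."""
    path = Path(path)
    state = net.state_dict()
    np.savez(path, **state)
    sidecar = path.with_suffix(path.suffix + ".json") if path.suffix != ".npz" \
        else path.with_suffix(".json")
    sidecar.write_text(json.dumps(net.spec.to_dict(), indent=2))


def load_checkpoint(path, dtype=np.float64) -> GGENet:
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_suffix(path.suffix + ".npz")
    sidecar = path.with_suffix(".json")
    spec = ModelSpec.from_dict(json.loads(sidecar.read_text()))
    net = GGENet(spec, dtype=dtype)
    with np.load(path) as data:
        net.load_state_dict({k: data[k] for k in data.files})
    return net
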