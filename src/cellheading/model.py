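"""The 14-layer direction-prediction CNN.

Eight same-padded 5×5/3×3 convolutions interleaved with four 2×2 max
pools, then a 1000-unit fully connected layer (with dropout during
training) and a 4-way softmax output — one unit per moving-direction
quadrant.  With same padding the spatial side halves at each pool
(128 → 64 → 32 → 16 → 8), so the first fully connected layer sees
8·8·72 = 4608 features at the default input size.

All weights are He-normal initialized, biases zero.  Note that the
parameter count implied by this layer table is ≈5.0 M (dominated by
the first fully connected layer); see ``parameter_count`` for the
exact number at a given input size.
"""

from __future__ import annotations

import io
import json
import zipfile
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .nn import Conv2D, Dense, Dropout, Flatten, Layer, MaxPool2, ReLU, softmax


@dataclass(frozen=True)
class LayerSpec:
    kind: str                  # "conv" | "pool" | "fc"
    ksize: int = 0
    channels: int = 0          # conv filters or fc units


DEFAULT_LAYERS: tuple[LayerSpec, ...] = (
    LayerSpec("conv", 5, 8),
    LayerSpec("conv", 5, 32),
    LayerSpec("pool"),
    LayerSpec("conv", 3, 40),
    LayerSpec("conv", 5, 32),
    LayerSpec("pool"),
    LayerSpec("conv", 5, 48),
    LayerSpec("conv", 5, 64),
    LayerSpec("pool"),
    LayerSpec("conv", 5, 64),
    LayerSpec("conv", 5, 72),
    LayerSpec("pool"),
    LayerSpec("fc", 0, 1000),
    LayerSpec("fc", 0, 4),
)


@dataclass(frozen=True)
class ModelSpec:
    """Architecture description: fixed layer order plus input geometry."""

    layers: tuple[LayerSpec, ...] = DEFAULT_LAYERS
    input_px: int = 128
    input_channels: int = 1
    dropout_rate: float = 0.3

    @property
    def n_classes(self) -> int:
        return self.layers[-1].channels

    def to_json(self) -> str:
        return json.dumps(
            {
                "layers": [[l.kind, l.ksize, l.channels] for l in self.layers],
                "input_px": self.input_px,
                "input_channels": self.input_channels,
                "dropout_rate": self.dropout_rate,
            }
        )

    @classmethod
    def from_json(cls, s: str) -> "ModelSpec":
        d = json.loads(s)
        return cls(
            layers=tuple(LayerSpec(k, ks, ch) for k, ks, ch in d["layers"]),
            input_px=d["input_px"],
            input_channels=d["input_channels"],
            dropout_rate=d["dropout_rate"],
        )


def default_spec(input_px: int = 128) -> ModelSpec:
    return ModelSpec(input_px=input_px)


def reduced_spec(input_px: int = 16) -> ModelSpec:
    """A two-conv miniature of the architecture for fast numerical tests."""
    layers = (
        LayerSpec("conv", 3, 4),
        LayerSpec("pool"),
        LayerSpec("conv", 3, 6),
        LayerSpec("pool"),
        LayerSpec("fc", 0, 10),
        LayerSpec("fc", 0, 4),
    )
    return ModelSpec(layers=layers, input_px=input_px)


class ShapeError(ValueError):
    """Input does not match the model's expected geometry."""


class Network:
    """A concrete stack of layers built from a :class:`ModelSpec`."""

    def __init__(self, spec: ModelSpec, layers: list[Layer]):
        self.spec = spec
        self.layers = layers

    # -- construction -----------------------------------------------------
    @classmethod
    def build(cls, spec: ModelSpec, seed: int = 0, dtype=np.float32) -> "Network":
        rng = np.random.default_rng(seed)
        layers: list[Layer] = []
        ch = spec.input_channels
        side = spec.input_px
        conv_i = fc_i = 0
        flat = False
        for ls in spec.layers:
            if ls.kind == "conv":
                conv_i += 1
                layers.append(Conv2D(ch, ls.channels, ls.ksize, name=f"conv{conv_i}"))
                layers.append(ReLU(name=f"relu_conv{conv_i}"))
                ch = ls.channels
            elif ls.kind == "pool":
                if side % 2:
                    raise ShapeError(f"cannot 2x2-pool odd side {side}")
                layers.append(MaxPool2(name=f"pool{side}"))
                side //= 2
            elif ls.kind == "fc":
                fc_i += 1
                if not flat:
                    layers.append(Flatten())
                    dim = side * side * ch
                    flat = True
                layers.append(Dense(dim, ls.channels, name=f"fc{fc_i}"))
                dim_is_last = ls is spec.layers[-1]
                if not dim_is_last:
                    layers.append(ReLU(name=f"relu_fc{fc_i}"))
                    if spec.dropout_rate > 0:
                        layers.append(Dropout(spec.dropout_rate, name="dropout"))
                dim = ls.channels
            else:
                raise ValueError(f"unknown layer kind {ls.kind!r}")
        net = cls(spec, layers)
        for layer in layers:
            layer.init(rng, dtype)
        return net

    def astype(self, dtype) -> "Network":
        for layer in self.layers:
            layer.astype(dtype)
        return self

    # -- inference / training ---------------------------------------------
    def _check(self, x: np.ndarray) -> np.ndarray:
        if x.ndim == 2:
            x = x[None, :, :, None]
        elif x.ndim == 3:
            x = x[..., None]
        s = self.spec
        if x.shape[1:] != (s.input_px, s.input_px, s.input_channels):
            raise ShapeError(
                f"expected (N, {s.input_px}, {s.input_px}, {s.input_channels}), got {x.shape}"
            )
        return x

    def logits(self, x: np.ndarray, train: bool = False,
               rng: np.random.Generator | None = None) -> np.ndarray:
        h = self._check(x)
        dt = self.layers_dtype()
        if h.dtype != dt:
            h = h.astype(dt)
        for layer in self.layers:
            h = layer.forward(h, train=train, rng=rng)
        return h

    def forward(self, x: np.ndarray) -> np.ndarray:
        """Class probability distribution(s); rows sum to 1."""
        return softmax(self.logits(x))

    def predict_label(self, x: np.ndarray) -> np.ndarray:
        """Argmax class per sample; ties break to the lowest index."""
        return np.argmax(self.logits(x), axis=-1)

    def backward(self, dlogits: np.ndarray) -> np.ndarray:
        h = dlogits
        for layer in reversed(self.layers):
            h = layer.backward(h)
        return h

    def layers_dtype(self):
        for layer in self.layers:
            for p in layer.params.values():
                return p.dtype
        return np.float32

    # -- bookkeeping -------------------------------------------------------
    def parameter_count(self) -> int:
        return sum(layer.n_params() for layer in self.layers)

    def conv_layers(self) -> list[Conv2D]:
        return [l for l in self.layers if isinstance(l, Conv2D)]

    def summary(self) -> str:
        rows = [("layer", "output shape", "params")]
        side, ch = self.spec.input_px, self.spec.input_channels
        for layer in self.layers:
            if isinstance(layer, Conv2D):
                ch = layer.out_ch
                shape = f"{side}x{side}x{ch}"
            elif isinstance(layer, MaxPool2):
                side //= 2
                shape = f"{side}x{side}x{ch}"
            elif isinstance(layer, Dense):
                ch = layer.out_dim
                shape = f"{ch}"
            elif isinstance(layer, Flatten):
                ch = side * side * ch
                shape = f"{ch}"
            else:
                shape = "-"
            rows.append((layer.name or type(layer).__name__, shape, str(layer.n_params())))
        widths = [max(len(r[i]) for r in rows) for i in range(3)]
        lines = ["  ".join(c.ljust(w) for c, w in zip(r, widths)) for r in rows]
        lines.append(f"total trainable parameters: {self.parameter_count()}")
        return "\n".join(lines)

    def state_dict(self) -> dict[str, np.ndarray]:
        out = {}
        for i, layer in enumerate(self.layers):
            for key, p in layer.params.items():
                out[f"{i}.{layer.name}.{key}"] = p
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for i, layer in enumerate(self.layers):
            for key in layer.params:
                layer.params[key] = np.array(state[f"{i}.{layer.name}.{key}"])

    def copy_weights(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.state_dict().items()}

    # -- checkpoint I/O ----------------------------------------------------
    def save(self, path: str | Path) -> None:
        buf = io.BytesIO()
        np.savez(buf, **self.state_dict())
        with zipfile.ZipFile(path, "w") as zf:
            zf.writestr("spec.json", self.spec.to_json())
            zf.writestr("weights.npz", buf.getvalue())

    @classmethod
    def load(cls, path: str | Path) -> "Network":
        with zipfile.ZipFile(path) as zf:
            spec = ModelSpec.from_json(zf.read("spec.json").decode())
            with zf.open("weights.npz") as f:
                state = dict(np.load(io.BytesIO(f.read())))
        net = cls.build(spec, seed=0)
        net.load_state_dict(state)
        return net


def build_model(spec: ModelSpec | None = None, seed: int = 0,
                dtype=np.float32) -> Network:
    """He-normal initialized network from a spec (default architecture)."""
    return Network.build(spec or default_spec(), seed=seed, dtype=dtype)
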