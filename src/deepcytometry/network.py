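"""VGG-style convolutional classifier, implemented directly in numpy.

The architecture is a stack of 3x3 / stride-1 / same-padding convolutions
with ReLU, grouped into blocks separated by 2x2 max pooling, followed by
three fully-connected layers (1024, 64, 3 at defaults) with dropout after
the first two.  Defaults give 16 convolutional layers with channel depth
growing 16 -> 32 -> 64, three pools, and a 3-way logit output
(SW-480 / OT-II / blank).

The forward pass ends in logits l_{i,c}; class probabilities are
p_{i,c} = exp(l_{i,c}) / sum_c' exp(l_{i,c'}) and training minimizes the
mean cross-entropy -1/N sum_i sum_c y_{i,c} log p_{i,c} plus an L2 penalty
(multiplier times the summed squared weights).  Every layer implements its
exact analytic backward pass; the test suite checks the full gradient
against central finite differences.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "ModelConfig",
    "Network",
    "LayerSpec",
    "build_network",
    "forward",
    "softmax",
    "cross_entropy",
    "one_hot",
    "l2_penalty",
    "l2_gradients",
    "apply_dropout",
]


@dataclass(frozen=True)
class ModelConfig:
    """Declarative description of the network.

    ``conv_blocks`` is a list of (layer count m, output channels p): each
    block is m 3x3 convolutions with p filters, followed by one 2x2 max
    pool.  ``fc_sizes`` are the fully-connected widths ending in the number
    of classes; dropout (inverted scaling, keep probability
    ``dropout_keep_prob``) follows every hidden FC layer.  The defaults are
    the optimized regularization pair found by random search
    (L2 multiplier 0.00408, keep probability 55.14%).
    """

    conv_blocks: tuple = ((4, 16), (6, 32), (6, 64))
    fc_sizes: tuple = (1024, 64, 3)
    dropout_keep_prob: float = 0.5514
    l2_multiplier: float = 0.00408
    input_shape: tuple = (20, 1366)

    def __post_init__(self) -> None:
        if not self.conv_blocks or not self.fc_sizes:
            raise ValueError("conv_blocks and fc_sizes must be non-empty")
        if any(m < 1 or p < 1 for m, p in self.conv_blocks):
            raise ValueError("invalid conv block")
        if not 0.0 < self.dropout_keep_prob <= 1.0:
            raise ValueError("dropout_keep_prob must be in (0, 1]")
        if self.l2_multiplier < 0:
            raise ValueError("l2_multiplier must be non-negative")

    @property
    def n_conv_layers(self) -> int:
        return sum(m for m, _ in self.conv_blocks)

    @property
    def n_pool_layers(self) -> int:
        return len(self.conv_blocks)

    @property
    def n_fc_layers(self) -> int:
        return len(self.fc_sizes)

    @property
    def n_classes(self) -> int:
        return self.fc_sizes[-1]

    def to_json(self) -> str:
        return json.dumps({
            "conv_blocks": [list(b) for b in self.conv_blocks],
            "fc_sizes": list(self.fc_sizes),
            "dropout_keep_prob": self.dropout_keep_prob,
            "l2_multiplier": self.l2_multiplier,
            "input_shape": list(self.input_shape),
        })

    @classmethod
    def from_json(cls, text: str) -> "ModelConfig":
        d = json.loads(text)
        return cls(
            conv_blocks=tuple(tuple(b) for b in d["conv_blocks"]),
            fc_sizes=tuple(d["fc_sizes"]),
            dropout_keep_prob=d["dropout_keep_prob"],
            l2_multiplier=d["l2_multiplier"],
            input_shape=tuple(d["input_shape"]),
        )


@dataclass
class LayerSpec:
    name: str
    kind: str
    output_shape: tuple
    param_shapes: dict = field(default_factory=dict)

    @property
    def n_parameters(self) -> int:
        return int(sum(np.prod(s) for s in self.param_shapes.values()))


# ---------------------------------------------------------------------------
# layers

class _Conv3x3:
    """3x3 convolution, stride 1, 'same' zero padding, NHWC layout."""

    def __init__(self, name, in_ch, out_ch, rng):
        self.name = name
        fan_in = 9 * in_ch
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in), (3, 3, in_ch, out_ch))
        self.b = np.zeros(out_ch)
        self.in_ch, self.out_ch = in_ch, out_ch

    def params(self):
        return {"W": self.W, "b": self.b}

    def forward(self, x, train, rng):
        N, H, W, C = x.shape
        xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
        win = sliding_window_view(xp, (3, 3), axis=(1, 2))  # (N,H,W,C,3,3)
        cols = win.transpose(0, 1, 2, 4, 5, 3).reshape(N * H * W, 9 * C)
        Wm = self.W.reshape(9 * self.in_ch, self.out_ch)
        out = cols @ Wm + self.b
        self._cache = (x.shape, cols)
        return out.reshape(N, H, W, self.out_ch)

    def backward(self, dout):
        (N, H, W, C), cols = self._cache
        d = dout.reshape(-1, self.out_ch)
        self.dW = (cols.T @ d).reshape(3, 3, self.in_ch, self.out_ch)
        self.db = d.sum(axis=0)
        dcols = (d @ self.W.reshape(9 * self.in_ch, self.out_ch).T)
        dcols = dcols.reshape(N, H, W, 3, 3, C)
        dxp = np.zeros((N, H + 2, W + 2, C))
        for i in range(3):
            for j in range(3):
                dxp[:, i:i + H, j:j + W, :] += dcols[:, :, :, i, j, :]
        self._cache = None
        return dxp[:, 1:H + 1, 1:W + 1, :]

    def out_shape(self, shape):
        H, W, _ = shape
        return (H, W, self.out_ch)


class _ReLU:
    def __init__(self, name):
        self.name = name

    def params(self):
        return {}

    def forward(self, x, train, rng):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask

    def out_shape(self, shape):
        return shape


class _MaxPool2:
    """2x2 max pooling, stride 2; odd trailing rows/columns are cropped."""

    def __init__(self, name):
        self.name = name

    def params(self):
        return {}

    def forward(self, x, train, rng):
        N, H, W, C = x.shape
        H2, W2 = H // 2, W // 2
        xc = x[:, :H2 * 2, :W2 * 2, :]
        xr = (xc.reshape(N, H2, 2, W2, 2, C)
                .transpose(0, 1, 3, 5, 2, 4)
                .reshape(N, H2, W2, C, 4))
        arg = xr.argmax(axis=-1)
        out = np.take_along_axis(xr, arg[..., None], axis=-1)[..., 0]
        self._cache = (x.shape, arg)
        return out

    def backward(self, dout):
        (N, H, W, C), arg = self._cache
        H2, W2 = H // 2, W // 2
        dxr = np.zeros((N, H2, W2, C, 4))
        np.put_along_axis(dxr, arg[..., None], dout[..., None], axis=-1)
        dxc = (dxr.reshape(N, H2, W2, C, 2, 2)
                  .transpose(0, 1, 4, 2, 5, 3)
                  .reshape(N, H2 * 2, W2 * 2, C))
        dx = np.zeros((N, H, W, C))
        dx[:, :H2 * 2, :W2 * 2, :] = dxc
        self._cache = None
        return dx

    def out_shape(self, shape):
        H, W, C = shape
        return (H // 2, W // 2, C)


class _Flatten:
    def __init__(self, name):
        self.name = name

    def params(self):
        return {}

    def forward(self, x, train, rng):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)

    def out_shape(self, shape):
        return (int(np.prod(shape)),)


class _Dense:
    def __init__(self, name, n_in, n_out, rng):
        self.name = name
        self.W = rng.normal(0.0, np.sqrt(2.0 / n_in), (n_in, n_out))
        self.b = np.zeros(n_out)

    def params(self):
        return {"W": self.W, "b": self.b}

    def forward(self, x, train, rng):
        self._x = x
        return x @ self.W + self.b

    def backward(self, dout):
        self.dW = self._x.T @ dout
        self.db = dout.sum(axis=0)
        dx = dout @ self.W.T
        self._x = None
        return dx

    def out_shape(self, shape):
        return (self.W.shape[1],)


class _Dropout:
    def __init__(self, name, keep_prob):
        self.name = name
        self.keep_prob = keep_prob

    def params(self):
        return {}

    def forward(self, x, train, rng):
        if not train or self.keep_prob >= 1.0:
            self._mask = None
            return x
        if rng is None:
            raise ValueError("training-mode dropout needs a random generator")
        self._mask = (rng.random(x.shape) < self.keep_prob) / self.keep_prob
        return x * self._mask

    def backward(self, dout):
        if self._mask is None:
            return dout
        return dout * self._mask

    def out_shape(self, shape):
        return shape


# ---------------------------------------------------------------------------
# network

class Network:
    """An ordered layer stack with explicit forward/backward passes."""

    def __init__(self, config: ModelConfig, layers, specs):
        self.config = config
        self.layers = layers
        self.specs = specs

    # -- introspection ------------------------------------------------------

    @property
    def n_parameters(self) -> int:
        return sum(s.n_parameters for s in self.specs)

    def parameters(self) -> dict:
        out = {}
        for layer in self.layers:
            for pname, arr in layer.params().items():
                out[f"{layer.name}.{pname}"] = arr
        return out

    def set_parameters(self, values: dict) -> None:
        for layer in self.layers:
            for pname in layer.params():
                key = f"{layer.name}.{pname}"
                setattr(layer, pname, np.asarray(values[key], dtype=float))

    def gradients(self) -> dict:
        out = {}
        for layer in self.layers:
            for pname in layer.params():
                out[f"{layer.name}.{pname}"] = getattr(layer, "d" + pname)
        return out

    def weight_keys(self) -> list[str]:
        """Parameter names subject to the L2 penalty (weights, not biases)."""
        return [k for k in self.parameters() if k.endswith(".W")]

    def set_dropout_keep_prob(self, keep_prob: float) -> None:
        if not 0.0 < keep_prob <= 1.0:
            raise ValueError("keep_prob must be in (0, 1]")
        for layer in self.layers:
            if isinstance(layer, _Dropout):
                layer.keep_prob = keep_prob

    # -- computation --------------------------------------------------------

    def forward(self, x: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        """Run the batch to logits.  Eval mode (train=False) is deterministic;
        train mode draws dropout masks from ``rng``."""
        x = np.asarray(x, dtype=float)
        if x.ndim == 3:
            x = x[..., None]
        if x.shape[1:3] != tuple(self.config.input_shape):
            raise ValueError(
                f"batch spatial shape {x.shape[1:3]} does not match the "
                f"configured input shape {tuple(self.config.input_shape)}")
        for layer in self.layers:
            x = layer.forward(x, train, rng)
        return x

    def backward(self, dlogits: np.ndarray) -> None:
        d = dlogits
        for layer in reversed(self.layers):
            d = layer.backward(d)


def build_network(config: ModelConfig, seed: int = 0) -> Network:
    """Instantiate the network with He-initialized weights and zero biases,
    validating that the input survives every pooling stage."""
    rng = np.random.default_rng(seed)
    layers = []
    specs = []
    H, W = config.input_shape
    shape = (H, W, 1)

    def add(layer, kind):
        nonlocal shape
        shape = layer.out_shape(shape)
        layers.append(layer)
        specs.append(LayerSpec(layer.name, kind, shape,
                               {k: v.shape for k, v in layer.params().items()}))

    in_ch = 1
    for bi, (m, p) in enumerate(config.conv_blocks):
        for li in range(m):
            add(_Conv3x3(f"block{bi}_conv{li}", in_ch, p, rng), "conv3x3")
            add(_ReLU(f"block{bi}_relu{li}"), "relu")
            in_ch = p
        if shape[0] < 2 or shape[1] < 2:
            raise ValueError(
                "input too small: spatial dimensions collapse before "
                f"pool {bi} (shape {shape[:2]})")
        add(_MaxPool2(f"pool{bi}"), "maxpool2x2")
    add(_Flatten("flatten"), "flatten")
    n_in = int(np.prod(shape))
    for fi, width in enumerate(config.fc_sizes):
        add(_Dense(f"fc{fi}", n_in, width, rng), "dense")
        if fi < len(config.fc_sizes) - 1:
            add(_ReLU(f"fc{fi}_relu"), "relu")
            add(_Dropout(f"fc{fi}_dropout", config.dropout_keep_prob), "dropout")
        n_in = width
    return Network(config, layers, specs)


def forward(network: Network, batch: np.ndarray, mode: str = "eval",
            seed: int | None = None) -> np.ndarray:
    """Functional wrapper: run a batch to logits in 'train' or 'eval' mode."""
    if mode not in ("train", "eval"):
        raise ValueError("mode must be 'train' or 'eval'")
    rng = np.random.default_rng(seed) if mode == "train" else None
    return network.forward(batch, train=(mode == "train"), rng=rng)


# ---------------------------------------------------------------------------
# loss pieces

def softmax(logits: np.ndarray) -> np.ndarray:
    """Row-wise softmax with max subtraction (shift-invariant, no overflow)."""
    logits = np.asarray(logits, dtype=float)
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def one_hot(labels: np.ndarray, n_classes: int = 3) -> np.ndarray:
    labels = np.asarray(labels, dtype=int)
    out = np.zeros((len(labels), n_classes))
    out[np.arange(len(labels)), labels] = 1.0
    return out


def cross_entropy(probs: np.ndarray, labels_onehot: np.ndarray) -> float:
    """Mean over examples of -log(probability of the true class),
    natural log.  True-class probabilities below 1e-12 are clamped (with a
    warning) to keep the loss finite."""
    probs = np.asarray(probs, dtype=float)
    labels_onehot = np.asarray(labels_onehot, dtype=float)
    if probs.shape != labels_onehot.shape:
        raise ValueError("probs and labels must have matching shapes")
    p_true = (probs * labels_onehot).sum(axis=-1)
    if np.any(p_true < 1e-12):
        warnings.warn("true-class probability clamped at 1e-12", RuntimeWarning)
        p_true = np.clip(p_true, 1e-12, None)
    return float(-np.mean(np.log(p_true)))


def l2_penalty(network: Network, multiplier: float,
               include_biases: bool = False) -> float:
    """multiplier * sum of squared parameter values (weights only by
    default; biases can be included)."""
    if multiplier < 0:
        raise ValueError("multiplier must be non-negative")
    params = network.parameters()
    keys = params if include_biases else network.weight_keys()
    return multiplier * float(sum(np.sum(params[k] ** 2) for k in keys))


def l2_gradients(network: Network, multiplier: float,
                 include_biases: bool = False) -> dict:
    params = network.parameters()
    keys = params if include_biases else network.weight_keys()
    return {k: 2.0 * multiplier * params[k] for k in keys}


def apply_dropout(activations: np.ndarray, keep_prob: float,
                  mode: str = "train",
                  seed: int | None = None) -> np.ndarray:
    """Inverted dropout: in train mode keep each unit with probability
    ``keep_prob`` and divide the kept ones by it, so eval mode is a true
    identity."""
    if not keep_prob > 0:
        raise ValueError("keep_prob must be positive")
    if mode not in ("train", "eval"):
        raise ValueError("mode must be 'train' or 'eval'")
    if mode == "eval" or keep_prob >= 1.0:
        return np.asarray(activations)
    rng = np.random.default_rng(seed)
    mask = (rng.random(np.shape(activations)) < keep_prob) / keep_prob
    return np.asarray(activations) * mask
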