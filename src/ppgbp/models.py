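"""Architecture zoo for scalar SBP/DBP regression.

Five architectures behind one registry:

* ``alexnet1d`` — AlexNet translated to 1-D: the original kernel extents
  (11/5/3) and conv channel counts (64/192/384/256/256) along time, with
  desk-scale fully connected layers (overridable via hyperparams);
* ``resnet1d`` — ResNet-18 block layout with 1-D convolutions;
* ``spectrotemporal`` — parallel residual temporal conv stack and
  log-magnitude spectrogram branch, concatenated into a GRU head;
* ``cnn_lstm`` — conv(32 filters, kernel 5, stride 1) + ReLU, three
  bidirectional LSTM layers (64, 64, 32 units per direction), dense 128;
* ``cnn_small`` — a compact strided CNN used for desk-scale experiments;

plus a ``mean_regressor`` baseline that always predicts the training-set
mean SBP/DBP.  Every network ends in a two-neuron linear regression head
(SBP, DBP).  Networks internally predict standardized targets; the
training routine fits the target scaler and predictions are returned in
mmHg.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ppgbp import nn
from ppgbp.labels import BPLabel

__all__ = [
    "ModelSpec", "NeuralModel", "MeanRegressor", "build_model",
    "mean_regressor_fit", "ARCHITECTURES", "save_model", "load_model",
]


@dataclass
class ModelSpec:
    architecture: str
    input_length: int
    input_channels: int = 1
    hyperparams: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.architecture not in ARCHITECTURES:
            raise ValueError(
                f"unknown architecture {self.architecture!r}; "
                f"available: {sorted(ARCHITECTURES)}")
        if self.input_length <= 0:
            raise ValueError("input_length must be positive")
        if self.input_channels not in (1, 3):
            raise ValueError("input_channels must be 1 or 3")


class NeuralModel:
    """A network plus its target scaler and weight bookkeeping.

    ``head`` is the final two-neuron linear layer; everything before it is
    the "body", whose byte-exact fingerprint backs the freeze contract of
    final-layer-only transfer learning.
    """

    def __init__(self, spec: ModelSpec, body: nn.Sequential, head: nn.Dense,
                 seed: int):
        self.spec = spec
        self.body = body
        self.head = head
        self.seed = seed
        self.y_mean: np.ndarray | None = None
        self.y_std: np.ndarray | None = None

    # -- forward/backward in standardized target units ---------------------
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return self.head.forward(self.body.forward(x, train=train), train=train)

    def backward(self, grad: np.ndarray) -> None:
        self.body.backward(self.head.backward(grad))

    def parameters(self, scope: str = "all") -> list[nn.Param]:
        if scope == "all":
            return self.body.params() + self.head.params()
        if scope == "final_layer_only":
            return self.head.params()
        raise ValueError(f"unknown trainable scope {scope!r}")

    def set_target_scaler(self, y: np.ndarray) -> None:
        self.y_mean = y.mean(axis=0)
        std = y.std(axis=0)
        self.y_std = np.where(std > 0, std, 1.0)

    def standardize(self, y: np.ndarray) -> np.ndarray:
        return (y - self.y_mean) / self.y_std

    def predict(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """Predicted (SBP, DBP) in mmHg, shape (n, 2)."""
        if self.y_mean is None:
            raise RuntimeError("model has no target scaler; train it first")
        outs = [self.forward(x[i:i + batch_size])
                for i in range(0, len(x), batch_size)]
        return np.concatenate(outs) * self.y_std + self.y_mean

    # -- state -------------------------------------------------------------
    def state_dict(self) -> dict:
        state = {p.name: p.value.copy() for p in self.parameters("all")}
        for layer in _iter_layers(self.body):
            if isinstance(layer, nn.BatchNorm1d):
                state[f"{layer.gamma.name}.running_mean"] = layer.running_mean.copy()
                state[f"{layer.gamma.name}.running_var"] = layer.running_var.copy()
        if self.y_mean is not None:
            state["__y_mean__"] = self.y_mean.copy()
            state["__y_std__"] = self.y_std.copy()
        return state

    def load_state_dict(self, state: dict) -> None:
        for p in self.parameters("all"):
            p.value[...] = state[p.name]
        for layer in _iter_layers(self.body):
            if isinstance(layer, nn.BatchNorm1d):
                layer.running_mean[...] = state[f"{layer.gamma.name}.running_mean"]
                layer.running_var[...] = state[f"{layer.gamma.name}.running_var"]
        if "__y_mean__" in state:
            self.y_mean = state["__y_mean__"].copy()
            self.y_std = state["__y_std__"].copy()

    def clone(self) -> "NeuralModel":
        fresh = build_model(self.spec, seed=self.seed)
        fresh.load_state_dict(self.state_dict())
        return fresh

    def fingerprint(self, include_head: bool = False) -> str:
        params = self.parameters("all") if include_head \
            else self.body.params()
        return nn.fingerprint_params(params)


def _iter_layers(layer):
    yield layer
    for attr in ("layers", "branches"):
        for child in getattr(layer, attr, []):
            yield from _iter_layers(child)
    for attr in ("main", "shortcut"):
        child = getattr(layer, attr, None)
        if child is not None:
            yield from _iter_layers(child)


# ---------------------------------------------------------------------------
# builders
# ---------------------------------------------------------------------------

def _conv_block(c_in, c_out, kernel, stride, rng, name, padding="same"):
    return [nn.Conv1d(c_in, c_out, kernel, stride, rng, padding=padding,
                      name=name), nn.ReLU()]


def _alexnet1d(spec: ModelSpec, rng) -> tuple[nn.Sequential, int]:
    hp = {"dense_sizes": (256, 128), **spec.hyperparams}
    layers = []
    layers += _conv_block(spec.input_channels, 64, 11, 4, rng, "c1")
    layers.append(nn.MaxPool1d(3, 2))
    layers += _conv_block(64, 192, 5, 1, rng, "c2")
    layers.append(nn.MaxPool1d(3, 2))
    layers += _conv_block(192, 384, 3, 1, rng, "c3")
    layers += _conv_block(384, 256, 3, 1, rng, "c4")
    layers += _conv_block(256, 256, 3, 1, rng, "c5")
    layers.append(nn.MaxPool1d(3, 2))
    layers.append(nn.Flatten())
    feat = _probe(layers, spec)
    for i, width in enumerate(hp["dense_sizes"]):
        layers.append(nn.Dense(feat, width, rng, name=f"fc{i + 1}"))
        layers.append(nn.ReLU())
        feat = width
    return nn.Sequential(layers), feat


def _res_block(c_in, c_out, stride, rng, name):
    main = nn.Sequential([
        nn.Conv1d(c_in, c_out, 3, stride, rng, name=f"{name}.conv1"),
        nn.BatchNorm1d(c_out, name=f"{name}.bn1"),
        nn.ReLU(),
        nn.Conv1d(c_out, c_out, 3, 1, rng, name=f"{name}.conv2"),
        nn.BatchNorm1d(c_out, name=f"{name}.bn2"),
    ])
    shortcut = None
    if stride != 1 or c_in != c_out:
        shortcut = nn.Sequential([
            nn.Conv1d(c_in, c_out, 1, stride, rng, name=f"{name}.proj"),
            nn.BatchNorm1d(c_out, name=f"{name}.projbn"),
        ])
    return [nn.Residual(main, shortcut), nn.ReLU()]


def _resnet1d(spec: ModelSpec, rng) -> tuple[nn.Sequential, int]:
    hp = {"width": 1.0, **spec.hyperparams}
    w = hp["width"]
    chans = [max(8, int(c * w)) for c in (64, 128, 256, 512)]
    layers = [
        nn.Conv1d(spec.input_channels, chans[0], 7, 2, rng, name="stem"),
        nn.BatchNorm1d(chans[0], name="stembn"),
        nn.ReLU(),
        nn.MaxPool1d(3, 2),
    ]
    c_prev = chans[0]
    for stage, c in enumerate(chans):
        for block in range(2):
            stride = 2 if (stage > 0 and block == 0) else 1
            layers += _res_block(c_prev, c, stride, rng, f"s{stage}b{block}")
            c_prev = c
    layers.append(nn.GlobalAvgPool1d())
    return nn.Sequential(layers), c_prev


def _spectrotemporal(spec: ModelSpec, rng) -> tuple[nn.Sequential, int]:
    hp = {"conv_channels": 32, "gru_hidden": 32, "dense": 64,
          **spec.hyperparams}
    c = hp["conv_channels"]
    temporal = nn.Sequential(
        _conv_block(spec.input_channels, c, 7, 4, rng, "t1")
        + _res_block(c, c, 1, rng, "tres1")
        + _res_block(c, c, 2, rng, "tres2"))
    frame = max(16, min(125, spec.input_length // 4))
    n_freq = min(33, frame // 2 + 1)
    spectral = nn.Sequential([
        nn.Spectrogram(frame=frame, hop=max(8, frame // 2), n_freq=n_freq),
        nn.Conv1d(n_freq, c, 3, 1, rng, name="sp1"), nn.ReLU(),
    ])
    layers = [
        nn.Parallel([temporal, spectral]),
        nn.GRU(2 * c, hp["gru_hidden"], rng, name="gru"),
        nn.Dense(hp["gru_hidden"], hp["dense"], rng, name="fc"),
        nn.ReLU(),
    ]
    return nn.Sequential(layers), hp["dense"]


def _cnn_lstm(spec: ModelSpec, rng) -> tuple[nn.Sequential, int]:
    hp = {"conv_filters": 32, "conv_kernel": 5, "conv_stride": 1,
          "lstm_sizes": (64, 64, 32), "dense": 128, **spec.hyperparams}
    sizes = hp["lstm_sizes"]
    layers = [
        nn.Conv1d(spec.input_channels, hp["conv_filters"], hp["conv_kernel"],
                  hp["conv_stride"], rng, padding="valid", name="conv"),
        nn.ReLU(),
    ]
    c_in = hp["conv_filters"]
    for i, h in enumerate(sizes):
        last = i == len(sizes) - 1
        layers.append(nn.LSTM(c_in, h, rng, bidirectional=True,
                              return_sequences=not last, name=f"lstm{i + 1}"))
        c_in = 2 * h
    layers.append(nn.Dense(c_in, hp["dense"], rng, name="fc"))
    layers.append(nn.ReLU())
    return nn.Sequential(layers), hp["dense"]


def _cnn_small(spec: ModelSpec, rng) -> tuple[nn.Sequential, int]:
    hp = {"channels": (16, 32, 32), "dense": 64, **spec.hyperparams}
    c1, c2, c3 = hp["channels"]
    layers = []
    layers += _conv_block(spec.input_channels, c1, 7, 4, rng, "c1")
    layers += _conv_block(c1, c2, 5, 4, rng, "c2")
    layers += _conv_block(c2, c3, 3, 2, rng, "c3")
    layers.append(nn.Flatten())
    feat = _probe(layers, spec)
    layers.append(nn.Dense(feat, hp["dense"], rng, name="fc"))
    layers.append(nn.ReLU())
    return nn.Sequential(layers), hp["dense"]


def _probe(layers: list, spec: ModelSpec) -> int:
    """Feature width after ``layers`` for a single dummy input."""
    x = np.zeros((1, spec.input_length, spec.input_channels))
    for layer in layers:
        x = layer.forward(x, train=False)
    return x.shape[-1]


ARCHITECTURES = {
    "alexnet1d": _alexnet1d,
    "resnet1d": _resnet1d,
    "spectrotemporal": _spectrotemporal,
    "cnn_lstm": _cnn_lstm,
    "cnn_small": _cnn_small,
}


def build_model(spec: ModelSpec, seed: int = 0) -> NeuralModel:
    """Instantiate a seeded network with a two-neuron linear head."""
    rng = np.random.default_rng(seed)
    body, feat = ARCHITECTURES[spec.architecture](spec, rng)
    head = nn.Dense(feat, 2, rng, name="head")
    return NeuralModel(spec, body, head, seed=seed)


class MeanRegressor:
    """Baseline predicting the training-set mean SBP/DBP for every input."""

    def __init__(self, mean_sbp: float, mean_dbp: float):
        self.mean_sbp = mean_sbp
        self.mean_dbp = mean_dbp

    def predict(self, x) -> np.ndarray:
        n = len(x)
        return np.tile([self.mean_sbp, self.mean_dbp], (n, 1))


def mean_regressor_fit(train_labels) -> MeanRegressor:
    """Fit the constant baseline from BPLabel objects or an (n, 2) array."""
    if len(train_labels) == 0:
        raise ValueError("empty training set")
    if isinstance(train_labels[0], BPLabel):
        y = np.array([[lb.sbp, lb.dbp] for lb in train_labels])
    else:
        y = np.asarray(train_labels, dtype=float)
    return MeanRegressor(float(y[:, 0].mean()), float(y[:, 1].mean()))


def save_model(model: NeuralModel, path: str | Path) -> Path:
    """Serialize spec + weights to ``<path>.npz`` and ``<path>.json``."""
    path = Path(path)
    state = model.state_dict()
    np.savez(path.with_suffix(".npz"), **state)
    meta = {"architecture": model.spec.architecture,
            "input_length": model.spec.input_length,
            "input_channels": model.spec.input_channels,
            "hyperparams": model.spec.hyperparams,
            "seed": model.seed}
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))
    return path.with_suffix(".npz")


def load_model(path: str | Path) -> NeuralModel:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    hp = meta["hyperparams"]
    # JSON round-trips tuples as lists; normalize for hyperparams
    hp = {k: tuple(v) if isinstance(v, list) else v for k, v in hp.items()}
    spec = ModelSpec(architecture=meta["architecture"],
                     input_length=meta["input_length"],
                     input_channels=meta["input_channels"], hyperparams=hp)
    model = build_model(spec, seed=meta["seed"])
    with np.load(path.with_suffix(".npz")) as data:
        model.load_state_dict({k: data[k] for k in data.files})
    return model
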