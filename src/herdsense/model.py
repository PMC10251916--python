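"""The 8-layer 1D CNN behaviour classifier.

The reference architecture stacks three valid-padding, stride-1
convolutions (128, 64, 32 filters, kernel 3, ReLU), a 0.3 dropout, a
pool-2 max-pooling, a flatten, a 100-unit ReLU dense layer and a
5-unit softmax output — 91,709 trainable parameters on a (40, 15)
input.  The module offers two independent views of that stack:

* :func:`audit` computes every layer's output shape and parameter
  count analytically, from the layer hyperparameters alone;
* :class:`BehaviourCNN` instantiates the stack as real weight arrays
  and trains it with mini-batch Adam on categorical cross-entropy.

``fit()`` refuses to run if the two disagree, which catches silent
architecture drift between the declaration and the built network.

Usage follows the model/results idiom::

    model = BehaviourCNN(split)           # split: windowing.SplitDataset
    res = model.fit(TrainConfig(epochs=30, seed=7))
    print(res.summary())
    report = res.evaluate()               # held-out confusion + metrics
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import nn
from .io import CLASSES
from .windowing import SplitDataset, one_hot, updates_per_epoch

N_CLASSES = len(CLASSES)
INPUT_SHAPE = (40, 15)


class ArchitectureError(ValueError):
    """A layer stack is geometrically impossible or inconsistent."""


@dataclass(frozen=True)
class LayerSpec:
    """Declarative description of one layer."""

    kind: str  # conv1d | dropout | maxpool1d | flatten | dense
    filters: int | None = None
    kernel_size: int | None = None
    stride: int = 1
    padding: str = "valid"
    activation: str = "none"   # relu | softmax | none
    rate: float | None = None
    pool_size: int | None = None
    units: int | None = None
    name: str = ""


@dataclass(frozen=True)
class ModelSpec:
    """Ordered layer stack with a fixed input shape and class count."""

    layers: tuple[LayerSpec, ...]
    input_shape: tuple[int, int] = INPUT_SHAPE
    n_classes: int = N_CLASSES


@dataclass
class TrainConfig:
    """Training hyperparameters.

    The reference settings are categorical cross-entropy, Adam at its
    framework defaults, batch size 32 and 600 epochs; ``epochs=30`` is
    the desk-testing profile (full fidelity is a config away).
    """

    batch: int = 32
    epochs: int = 30
    seed: int = 0
    learning_rate: float = 1e-3


def reference_model() -> ModelSpec:
    """The reference 8-layer stack.

    Two internal contradictions in the reference summary table are resolved
    by arithmetic, and the resolutions are printed by ``summary()``:
    the first convolution has 128 filters (its stated output shape
    (None, 38, 128) and parameter count 5888 = (3*15+1)*128 both
    require 128, against a stray "filter = 120"), and the output layer
    uses softmax (required to emit class probabilities; the summary
    table's "RELU" contradicts the accompanying description).
    """
    mk = LayerSpec
    return ModelSpec(layers=(
        mk("conv1d", filters=128, kernel_size=3, activation="relu",
           name="conv1d_1"),
        mk("conv1d", filters=64, kernel_size=3, activation="relu",
           name="conv1d_2"),
        mk("conv1d", filters=32, kernel_size=3, activation="relu",
           name="conv1d_3"),
        mk("dropout", rate=0.3, name="dropout_1"),
        mk("maxpool1d", pool_size=2, name="max_pooling1d_1"),
        mk("flatten", name="flatten_1"),
        mk("dense", units=100, activation="relu", name="dense_1"),
        mk("dense", units=N_CLASSES, activation="softmax", name="dense_2"),
    ))


@dataclass
class LayerAudit:
    """Analytic per-layer output shapes and parameter counts."""

    names: list[str]
    kinds: list[str]
    output_shapes: list[tuple]
    param_counts: list[int]

    @property
    def total_params(self) -> int:
        return sum(self.param_counts)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "layer": self.names, "type": self.kinds,
            "output_shape": [str(s) for s in self.output_shapes],
            "params": self.param_counts})


def audit(spec: ModelSpec) -> LayerAudit:
    """Compute output shapes and parameter counts from first principles.

    Valid convolution shortens the sequence by ``kernel - 1`` and costs
    ``(kernel * c_in + 1) * filters`` parameters; non-overlapping
    pooling divides the length by the pool size (floor); a dense layer
    costs ``(n_in + 1) * units``.  Dropout, pooling and flatten are
    parameter-free.
    """
    length, channels = spec.input_shape
    flat: int | None = None
    names, kinds, shapes, counts = [], [], [], []
    for i, ls in enumerate(spec.layers):
        name = ls.name or f"layer_{i}"
        if ls.kind == "conv1d":
            if flat is not None:
                raise ArchitectureError(f"{name}: conv after flatten")
            length = (length - ls.kernel_size) // ls.stride + 1
            if length < 1:
                raise ArchitectureError(
                    f"{name}: kernel {ls.kernel_size} leaves non-positive "
                    f"output length {length}")
            counts.append((ls.kernel_size * channels + 1) * ls.filters)
            channels = ls.filters
            shapes.append((length, channels))
        elif ls.kind == "dropout":
            counts.append(0)
            shapes.append((length, channels) if flat is None else (flat,))
        elif ls.kind == "maxpool1d":
            length = length // ls.pool_size
            if length < 1:
                raise ArchitectureError(f"{name}: pooling empties the "
                                        "sequence")
            counts.append(0)
            shapes.append((length, channels))
        elif ls.kind == "flatten":
            flat = length * channels
            counts.append(0)
            shapes.append((flat,))
        elif ls.kind == "dense":
            n_in = flat if flat is not None else length * channels
            counts.append((n_in + 1) * ls.units)
            flat = ls.units
            shapes.append((flat,))
        else:
            raise ArchitectureError(f"{name}: unknown layer kind {ls.kind}")
        names.append(name)
        kinds.append(ls.kind)
    return LayerAudit(names, kinds, shapes, counts)


def build_network(spec: ModelSpec, rng: np.random.Generator,
                  dropout_rng: np.random.Generator) -> nn.Sequential:
    """Instantiate the stack as weight arrays (the trainable network)."""
    length, channels = spec.input_shape
    flat = None
    layers: list[nn.Layer] = []
    for ls in spec.layers:
        if ls.kind == "conv1d":
            layers.append(nn.Conv1D(channels, ls.filters, ls.kernel_size,
                                    rng, activation=ls.activation))
            length = length - ls.kernel_size + 1
            channels = ls.filters
        elif ls.kind == "dropout":
            layers.append(nn.Dropout(ls.rate, dropout_rng))
        elif ls.kind == "maxpool1d":
            layers.append(nn.MaxPool1D(ls.pool_size))
            length = length // ls.pool_size
        elif ls.kind == "flatten":
            layers.append(nn.Flatten())
            flat = length * channels
        elif ls.kind == "dense":
            n_in = flat if flat is not None else length * channels
            layers.append(nn.Dense(n_in, ls.units, rng,
                                   activation=ls.activation))
            flat = ls.units
        else:
            raise ArchitectureError(f"unknown layer kind {ls.kind}")
    return nn.Sequential(layers)


class BehaviourCNN:
    """The behaviour classifier as a fittable model object.

    Parameters
    ----------
    data : SplitDataset
        Normalized train/test observation units.
    spec : ModelSpec, optional
        Layer stack; defaults to the 8-layer reference stack.
    """

    def __init__(self, data: SplitDataset,
                 spec: ModelSpec | None = None) -> None:
        self.data = data
        self.spec = spec if spec is not None else reference_model()
        self.audit = audit(self.spec)
        out_shape = self.audit.output_shapes[-1]
        if out_shape != (self.spec.n_classes,):
            raise ArchitectureError(
                f"final layer emits {out_shape}, expected "
                f"({self.spec.n_classes},)")

    def fit(self, cfg: TrainConfig | None = None) -> "CNNResults":
        """Train with shuffled mini-batch Adam; returns results.

        One top-level seed fans out to weight initialisation, dropout
        and per-epoch shuffling (the data split carries its own seed).
        Raises :class:`ArchitectureError` if the built network's
        parameter count disagrees with the analytic audit.
        """
        cfg = cfg or TrainConfig()
        ss = np.random.SeedSequence(cfg.seed)
        init_rng, drop_rng, shuffle_rng = map(np.random.default_rng,
                                              ss.spawn(3))
        net = build_network(self.spec, init_rng, drop_rng)
        if net.n_params() != self.audit.total_params:
            raise ArchitectureError(
                f"built network has {net.n_params()} parameters but the "
                f"analytic audit expects {self.audit.total_params}")

        # the backend computes in float32; tensors are stored float64
        X = np.ascontiguousarray(self.data.X_train, dtype=np.float32)
        X_test = np.ascontiguousarray(self.data.X_test, dtype=np.float32)
        y = self.data.y_train
        Y = one_hot(y, self.spec.n_classes)
        opt = nn.Adam(net.parameters(), lr=cfg.learning_rate)
        curve = []
        for epoch in range(cfg.epochs):
            order = shuffle_rng.permutation(len(X))
            losses = []
            for start in range(0, len(X), cfg.batch):
                idx = order[start:start + cfg.batch]
                losses.append(net.train_step(X[idx], Y[idx]))
                opt.step(net.gradients())
            curve.append({
                "epoch": epoch + 1,
                "train_loss": float(np.mean(losses)),
                "train_acc": _accuracy(net, X, y),
                "test_acc": _accuracy(net, X_test, self.data.y_test),
            })
        curve_df = pd.DataFrame(
            curve, columns=["epoch", "train_loss", "train_acc", "test_acc"])
        return CNNResults(model=self, network=net, config=cfg,
                          learning_curve=curve_df)


def _accuracy(net: nn.Sequential, X: np.ndarray, y: np.ndarray,
              batch: int = 256) -> float:
    if len(X) == 0:
        return float("nan")
    hits = 0
    for start in range(0, len(X), batch):
        probs = net.forward(X[start:start + batch])
        hits += int((probs.argmax(axis=1) == y[start:start + batch]).sum())
    return hits / len(X)


@dataclass
class CNNResults:
    """Fitted classifier: weights, learning curve, evaluation."""

    model: BehaviourCNN
    network: nn.Sequential
    config: TrainConfig
    learning_curve: pd.DataFrame = field(repr=False)

    def predict_proba(self, X: np.ndarray, batch: int = 256) -> np.ndarray:
        """Class-probability vectors for normalized (n, 40, 15) input."""
        X = np.asarray(X, dtype=np.float32)
        expected = self.model.spec.input_shape
        if X.ndim != 3 or X.shape[1:] != expected:
            raise ValueError(f"expected (n, {expected[0]}, {expected[1]}) "
                             f"input, got {X.shape}")
        out = [self.network.forward(X[s:s + batch])
               for s in range(0, len(X), batch)]
        return np.concatenate(out) if out else np.empty(
            (0, self.model.spec.n_classes), dtype=np.float32)

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Argmax behaviour labels (strings) for normalized input."""
        classes = np.array(self.model.data.classes)
        return classes[self.predict_proba(X).argmax(axis=1)]

    def evaluate(self, on: str = "test"):
        """Confusion matrix and full metric report on a partition."""
        from .evaluation import confusion, metrics
        data = self.model.data
        X, y = ((data.X_test, data.y_test) if on == "test"
                else (data.X_train, data.y_train))
        classes = np.array(data.classes)
        pred = self.predict(X)
        cm = confusion(classes[y], pred, classes=data.classes)
        return metrics(cm)

    def summary(self) -> str:
        """Table-style text summary of architecture and training."""
        aud = self.model.audit
        lines = ["Behaviour CNN — layer audit",
                 "=" * 62,
                 f"{'Layer':<18}{'Type':<12}{'Output shape':<16}{'Params':>8}",
                 "-" * 62]
        for name, kind, shape, count in zip(
                aud.names, aud.kinds, aud.output_shapes, aud.param_counts):
            lines.append(f"{name:<18}{kind:<12}{str(shape):<16}{count:>8}")
        lines += [
            "-" * 62,
            f"Total trainable parameters: {aud.total_params:,}",
            "Note: first conv uses 128 filters and the output layer uses",
            "softmax; both follow from the layer arithmetic.",
            "",
            f"epochs={self.config.epochs}  batch={self.config.batch}  "
            f"optimizer=adam(lr={self.config.learning_rate})  "
            f"loss=categorical_crossentropy  seed={self.config.seed}",
            f"train units={self.model.data.n_train}  "
            f"test units={self.model.data.n_test}  "
            f"updates/epoch={updates_per_epoch(self.model.data.n_train, self.config.batch)}",
        ]
        if len(self.learning_curve):
            last = self.learning_curve.iloc[-1]
            lines.append(f"final train acc={last.train_acc:.4f}  "
                         f"test acc={last.test_acc:.4f}")
        return "\n".join(lines)

    def save(self, path) -> None:
        """Weights as ``.npz`` plus a JSON architecture sidecar."""
        path = Path(path)
        arrays = {f"p{i}": p for i, p in
                  enumerate(self.network.parameters())}
        np.savez(path, **arrays)
        sidecar = {
            "layers": [vars(ls) for ls in self.model.spec.layers],
            "input_shape": list(self.model.spec.input_shape),
            "n_classes": self.model.spec.n_classes,
            "total_params": self.model.audit.total_params,
            "train_config": vars(self.config),
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))

    def plot_learning_curve(self, path=None):
        """Train/test accuracy per epoch (the learning-curve figure)."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        fig, ax = plt.subplots(figsize=(6, 4))
        ax.plot(self.learning_curve.epoch, self.learning_curve.train_acc,
                label="training", color="tab:orange")
        ax.plot(self.learning_curve.epoch, self.learning_curve.test_acc,
                label="testing", color="tab:blue")
        ax.set_xlabel("epoch")
        ax.set_ylabel("accuracy")
        ax.legend()
        fig.tight_layout()
        if path is not None:
            fig.savefig(path, dpi=120)
            plt.close(fig)
        return fig
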