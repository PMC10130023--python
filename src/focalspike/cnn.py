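"""1D and 2D convolutional epoch classifiers.

Both variants consume 19 x 300 epochs (1.5 s of 19-channel EEG at 200 Hz) and
share the same skeleton: three blocks of convolution -> batch normalization ->
ReLU -> max pooling (pool sizes 3, 2, 1 with stride 2), then flatten and a
dense softmax head with 2, 3 or 4 classes.

* ``cnn1d``: each kernel spans all 19 channels at once (channels are the input
  depth of a temporal convolution; 64/128/64 filters, kernel 6) — the "19 x 6
  kernel" reading.  Flattened feature width 64 * 33 = 2112 with valid padding.
* ``cnn2d``: 1 x 6 kernels slide over each channel row independently (the
  epoch is a one-deep 19 x 300 image; 32/64/32 filters), so the channel
  dimension survives to the flatten layer: 19 * 32 * 33 = 20064.

Training uses categorical cross-entropy, RMSprop (learning rate 1e-5 by
default), batch size 64, up to 300 epochs, and restores the weights of the
epoch with the highest validation accuracy (earliest epoch on ties).
"""

from __future__ import annotations

import copy
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import nn
from .epoching import CLASS_ORDER, DatasetSplits, EpochSet
from .errors import ContractError, DivergenceError
from .montage import N_CHANNELS

INPUT_SAMPLES = 300

_DEFAULT_FILTERS = {"cnn1d": (64, 128, 64), "cnn2d": (32, 64, 32)}


@dataclass(frozen=True)
class ModelSpec:
    variant: str = "cnn1d"
    n_classes: int = 2
    conv_filters: tuple[int, int, int] | None = None
    kernel_time: int = 6
    stride: int = 1
    pool_sizes: tuple[int, int, int] = (3, 2, 1)
    pool_stride: int = 2
    padding: str = "valid"
    activation: str = "relu"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.variant not in ("cnn1d", "cnn2d"):
            raise ValueError(f"variant must be cnn1d or cnn2d, got {self.variant!r}")
        if self.n_classes not in (2, 3, 4):
            raise ValueError("n_classes must be 2, 3 or 4")
        if self.conv_filters is not None and len(self.conv_filters) != 3:
            raise ValueError("conv_filters must have length 3")
        if len(self.pool_sizes) != 3:
            raise ValueError("pool_sizes must have length 3")
        if self.kernel_time < 1:
            raise ValueError("kernel_time must be >= 1")
        if self.padding not in ("valid", "same"):
            raise ValueError("padding must be 'valid' or 'same'")
        if self.activation != "relu":
            raise ValueError("only the 'relu' nonlinearity is implemented")

    @property
    def filters(self) -> tuple[int, int, int]:
        return self.conv_filters or _DEFAULT_FILTERS[self.variant]


@dataclass(frozen=True)
class TrainSpec:
    learning_rate: float = 1e-5
    max_epochs: int = 300
    batch_size: int = 64
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


class _SplitRows(nn.Layer):
    """(B, 19, L) -> (B*19, 1, L): each channel row becomes its own image row."""

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        b, r, length = x.shape
        self._b = b
        return x.reshape(b * r, 1, length)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        br, _, length = grad.shape
        return grad.reshape(self._b, br // self._b, length)


class _MergeRows(nn.Layer):
    """(B*R, F, L) -> (B, R*F, L): re-attach the channel rows before flatten."""

    def __init__(self, n_rows: int):
        self.n_rows = n_rows

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        br, f, length = x.shape
        b = br // self.n_rows
        self._shape = (br, f, length)
        return x.reshape(b, self.n_rows * f, length)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad.reshape(self._shape)


def layer_lengths(spec: ModelSpec, n_samples: int = INPUT_SAMPLES) -> list[int]:
    """Time-axis lengths after each conv/pool pair, by the closed-form recursion."""
    lengths = []
    length = n_samples
    for pool in spec.pool_sizes:
        if spec.padding == "valid":
            length = nn.conv_output_len(length, spec.kernel_time, spec.stride)
        length = nn.conv_output_len(length, pool, spec.pool_stride)
        lengths.append(length)
    return lengths


def flatten_width(spec: ModelSpec, n_samples: int = INPUT_SAMPLES) -> int:
    """Width of the flattened feature layer (2112 for cnn1d, 20064 for cnn2d)."""
    final_len = layer_lengths(spec, n_samples)[-1]
    width = spec.filters[-1] * final_len
    if spec.variant == "cnn2d":
        width *= N_CHANNELS
    return width


class ModelHandle:
    """A built (possibly untrained) network plus its spec."""

    def __init__(self, spec: ModelSpec, net: nn.Sequential):
        self.spec = spec
        self.net = net

    def logits(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return self.net.forward(x.astype(nn.DTYPE, copy=False), train=train)

    def clone_state(self) -> dict:
        return copy.deepcopy(self.net.state_dict())


def build_model(spec: ModelSpec) -> ModelHandle:
    """Construct the network for a spec, with seeded weight initialization."""
    rng = np.random.default_rng(spec.seed)
    layers: list[nn.Layer] = []
    in_channels = N_CHANNELS
    if spec.variant == "cnn2d":
        layers.append(_SplitRows())
        in_channels = 1
    for n_filters, pool in zip(spec.filters, spec.pool_sizes):
        layers.append(
            nn.Conv1d(in_channels, n_filters, spec.kernel_time, rng, spec.padding)
        )
        layers.append(nn.BatchNorm1d(n_filters))
        layers.append(nn.ReLU())
        layers.append(nn.MaxPool1d(pool, spec.pool_stride))
        in_channels = n_filters
    if spec.variant == "cnn2d":
        layers.append(_MergeRows(N_CHANNELS))
    layers.append(nn.Flatten())
    layers.append(nn.Dense(flatten_width(spec), spec.n_classes, rng))
    return ModelHandle(spec, nn.Sequential(layers))


@dataclass
class TrainedModel:
    spec: ModelSpec
    train_spec: TrainSpec
    handle: ModelHandle
    history: pd.DataFrame
    best_epoch: int
    class_order: tuple[str, ...]


def classes_present(epochs: EpochSet) -> tuple[str, ...]:
    """Labels present in an epoch set, in the fixed report order."""
    present = set(epochs.labels.astype(str).tolist())
    return tuple(c for c in CLASS_ORDER if c in present)


def _batched_probs(handle: ModelHandle, x: np.ndarray, batch: int = 256) -> np.ndarray:
    outs = [
        nn.softmax(handle.logits(x[i:i + batch]))
        for i in range(0, len(x), batch)
    ]
    return np.concatenate(outs) if outs else np.empty((0, handle.spec.n_classes))


def train(
    handle: ModelHandle, splits: DatasetSplits, train_spec: TrainSpec
) -> TrainedModel:
    """Train with RMSprop + categorical cross-entropy; keep the best-validation
    weights.

    Per-epoch shuffling is seeded; the returned model carries the full history
    and has the weights of the highest-validation-accuracy epoch restored.
    """
    if len(splits.train) == 0 or len(splits.val) == 0:
        raise ValueError("train and validation splits must be nonempty")
    class_order = classes_present(EpochSet.concat([splits.train, splits.val]))
    if len(class_order) != handle.spec.n_classes:
        raise ContractError(
            f"model has {handle.spec.n_classes} classes but data has "
            f"{len(class_order)}: {class_order}"
        )
    x_train, y_train = splits.train.to_xy(class_order)
    x_val, y_val = splits.val.to_xy(class_order)
    if x_train.shape[1:] != (N_CHANNELS, INPUT_SAMPLES):
        raise ContractError(
            f"epochs must be {N_CHANNELS} x {INPUT_SAMPLES}, got {x_train.shape[1:]}"
        )

    opt = nn.RMSprop(handle.net.parameters(), lr=train_spec.learning_rate)
    rng = np.random.default_rng(train_spec.seed)
    n = len(x_train)
    rows = []
    best_acc, best_epoch, best_state = -1.0, 0, None
    for epoch in range(1, train_spec.max_epochs + 1):
        perm = rng.permutation(n)
        loss_sum, correct = 0.0, 0
        for start in range(0, n, train_spec.batch_size):
            idx = perm[start:start + train_spec.batch_size]
            xb, yb = x_train[idx], y_train[idx]
            probs = nn.softmax(handle.logits(xb, train=True))
            loss = nn.cross_entropy(probs, yb)
            if not np.isfinite(loss):
                raise DivergenceError(epoch)
            loss_sum += loss * len(idx)
            correct += int((probs.argmax(axis=1) == yb).sum())
            grad = probs.copy()
            grad[np.arange(len(yb)), yb] -= 1.0
            handle.net.backward((grad / len(yb)).astype(nn.DTYPE))
            opt.step()
        val_probs = _batched_probs(handle, x_val)
        val_loss = nn.cross_entropy(val_probs, y_val)
        val_acc = float((val_probs.argmax(axis=1) == y_val).mean())
        rows.append(
            {
                "epoch": epoch,
                "train_loss": loss_sum / n,
                "train_acc": correct / n,
                "val_loss": val_loss,
                "val_acc": val_acc,
            }
        )
        if val_acc > best_acc:
            best_acc, best_epoch = val_acc, epoch
            best_state = handle.clone_state()
    handle.net.load_state_dict(best_state)
    return TrainedModel(
        spec=handle.spec,
        train_spec=train_spec,
        handle=handle,
        history=pd.DataFrame(rows),
        best_epoch=best_epoch,
        class_order=class_order,
    )


def predict_proba(model: TrainedModel, epochs: EpochSet | np.ndarray) -> np.ndarray:
    """Class probabilities, one row per epoch, columns in ``model.class_order``."""
    x = epochs.data if isinstance(epochs, EpochSet) else np.asarray(epochs)
    if x.shape[1:] != (N_CHANNELS, INPUT_SAMPLES):
        raise ContractError(f"epochs must be {N_CHANNELS} x {INPUT_SAMPLES}")
    return _batched_probs(model.handle, x.astype(nn.DTYPE, copy=False))


def predict_labels(model: TrainedModel, epochs: EpochSet | np.ndarray) -> np.ndarray:
    probs = predict_proba(model, epochs)
    return np.array([model.class_order[i] for i in probs.argmax(axis=1)], dtype=object)


def extract_features(model: TrainedModel, epochs: EpochSet | np.ndarray) -> np.ndarray:
    """Flattened-layer features (n_epochs x flatten_width)."""
    x = epochs.data if isinstance(epochs, EpochSet) else np.asarray(epochs)
    if x.shape[1:] != (N_CHANNELS, INPUT_SAMPLES):
        raise ContractError(f"epochs must be {N_CHANNELS} x {INPUT_SAMPLES}")
    x = x.astype(nn.DTYPE, copy=False)
    outs = [
        model.handle.net.forward_until(x[i:i + 256], nn.Flatten)
        for i in range(0, len(x), 256)
    ]
    return np.concatenate(outs)


def save_model(model: TrainedModel, out_dir: str | Path) -> Path:
    """Persist weights (npz) plus a JSON sidecar of specs and training history."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    flat = {}
    for i, layer_state in model.handle.net.state_dict().items():
        for key, arr in layer_state.items():
            flat[f"{i}/{key}"] = arr
    np.savez(out / "weights.npz", **flat)
    sidecar = {
        "model_spec": asdict(model.spec),
        "train_spec": asdict(model.train_spec),
        "best_epoch": model.best_epoch,
        "class_order": list(model.class_order),
    }
    (out / "model.json").write_text(json.dumps(sidecar, indent=2))
    model.history.to_csv(out / "history.csv", index=False)
    return out


def load_model(model_dir: str | Path) -> TrainedModel:
    model_dir = Path(model_dir)
    sidecar = json.loads((model_dir / "model.json").read_text())
    spec_kwargs = sidecar["model_spec"]
    for key in ("conv_filters", "pool_sizes"):
        if spec_kwargs.get(key) is not None:
            spec_kwargs[key] = tuple(spec_kwargs[key])
    spec = ModelSpec(**spec_kwargs)
    handle = build_model(spec)
    with np.load(model_dir / "weights.npz") as npz:
        state: dict[int, dict] = {}
        for name in npz.files:
            i, key = name.split("/", 1)
            state.setdefault(int(i), {})[key] = npz[name]
    for i, layer in enumerate(handle.net.layers):
        if i in state:
            layer.load_state(state[i])
        elif layer.parameters():
            raise ValueError(f"checkpoint lacks state for layer {i}")
    history = pd.read_csv(model_dir / "history.csv")
    return TrainedModel(
        spec=spec,
        train_spec=TrainSpec(**sidecar["train_spec"]),
        handle=handle,
        history=history,
        best_epoch=int(sidecar["best_epoch"]),
        class_order=tuple(sidecar["class_order"]),
    )
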