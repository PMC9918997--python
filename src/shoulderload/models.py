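"""Sequence-regression models and training protocol.

Two architectures map the standardized sensor matrix (N × C) to the
standardized SJRF target (N × 3):

* ``bilstm`` — three bidirectional LSTM layers (default 128 units per
  direction), each followed by dropout (p = 0.37) and ReLU, then a linear
  output map to the three force components.  The recurrent state lets the
  model exploit temporal context in both directions.
* ``linear`` — a time-distributed feedforward network with two hidden
  layers (250 and 100 units, ReLU after each) and a linear output map; it
  sees each 25 Hz sample independently, so it can only realize a static
  (per-sample) mapping.

Training minimizes masked mean squared error on standardized targets with
Adam (learning rate 1e-3, batches of 8 whole padded sequences, gradient
clipping at global norm 1), for at most 200 epochs with early stopping once
the validation loss has not improved for 6 consecutive epochs; the
parameters from the best validation epoch are restored.  Each experiment
repeats training for several iterations that differ only in the
initialization/shuffling seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from shoulderload import nn
from shoulderload.datasets import Standardizer, SubtrialSample
from shoulderload.nn import Adam, BiLSTM, Dense, Dropout, ReLU, Sequential, masked_mse, pad_batch

__all__ = [
    "ModelConfig",
    "TrainedModel",
    "EarlyStopper",
    "build_model",
    "count_parameters",
    "train_model",
    "predict",
    "save_model",
    "load_model",
    "run_iterations",
]


@dataclass(frozen=True)
class ModelConfig:
    """Architecture and training hyperparameters."""

    architecture: str = "bilstm"  # "bilstm" | "linear"
    bilstm_layers: int = 3
    bilstm_units: int = 128  # per direction
    dropout: float = 0.37
    linear_hidden: tuple[int, int] = (250, 100)
    max_epochs: int = 200
    patience: int = 6
    learning_rate: float = 1e-3
    batch_size: int = 8
    clip_norm: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.architecture not in ("bilstm", "linear"):
            raise ValueError(f"unknown architecture {self.architecture!r}")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")
        if not (0 < self.patience < self.max_epochs):
            raise ValueError("patience must be positive and below max_epochs")
        if min(self.bilstm_layers, self.bilstm_units, *self.linear_hidden, self.batch_size) < 1:
            raise ValueError("all size parameters must be positive")


def build_model(config: ModelConfig, n_inputs: int) -> Sequential:
    """Instantiate an untrained model; identical seeds give identical
    initial parameters."""
    rng = np.random.default_rng([config.seed, 707])
    layers: list[nn.Layer] = []
    if config.architecture == "bilstm":
        width = n_inputs
        for _ in range(config.bilstm_layers):
            layers.append(BiLSTM(width, config.bilstm_units, rng))
            layers.append(Dropout(config.dropout, rng))
            layers.append(ReLU())
            width = 2 * config.bilstm_units
        layers.append(Dense(width, 3, rng))
    else:
        widths = [n_inputs, *config.linear_hidden]
        for a, b in zip(widths[:-1], widths[1:]):
            layers.append(Dense(a, b, rng))
            layers.append(ReLU())
        layers.append(Dense(widths[-1], 3, rng))
    return Sequential(layers)


def count_parameters(model: Sequential) -> int:
    return sum(p.size for p in model.params())


class EarlyStopper:
    """Patience-based early stopping on the validation loss.

    Training stops after ``patience`` consecutive epochs without improvement
    over the best validation loss seen so far; ``best_epoch`` is the
    (1-based) epoch with the lowest validation loss.
    """

    def __init__(self, patience: int):
        self.patience = patience
        self.best_loss = np.inf
        self.best_epoch = 0
        self._since_best = 0

    def update(self, epoch: int, val_loss: float) -> bool:
        """Record one epoch's validation loss; returns True to stop."""
        if val_loss < self.best_loss:
            self.best_loss = val_loss
            self.best_epoch = epoch
            self._since_best = 0
            return False
        self._since_best += 1
        return self._since_best >= self.patience


@dataclass
class TrainedModel:
    """A trained model with its config, history and best-epoch parameters."""

    config: ModelConfig
    model: Sequential
    standardizer: Standardizer
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    best_epoch: int = 0

    @property
    def n_epochs(self) -> int:
        return len(self.val_loss)


def _standardized_batches(samples: list[SubtrialSample], standardizer: Standardizer,
                          batch_size: int, rng: np.random.Generator | None):
    order = np.arange(len(samples))
    if rng is not None:
        rng.shuffle(order)
    for start in range(0, len(order), batch_size):
        chunk = [samples[i] for i in order[start : start + batch_size]]
        X, Y, lengths = pad_batch(
            [standardizer.transform_x(s.X) for s in chunk],
            [standardizer.transform_y(s.Y) for s in chunk],
        )
        yield X, Y, lengths


def _evaluate_loss(model: Sequential, samples: list[SubtrialSample],
                   standardizer: Standardizer, batch_size: int) -> float:
    model.set_train(False)
    total, count = 0.0, 0
    for X, Y, lengths in _standardized_batches(samples, standardizer, batch_size, rng=None):
        pred = model.forward(X, lengths)
        loss, _ = masked_mse(pred, Y, lengths)
        n = int(np.sum(lengths))
        total += loss * n
        count += n
    return total / count


def train_model(train_samples: list[SubtrialSample], val_samples: list[SubtrialSample],
                standardizer: Standardizer, config: ModelConfig,
                verbose: bool = False) -> TrainedModel:
    """Train one model with early stopping; returns best-epoch parameters.

    Raises ``RuntimeError`` on divergence (non-finite loss), with the epoch
    and batch in the message.
    """
    if not train_samples or not val_samples:
        raise ValueError("train and validation sets must be non-empty")
    n_inputs = train_samples[0].X.shape[1]
    model = build_model(config, n_inputs)
    rng = np.random.default_rng([config.seed, 808])
    optimizer = Adam(model.params(), lr=config.learning_rate, clip_norm=config.clip_norm)
    stopper = EarlyStopper(config.patience)
    trained = TrainedModel(config=config, model=model, standardizer=standardizer)
    best_state = model.get_state()

    for epoch in range(1, config.max_epochs + 1):
        model.set_train(True)
        epoch_loss, n_batches = 0.0, 0
        for batch_idx, (X, Y, lengths) in enumerate(
            _standardized_batches(train_samples, standardizer, config.batch_size, rng)
        ):
            pred = model.forward(X, lengths)
            loss, grad = masked_mse(pred, Y, lengths)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"training diverged: non-finite loss at epoch {epoch}, batch {batch_idx}"
                )
            model.backward(grad)
            optimizer.step(model.grads())
            epoch_loss += loss
            n_batches += 1
        trained.train_loss.append(epoch_loss / max(n_batches, 1))
        val_loss = _evaluate_loss(model, val_samples, standardizer, config.batch_size)
        trained.val_loss.append(val_loss)
        if verbose:
            print(f"epoch {epoch:3d}  train {trained.train_loss[-1]:.4f}  val {val_loss:.4f}")
        improved = val_loss < stopper.best_loss
        stop = stopper.update(epoch, val_loss)
        if improved:
            best_state = model.get_state()
        if stop:
            break
    model.set_state(best_state)
    trained.best_epoch = stopper.best_epoch
    return trained


def predict(trained: TrainedModel, sample: SubtrialSample) -> np.ndarray:
    """Predict one subtrial's SJRF series (n, 3) in newtons.

    Inputs are standardized with the train-fitted statistics, the model runs
    in evaluation mode (dropout disabled), and the output is
    inverse-transformed back to force units.
    """
    st = trained.standardizer
    if sample.X.shape[1] != st.x_mean.shape[0]:
        raise ValueError(
            f"sample has {sample.X.shape[1]} input columns, model expects {st.x_mean.shape[0]}"
        )
    trained.model.set_train(False)
    X = st.transform_x(sample.X)[None, :, :]
    lengths = np.array([sample.n_samples])
    pred_z = trained.model.forward(X, lengths)[0]
    return st.inverse_y(pred_z)


def save_model(trained: TrainedModel, out_dir) -> None:
    """Serialize a trained model (config, parameters, standardizer,
    history) to a directory; load back with :func:`load_model`."""
    import json
    from dataclasses import asdict
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {
        "format_version": 1,
        "config": asdict(trained.config),
        "train_loss": trained.train_loss,
        "val_loss": trained.val_loss,
        "best_epoch": trained.best_epoch,
        "n_inputs": int(trained.standardizer.x_mean.shape[0]),
        "columns": trained.standardizer.columns,
    }
    (out / "model.json").write_text(json.dumps(meta, indent=2))
    arrays = {f"param_{i}": p for i, p in enumerate(trained.model.params())}
    st = trained.standardizer
    arrays.update(x_mean=st.x_mean, x_std=st.x_std, y_mean=st.y_mean, y_std=st.y_std)
    np.savez(out / "model.npz", **arrays)


def load_model(in_dir) -> TrainedModel:
    """Load a model serialized by :func:`save_model`."""
    import json
    from pathlib import Path

    src = Path(in_dir)
    meta = json.loads((src / "model.json").read_text())
    cfg = meta["config"]
    cfg["linear_hidden"] = tuple(cfg["linear_hidden"])
    config = ModelConfig(**cfg)
    data = np.load(src / "model.npz")
    standardizer = Standardizer(
        data["x_mean"], data["x_std"], data["y_mean"], data["y_std"], meta["columns"]
    )
    model = build_model(config, meta["n_inputs"])
    model.set_state([data[f"param_{i}"] for i in range(len(model.params()))])
    return TrainedModel(
        config=config, model=model, standardizer=standardizer,
        train_loss=meta["train_loss"], val_loss=meta["val_loss"],
        best_epoch=meta["best_epoch"],
    )


def run_iterations(train_samples: list[SubtrialSample], val_samples: list[SubtrialSample],
                   standardizer: Standardizer, config: ModelConfig,
                   n_iter: int = 10) -> list[TrainedModel]:
    """Train ``n_iter`` models differing only in the initialization seed
    (base seed + iteration index)."""
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    return [
        train_model(train_samples, val_samples, standardizer,
                    replace(config, seed=config.seed + i))
        for i in range(n_iter)
    ]
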