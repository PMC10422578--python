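"""The 9-layer regression CNN that inverts temperature-rise curves.

Architecture (1024-sample normalized curve in, 8 parameters out):

    input(1024)
      -> dense(1024, sigmoid)          # layer 1
      -> reshape 32 x 32 x 1
      -> 6 x conv2d(32 filters, 3x3, sigmoid, same)   # layers 2-7
      -> conv2d(1 filter, 3x3, same)   # layer 8, single-channel map
      -> flatten(1024)
      -> dense(8, sigmoid)             # layer 9
      = [tau_1..tau_4, T_1..T_4] on the [0, 1] scale

The sigmoid output guarantees every predicted time constant is strictly
positive and inside the trained range - negative tau, the failure mode of
unconstrained curve-fit optimizers, cannot occur by construction.

Training minimizes the weighted loss  0.2 * mse(tau) + 0.8 * mse(T)  with
stochastic gradient descent.  The down-weighting of the tau block
compensates for the stronger influence of time constants on the curve
shape, balancing how quickly the two blocks are learned.

The module follows the Model/Results convention: :class:`ThermalCNN` is
built from datasets, ``fit()`` returns a :class:`ThermalCNNResults` carrying
the trained weights, training history and prediction methods.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .datagen import CurveDataset
from .forward import ExponentialSpectrum, TemperatureCurve
from .nn import Conv2D, Dense, Reshape, Sequential

__all__ = [
    "NetworkConfig",
    "TrainingHistory",
    "ThermalCNN",
    "ThermalCNNResults",
    "weighted_loss",
    "build_network",
    "train",
    "predict_spectrum",
]

_MAP = 32  # feature-map side; 32*32 == n_input


@dataclass(frozen=True)
class NetworkConfig:
    """Hyperparameters of the network and its training protocol.

    The loss weights must sum to one; ``n_output`` is twice the number of
    exponential components.  Optimizer settings (learning rate, momentum,
    batch size) are conventional values for sigmoid networks and are fully
    configurable.
    """

    n_input: int = 1024
    n_output: int = 8
    conv_filters: int = 32
    n_conv: int = 6
    kernel: int = 3
    activation: str = "sigmoid"
    learning_rate: float = 0.005
    momentum: float = 0.99
    lr_decay: float = 0.2
    lr_decay_at: float = 0.75
    warmup_epochs: int = 2
    readout_lr_scale: float = 1.0
    w_tau: float = 0.2
    w_amp: float = 0.8
    epochs: int = 5000
    batch_size: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(self.w_tau + self.w_amp - 1.0) > 1e-12:
            raise ValueError(f"loss weights must sum to 1, got {self.w_tau} + {self.w_amp}")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.n_output % 2:
            raise ValueError("n_output must be 2 x number of components")
        if self.n_input != _MAP * _MAP:
            raise ValueError(f"n_input must be {_MAP * _MAP} (reshaped to {_MAP}x{_MAP}x1)")
        if self.learning_rate <= 0 or not (0 <= self.momentum < 1):
            raise ValueError("need learning_rate > 0 and 0 <= momentum < 1")
        if not (0 < self.lr_decay <= 1) or not (0 < self.lr_decay_at <= 1):
            raise ValueError("need 0 < lr_decay <= 1 and 0 < lr_decay_at <= 1")


@dataclass
class TrainingHistory:
    """Per-epoch weighted-loss traces."""

    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)

    @property
    def n_epochs(self) -> int:
        return len(self.train_loss)

    def to_csv(self, path: str | Path) -> None:
        arr = np.column_stack(
            [np.arange(1, self.n_epochs + 1), self.train_loss, self.val_loss]
        )
        np.savetxt(path, arr, delimiter=",", header="epoch,train_loss,val_loss",
                   comments="", fmt=["%d", "%.8g", "%.8g"])

    def plot(self, ax=None):
        """Loss-decay plot for train and validation traces."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        epochs = np.arange(1, self.n_epochs + 1)
        ax.plot(epochs, self.train_loss, label="train")
        ax.plot(epochs, self.val_loss, label="validation")
        ax.set_xlabel("epoch")
        ax.set_ylabel("weighted loss")
        ax.set_yscale("log")
        ax.legend()
        return ax


def weighted_loss(
    predicted: np.ndarray, true: np.ndarray, w_tau: float = 0.2, w_amp: float = 0.8
) -> float:
    """Weighted regression loss  w_tau * mse(tau block) + w_amp * mse(T block).

    Rows are [tau_1..tau_m, T_1..T_m]; both MSEs average over batch and
    components.
    """
    predicted = np.atleast_2d(np.asarray(predicted, dtype=float))
    true = np.atleast_2d(np.asarray(true, dtype=float))
    if predicted.shape != true.shape or predicted.shape[1] % 2:
        raise ValueError(
            f"need matching (N, 2m) batches, got {predicted.shape} and {true.shape}"
        )
    m = predicted.shape[1] // 2
    err = predicted - true
    mse_tau = float(np.mean(err[:, :m] ** 2))
    mse_amp = float(np.mean(err[:, m:] ** 2))
    return w_tau * mse_tau + w_amp * mse_amp


def _loss_gradient(predicted: np.ndarray, true: np.ndarray, w_tau: float, w_amp: float) -> np.ndarray:
    """d(weighted loss)/d(predicted) for one batch."""
    n, width = predicted.shape
    m = width // 2
    g = (predicted - true) * (2.0 / (n * m))
    g[:, :m] *= w_tau
    g[:, m:] *= w_amp
    return g


def _build_stack(config: NetworkConfig) -> Sequential:
    rng = np.random.default_rng(config.seed)
    layers: list = [Dense(config.n_input, config.n_input, config.activation, rng),
                    Reshape((_MAP, _MAP, 1))]
    c_in = 1
    for _ in range(config.n_conv):
        layers.append(Conv2D(c_in, config.conv_filters, config.kernel, config.activation, rng))
        c_in = config.conv_filters
    layers.append(Conv2D(c_in, 1, config.kernel, "linear", rng))
    layers.append(Reshape((_MAP * _MAP,)))
    # output layer: small init (gain 1) so initial predictions sit near 0.5
    # instead of at the sigmoid rails; the variance-preserving gain is for
    # hidden layers only
    readout = Dense(_MAP * _MAP, config.n_output, "sigmoid", rng, gain=1.0)
    readout.lr_scale = config.readout_lr_scale
    layers.append(readout)
    return Sequential(layers)


class ThermalCNN:
    """Model object: the network plus the data it will be trained on.

    Parameters
    ----------
    train_set, val_set : CurveDataset
        Normalized clean corpora with tau-sorted targets.  ``val_set`` may be
        None for quick experiments (the training loss doubles as the
        monitored quantity).
    config : NetworkConfig
        Architecture and protocol hyperparameters.
    """

    def __init__(
        self,
        train_set: CurveDataset,
        val_set: CurveDataset | None = None,
        config: NetworkConfig | None = None,
    ) -> None:
        self.config = config or NetworkConfig()
        if train_set.curves.shape[1] != self.config.n_input:
            raise ValueError(
                f"curves have {train_set.curves.shape[1]} samples, expected {self.config.n_input}"
            )
        if train_set.targets.shape[1] != self.config.n_output:
            raise ValueError(
                f"targets have {train_set.targets.shape[1]} entries, expected {self.config.n_output}"
            )
        self.train_set = train_set
        self.val_set = val_set
        self.stack = _build_stack(self.config)

    def predict_raw(self, curves: np.ndarray, batch: int = 256) -> np.ndarray:
        """Forward pass on (N, 1024) inputs; no sorting applied."""
        curves = np.atleast_2d(np.asarray(curves, dtype=np.float32))
        if curves.shape[1] != self.config.n_input:
            raise ValueError(f"curve length {curves.shape[1]} != {self.config.n_input}")
        out = np.empty((curves.shape[0], self.config.n_output), dtype=np.float32)
        for lo in range(0, curves.shape[0], batch):
            out[lo : lo + batch] = self.stack.forward(curves[lo : lo + batch])
        return out.astype(float)

    def fit(
        self,
        epochs: int | None = None,
        verbose: bool = False,
        callback=None,
    ) -> "ThermalCNNResults":
        """Run SGD for ``epochs`` (default: config.epochs) and return results.

        The best-validation-loss weights are checkpointed and restored at the
        end; epochs remain a hard cap.  Raises ``FloatingPointError`` if the
        loss turns non-finite.
        """
        cfg = self.config
        n_epochs = cfg.epochs if epochs is None else epochs
        x = self.train_set.curves.astype(np.float32)
        y = self.train_set.targets.astype(np.float32)
        if self.val_set is not None:
            xv = self.val_set.curves.astype(np.float32)
            yv = self.val_set.targets.astype(np.float32)
        rng = np.random.default_rng(cfg.seed + 1)
        history = TrainingHistory()
        best = (np.inf, self.stack.get_weights())
        n = x.shape[0]
        # Polyak tail averaging: accumulate post-decay epoch weights; the
        # average quenches SGD noise and is kept if it validates better.
        tail_sum: list[np.ndarray] | None = None
        tail_count = 0
        for epoch in range(n_epochs):
            # warmup ramp guards the momentum buffer against the large
            # fresh-init gradients; step decay quenches SGD noise at the end
            lr = cfg.learning_rate
            if epoch < cfg.warmup_epochs:
                lr *= (epoch + 1) / (cfg.warmup_epochs + 1)
            elif n_epochs > 1 and epoch >= int(cfg.lr_decay_at * n_epochs):
                lr *= cfg.lr_decay
            order = rng.permutation(n)
            running = 0.0
            for lo in range(0, n, cfg.batch_size):
                idx = order[lo : lo + cfg.batch_size]
                xb, yb = x[idx], y[idx]
                pred = self.stack.forward(xb)
                err = pred - yb
                m = cfg.n_output // 2
                loss = cfg.w_tau * float(np.mean(err[:, :m] ** 2)) + cfg.w_amp * float(
                    np.mean(err[:, m:] ** 2)
                )
                if not np.isfinite(loss):
                    raise FloatingPointError(
                        f"non-finite training loss at epoch {epoch + 1}"
                    )
                running += loss * len(idx)
                self.stack.backward(
                    _loss_gradient(pred, yb, cfg.w_tau, cfg.w_amp).astype(np.float32)
                )
                self.stack.sgd_step(lr, cfg.momentum)
            train_loss = running / n
            if self.val_set is not None:
                val_pred = self.predict_raw(xv)
                val_loss = weighted_loss(val_pred, yv, cfg.w_tau, cfg.w_amp)
            else:
                val_loss = train_loss
            history.train_loss.append(train_loss)
            history.val_loss.append(val_loss)
            if val_loss < best[0]:
                best = (val_loss, self.stack.get_weights())
            if n_epochs > 1 and epoch >= int(cfg.lr_decay_at * n_epochs):
                w = self.stack.get_weights()
                if tail_sum is None:
                    tail_sum = w
                else:
                    for acc, wi in zip(tail_sum, w):
                        acc += wi
                tail_count += 1
            if verbose:
                print(f"epoch {epoch + 1:5d}  train {train_loss:.6f}  val {val_loss:.6f}")
            if callback is not None and callback(epoch, train_loss, val_loss):
                break
        best_loss, best_weights = best
        if tail_count > 1 and self.val_set is not None:
            avg = [acc / tail_count for acc in tail_sum]
            self.stack.set_weights(avg)
            avg_loss = weighted_loss(self.predict_raw(xv), yv, cfg.w_tau, cfg.w_amp)
            if avg_loss < best_loss:
                best_loss, best_weights = avg_loss, avg
        self.stack.set_weights(best_weights)
        return ThermalCNNResults(model=self, history=history, best_val_loss=best_loss)


@dataclass
class ThermalCNNResults:
    """Trained network state, training history and prediction interface."""

    model: ThermalCNN
    history: TrainingHistory
    best_val_loss: float

    @property
    def config(self) -> NetworkConfig:
        return self.model.config

    def predict(self, curves: np.ndarray) -> np.ndarray:
        """Predict (N, 8) target vectors, each row re-sorted tau-ascending.

        Outputs are clipped into the open unit interval: float32 sigmoid
        saturation can touch exactly 0/1, which would violate the
        strictly-positive-tau contract.
        """
        raw = np.clip(self.model.predict_raw(curves), 1e-7, 1.0 - 1e-7)
        m = self.config.n_output // 2
        order = np.argsort(raw[:, :m], axis=1)
        tau = np.take_along_axis(raw[:, :m], order, axis=1)
        amp = np.take_along_axis(raw[:, m:], order, axis=1)
        return np.hstack([tau, amp])

    def predict_spectrum(self, curve: TemperatureCurve | np.ndarray) -> ExponentialSpectrum:
        """Invert one normalized curve into a normalized spectrum."""
        values = curve.values if isinstance(curve, TemperatureCurve) else np.asarray(curve)
        if values.ndim != 1 or values.size != self.config.n_input:
            raise ValueError(f"curve must have {self.config.n_input} samples, got {values.shape}")
        vec = self.predict(values[None, :])[0]
        return ExponentialSpectrum.from_vector(vec, normalized=True)

    def summary(self) -> str:
        cfg = self.config
        n_params = sum(p.size for layer in self.model.stack.layers for p in layer.params)
        lines = [
            "Thermal time-constant regression CNN",
            "=" * 44,
            f"architecture        dense({cfg.n_input}) -> {cfg.n_conv} x conv({cfg.conv_filters},"
            f" {cfg.kernel}x{cfg.kernel}) -> conv(1) -> dense({cfg.n_output})",
            f"activation          {cfg.activation}",
            f"trainable params    {n_params}",
            f"loss                {cfg.w_tau} * mse(tau) + {cfg.w_amp} * mse(T)",
            f"optimizer           SGD(lr={cfg.learning_rate}, momentum={cfg.momentum})",
            f"batch size          {cfg.batch_size}",
            f"epochs run          {self.history.n_epochs}",
            f"train set           {self.model.train_set.n} curves",
            f"validation set      {self.model.val_set.n if self.model.val_set else 0} curves",
            f"final train loss    {self.history.train_loss[-1]:.6f}"
            if self.history.train_loss
            else "final train loss    n/a",
            f"best val loss       {self.best_val_loss:.6f}",
        ]
        return "\n".join(lines)

    def save(self, directory: str | Path) -> None:
        """Persist weights (.npz) plus a JSON config/history sidecar."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        weights = self.model.stack.get_weights()
        np.savez_compressed(
            directory / "weights.npz", **{f"w{i}": w for i, w in enumerate(weights)}
        )
        meta = {
            "config": asdict(self.config),
            "history": {
                "train_loss": self.history.train_loss,
                "val_loss": self.history.val_loss,
            },
            "best_val_loss": self.best_val_loss,
        }
        (directory / "model.json").write_text(json.dumps(meta, indent=2) + "\n")

    @classmethod
    def load(cls, directory: str | Path) -> "ThermalCNNResults":
        """Rehydrate a saved model; prediction works without training data."""
        directory = Path(directory)
        meta = json.loads((directory / "model.json").read_text())
        config = NetworkConfig(**meta["config"])
        from .forward import make_time_grid  # placeholder dataset for the model object

        grid = make_time_grid(config.n_input)
        dummy = _placeholder_dataset(grid, config)
        model = ThermalCNN(dummy, None, config)
        with np.load(directory / "weights.npz") as z:
            weights = [z[f"w{i}"] for i in range(len(z.files))]
        model.stack.set_weights(weights)
        history = TrainingHistory(
            train_loss=meta["history"]["train_loss"], val_loss=meta["history"]["val_loss"]
        )
        return cls(model=model, history=history, best_val_loss=meta["best_val_loss"])


def _placeholder_dataset(grid, config: NetworkConfig) -> CurveDataset:
    # 1-row stand-in so a loaded model satisfies the ThermalCNN constructor.
    curves = np.zeros((1, config.n_input))
    targets = np.full((1, config.n_output), 0.5)
    return CurveDataset(curves=curves, targets=targets, grid=grid, meta={"placeholder": True})


# ---------------------------------------------------------------------------
# Functional wrappers mirroring the operation-style interface.

def build_network(config: NetworkConfig | None = None) -> ThermalCNN:
    """Construct an untrained network (weights seeded from config.seed)."""
    config = config or NetworkConfig()
    from .forward import make_time_grid

    grid = make_time_grid(config.n_input)
    return ThermalCNN(_placeholder_dataset(grid, config), None, config)


def train(
    model: ThermalCNN,
    train_set: CurveDataset,
    val_set: CurveDataset,
    epochs: int | None = None,
    verbose: bool = False,
) -> tuple[ThermalCNNResults, TrainingHistory]:
    """Train ``model`` on the given corpora; returns (results, history)."""
    model.train_set = train_set
    model.val_set = val_set
    results = model.fit(epochs=epochs, verbose=verbose)
    return results, results.history


def predict_spectrum(results: ThermalCNNResults, curve) -> ExponentialSpectrum:
    """Operation-style alias for :meth:`ThermalCNNResults.predict_spectrum`."""
    return results.predict_spectrum(curve)
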