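"""Single-task fully connected feed-forward regressor, in NumPy.

The network maps a descriptor count vector through one or more ReLU
hidden layers to a single linear output neuron predicting the activity.
Training minimises mean squared error with the Adam optimiser, one
update per mini-batch, with inverted dropout on the hidden layers
(dropout on the input layer is fixed at 0). Evaluation always runs
dropout-free; with inverted dropout the train-time scaling makes the
evaluation pass equal the expectation over dropout masks for any layer
that is read out linearly.

Everything is deterministic given the run seed: weight initialisation
and per-epoch shuffling/mask draws come from two separate named
child streams of the seed, so the same (seed, data, setting) triple
reproduces the same parameter trajectory bit for bit on one platform.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DNNSetting",
    "TrainConfig",
    "AdamState",
    "RegressionModel",
    "build_model",
    "updates_per_epoch",
    "train_one_epoch",
    "predict",
]


@dataclass(frozen=True)
class DNNSetting:
    """One hyperparameter setting of the benchmark grid.

    ``hidden_sizes`` and ``dropout_percents`` are per-hidden-layer and
    must have equal length; dropout percentages are in [0, 100). The
    input layer never has dropout. ``log_transform`` asks for log(1+x)
    on the descriptor counts before training.
    """

    name: str
    hidden_sizes: tuple[int, ...]
    dropout_percents: tuple[float, ...]
    minibatch_size: int = 100
    log_transform: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "hidden_sizes", tuple(int(h) for h in self.hidden_sizes))
        object.__setattr__(
            self, "dropout_percents", tuple(float(d) for d in self.dropout_percents)
        )
        if len(self.hidden_sizes) != len(self.dropout_percents):
            raise ValueError(
                f"{len(self.hidden_sizes)} hidden sizes but "
                f"{len(self.dropout_percents)} dropout rates"
            )
        if not self.hidden_sizes:
            raise ValueError("need at least one hidden layer")
        if any(h < 1 for h in self.hidden_sizes):
            raise ValueError("hidden sizes must be >= 1")
        if any(not (0 <= d < 100) for d in self.dropout_percents):
            raise ValueError("dropout percentages must be in [0, 100)")
        if self.minibatch_size < 1:
            raise ValueError("minibatch size must be >= 1")

    @property
    def n_hidden_layers(self) -> int:
        return len(self.hidden_sizes)


@dataclass(frozen=True)
class TrainConfig:
    """Protocol-level training knobs.

    Defaults are the benchmark protocol: 1000 epochs, best-epoch score,
    5 independent runs. Adam constants follow the optimiser's standard
    recommendation; they are exposed because the learning rate in
    particular interacts with the un-normalised count inputs.
    """

    epochs: int = 1000
    n_runs: int = 5
    base_seed: int = 0
    adam_alpha: float = 1e-3
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    adam_epsilon: float = 1e-8

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")


class AdamState:
    """Per-parameter Adam moment estimates and step counter."""

    def __init__(self, params: list[np.ndarray], config: TrainConfig):
        self.alpha = config.adam_alpha
        self.beta1 = config.adam_beta1
        self.beta2 = config.adam_beta2
        self.epsilon = config.adam_epsilon
        self.t = 0
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]

    def update(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1**self.t
        bias2 = 1.0 - b2**self.t
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= b1
            m += (1.0 - b1) * g
            v *= b2
            v += (1.0 - b2) * np.square(g)
            p -= self.alpha * (m / bias1) / (np.sqrt(v / bias2) + self.epsilon)


class RegressionModel:
    """Feed-forward ReLU network with a single linear output neuron.

    Weight matrices are He-initialised (fan-in-scaled normal, the right
    scale for ReLU), biases start at zero, and there is no unsupervised
    pre-training. The forward pass is deterministic once parameters are
    fixed; dropout only enters through :meth:`forward_train`.
    """

    def __init__(self, setting: DNNSetting, input_dim: int, seed: int):
        if input_dim < 1:
            raise ValueError("input_dim must be >= 1")
        self.setting = setting
        self.input_dim = input_dim
        self.seed = seed
        init_rng, train_rng = _seed_streams(seed)
        self.train_rng = train_rng
        sizes = [input_dim, *setting.hidden_sizes, 1]
        self.weights: list[np.ndarray] = []
        self.biases: list[np.ndarray] = []
        for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
            scale = math.sqrt(2.0 / fan_in)
            self.weights.append(
                init_rng.normal(0.0, scale, size=(fan_in, fan_out))
            )
            self.biases.append(np.zeros(fan_out))

    @property
    def parameters(self) -> list[np.ndarray]:
        return [*self.weights, *self.biases]

    def architecture(self) -> dict:
        """Layer sizes, dropout schedule and activation, for run logs."""
        return {
            "setting": self.setting.name,
            "input_dim": self.input_dim,
            "hidden_sizes": list(self.setting.hidden_sizes),
            "dropout_percents": list(self.setting.dropout_percents),
            "activation": "relu",
            "output": "linear(1)",
        }

    # -- forward / backward ------------------------------------------------

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Dropout-free forward pass; one prediction per row of ``x``."""
        h = self._check_width(x)
        last = len(self.weights) - 1
        for layer, (w, b) in enumerate(zip(self.weights, self.biases)):
            h = h @ w + b
            if layer < last:
                np.maximum(h, 0.0, out=h)
        return h[:, 0]

    def forward_train(
        self, x: np.ndarray, rng: np.random.Generator
    ) -> tuple[np.ndarray, list]:
        """Forward pass with inverted dropout; returns output and cache."""
        h = self._check_width(x)
        cache = []
        last = len(self.weights) - 1
        rates = self.setting.dropout_percents
        for layer, (w, b) in enumerate(zip(self.weights, self.biases)):
            inp = h
            z = inp @ w + b
            if layer < last:
                a = np.maximum(z, 0.0)
                rate = rates[layer] / 100.0
                if rate > 0.0:
                    mask = (rng.random(a.shape) >= rate) / (1.0 - rate)
                    a = a * mask
                else:
                    mask = None
                cache.append((inp, z, mask))
                h = a
            else:
                cache.append((inp, z, None))
                h = z
        return h[:, 0], cache

    def backward(self, dout: np.ndarray, cache: list) -> list[np.ndarray]:
        """Gradients of the cached forward pass, ordered like ``parameters``."""
        grad_w = [None] * len(self.weights)
        grad_b = [None] * len(self.biases)
        delta = dout[:, None]
        last = len(self.weights) - 1
        for layer in range(last, -1, -1):
            inp, z, mask = cache[layer]
            if layer < last:
                if mask is not None:
                    delta = delta * mask
                delta = delta * (z > 0.0)
            grad_w[layer] = inp.T @ delta
            grad_b[layer] = delta.sum(axis=0)
            if layer > 0:
                delta = delta @ self.weights[layer].T
        return [*grad_w, *grad_b]

    def _check_width(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float64)
        if x.ndim != 2 or x.shape[1] != self.input_dim:
            raise ValueError(
                f"input width {x.shape[-1] if x.ndim else '?'} does not match "
                f"model input_dim {self.input_dim}"
            )
        return x

    # -- persistence --------------------------------------------------------

    def save(self, path) -> None:
        """Checkpoint parameters + architecture to a portable .npz file."""
        arrays = {f"w{i}": w for i, w in enumerate(self.weights)}
        arrays.update({f"b{i}": b for i, b in enumerate(self.biases)})
        np.savez(
            path,
            hidden_sizes=np.array(self.setting.hidden_sizes),
            dropout_percents=np.array(self.setting.dropout_percents),
            minibatch_size=np.array(self.setting.minibatch_size),
            log_transform=np.array(self.setting.log_transform),
            name=np.array(self.setting.name),
            input_dim=np.array(self.input_dim),
            seed=np.array(self.seed),
            **arrays,
        )

    @classmethod
    def load(cls, path) -> "RegressionModel":
        data = np.load(path, allow_pickle=False)
        setting = DNNSetting(
            name=str(data["name"]),
            hidden_sizes=tuple(int(h) for h in data["hidden_sizes"]),
            dropout_percents=tuple(float(d) for d in data["dropout_percents"]),
            minibatch_size=int(data["minibatch_size"]),
            log_transform=bool(data["log_transform"]),
        )
        model = cls(setting, int(data["input_dim"]), int(data["seed"]))
        model.weights = [data[f"w{i}"] for i in range(len(setting.hidden_sizes) + 1)]
        model.biases = [data[f"b{i}"] for i in range(len(setting.hidden_sizes) + 1)]
        return model


def _seed_streams(seed: int) -> tuple[np.random.Generator, np.random.Generator]:
    """Two named child streams of one run seed: (init, shuffle/dropout)."""
    init_ss, train_ss = np.random.SeedSequence(seed).spawn(2)
    return np.random.default_rng(init_ss), np.random.default_rng(train_ss)


def build_model(setting: DNNSetting, input_dim: int, seed: int) -> RegressionModel:
    """Randomly initialised network for one setting; no pre-training."""
    return RegressionModel(setting, input_dim, seed)


def updates_per_epoch(n_train: int, minibatch_size: int) -> int:
    """Parameter updates per epoch: ceil(n_train / minibatch_size).

    The number of updates is inversely proportional to the mini-batch
    size — halving the batch doubles the updates at fixed epochs. The
    partial final batch, if any, is trained on (ceiling rule).
    """
    if n_train < 1 or minibatch_size < 1:
        raise ValueError("n_train and minibatch_size must be >= 1")
    return -(-n_train // minibatch_size)


def train_one_epoch(
    model: RegressionModel,
    x: np.ndarray,
    y: np.ndarray,
    optimizer: AdamState,
    rng: np.random.Generator | None = None,
) -> None:
    """One pass over the training set: shuffle, then one Adam step per batch.

    The loss is the mini-batch MSE with dropout active. ``rng`` defaults
    to the model's dedicated training stream; pass one explicitly to
    control shuffling and dropout masks from outside.
    """
    x = model._check_width(x)
    y = np.asarray(y, dtype=np.float64).ravel()
    if y.shape[0] != x.shape[0]:
        raise ValueError(f"{x.shape[0]} rows but {y.shape[0]} activities")
    if rng is None:
        rng = model.train_rng
    order = rng.permutation(x.shape[0])
    batch = model.setting.minibatch_size
    params = model.parameters
    for start in range(0, x.shape[0], batch):
        idx = order[start : start + batch]
        xb, yb = x[idx], y[idx]
        pred, cache = model.forward_train(xb, rng)
        # d(MSE)/d(pred) for batch mean of (y - pred)^2
        dout = 2.0 * (pred - yb) / yb.shape[0]
        grads = model.backward(dout, cache)
        optimizer.update(params, grads)


def predict(model: RegressionModel, x: np.ndarray) -> np.ndarray:
    """Dropout-free predictions, one per row; deterministic."""
    return model.predict(x)
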