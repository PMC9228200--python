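"""Autoencoder data augmentation and MLP response prediction.

The designed experiment yields only 27 runs — far too few to train a neural
predictor directly.  The augmentation strategy is: (1) min-max normalize all
attributes (factors and response) to [0, 1]; (2) train an autoencoder whose
encoder compresses the joint attribute vector through a low-dimensional
embedding (default four neurons) and whose decoder reconstructs it; (3) feed
random embedding vectors, drawn uniformly per dimension from a fixed
interval (default [-1, 2.5], the useful range of the elu embedding
activation), to the trained decoder, producing an arbitrary number of new
samples that lie on the learned data manifold; (4) train a three-hidden-layer
perceptron on the augmented factors->response pairs, with dropout and l2
regularization, selecting hyperparameters by k-fold cross-validation; and
(5) validate on the original experimental rows, which never enter training.

All networks are small dense feed-forward nets implemented directly on numpy
arrays and trained by mini-batch (or full-batch) gradient descent — plain
momentum descent for the autoencoder, the adaptively scaled Adam variant for
the predictor — under a shared stepwise-exponential learning-rate decay.
Every source of randomness (initialization, embedding sampling, dropout,
batch shuffling, fold assignment) is driven by one integer seed, so a run is
reproducible bit-for-bit on one platform.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold

from .errors import DivergenceError, RangeError, ValidationError

__all__ = [
    "NormalizationSpec",
    "rescale",
    "AutoencoderConfig",
    "AugmentationConfig",
    "PredictorConfig",
    "AugmentedDataset",
    "FeedForwardNet",
    "train_autoencoder",
    "search_autoencoder",
    "augment",
    "train_predictor",
    "cross_validate_predictor",
    "validate_on_original",
    "evaluate",
]


# ---------------------------------------------------------------------------
# normalization


@dataclass(frozen=True)
class NormalizationSpec:
    """Per-attribute min-max ranges mapped onto [0, 1].

    ``ranges`` maps attribute name -> (range_min, range_max) in original
    units (g/L for factors, mm for responses).
    """

    ranges: dict[str, tuple[float, float]]

    def __post_init__(self) -> None:
        for name, (lo, hi) in self.ranges.items():
            if not lo < hi:
                raise ValidationError(f"attribute {name!r}: range_min must be < range_max")

    @property
    def names(self) -> list[str]:
        return list(self.ranges)


def rescale(
    values: pd.DataFrame,
    spec: NormalizationSpec,
    direction: str = "to_unit",
) -> pd.DataFrame:
    """Affine min-max map between original units and the unit interval.

    ``direction="to_unit"`` maps [range_min, range_max] -> [0, 1];
    ``"to_original"`` inverts it.  Inputs outside the admissible range raise
    :class:`RangeError` naming the attribute.  Columns without a spec entry
    pass through unchanged.
    """
    if direction not in ("to_unit", "to_original"):
        raise ValidationError(f"unknown direction {direction!r}")
    out = values.copy()
    tol = 1e-9
    for name in values.columns:
        if name not in spec.ranges:
            continue
        lo, hi = spec.ranges[name]
        col = values[name].to_numpy(dtype=float)
        if direction == "to_unit":
            if np.any(col < lo - tol) or np.any(col > hi + tol):
                raise RangeError(
                    f"attribute {name!r} has values outside its normalization "
                    f"range [{lo}, {hi}]"
                )
            out[name] = (col - lo) / (hi - lo)
        else:
            if np.any(col < -tol) or np.any(col > 1 + tol):
                raise RangeError(f"attribute {name!r} has values outside [0, 1]")
            out[name] = lo + col * (hi - lo)
    return out


# ---------------------------------------------------------------------------
# dense feed-forward engine


def _elu(x):
    return np.where(x > 0, x, np.expm1(np.minimum(x, 0.0)))


def _elu_grad(x, a):
    return np.where(x > 0, 1.0, a + 1.0)


def _relu(x):
    return np.maximum(x, 0.0)


def _relu_grad(x, a):
    return (x > 0).astype(float)


def _sigmoid(x):
    return 0.5 * (1.0 + np.tanh(0.5 * x))


def _sigmoid_grad(x, a):
    return a * (1.0 - a)


def _identity(x):
    return x


def _identity_grad(x, a):
    return np.ones_like(x)


_ACTIVATIONS = {
    "elu": (_elu, _elu_grad),
    "relu": (_relu, _relu_grad),
    "sigmoid": (_sigmoid, _sigmoid_grad),
    "identity": (_identity, _identity_grad),
}


class FeedForwardNet:
    """Dense multilayer perceptron on numpy arrays.

    ``sizes`` lists layer widths input-first; ``activations`` names one
    activation per weight layer (``len(sizes) - 1`` entries).  Weights use
    seeded Glorot-uniform initialization.
    """

    def __init__(self, sizes: list[int], activations: list[str], rng: np.random.Generator):
        if len(activations) != len(sizes) - 1:
            raise ValidationError("need one activation per weight layer")
        for a in activations:
            if a not in _ACTIVATIONS:
                raise ValidationError(f"unknown activation {a!r}")
        self.sizes = list(sizes)
        self.activations = list(activations)
        self.weights: list[np.ndarray] = []
        self.biases: list[np.ndarray] = []
        for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
            limit = np.sqrt(6.0 / (fan_in + fan_out))
            self.weights.append(rng.uniform(-limit, limit, size=(fan_in, fan_out)))
            self.biases.append(np.zeros(fan_out))

    @property
    def n_layers(self) -> int:
        return len(self.weights)

    def predict(self, X: np.ndarray) -> np.ndarray:
        a = np.asarray(X, dtype=float)
        for W, b, name in zip(self.weights, self.biases, self.activations):
            f, _ = _ACTIVATIONS[name]
            a = f(a @ W + b)
        return a

    def _forward(
        self,
        X,
        dropout: float,
        rng: np.random.Generator | None,
        drop_layers: tuple[int, ...] = (0,),
    ):
        acts = [np.asarray(X, dtype=float)]
        pres, masks = [], []
        a = acts[0]
        last = self.n_layers - 1
        for li, (W, b, name) in enumerate(zip(self.weights, self.biases, self.activations)):
            z = a @ W + b
            f, _ = _ACTIVATIONS[name]
            a = f(z)
            mask = None
            if dropout > 0.0 and rng is not None and li in drop_layers and li < last:
                mask = (rng.random(a.shape) >= dropout) / (1.0 - dropout)
                a = a * mask
            pres.append(z)
            masks.append(mask)
            acts.append(a)
        return acts, pres, masks

    def _backward(self, acts, pres, masks, Y, l2: float):
        n = Y.shape[0]
        delta = 2.0 * (acts[-1] - Y) / (n * Y.shape[1])
        gW, gb = [None] * self.n_layers, [None] * self.n_layers
        for li in range(self.n_layers - 1, -1, -1):
            _, dfun = _ACTIVATIONS[self.activations[li]]
            post = acts[li + 1]
            if masks[li] is not None:
                # activation value before the dropout mask
                post = post / np.where(masks[li] == 0, 1.0, masks[li])
                delta = delta * masks[li]
            delta = delta * dfun(pres[li], post)
            gW[li] = acts[li].T @ delta + l2 * self.weights[li]
            gb[li] = delta.sum(axis=0)
            if li > 0:
                delta = delta @ self.weights[li].T
        return gW, gb

    def slice(self, start: int, stop: int) -> "FeedForwardNet":
        """View of weight layers [start, stop) sharing the same arrays."""
        sub = FeedForwardNet.__new__(FeedForwardNet)
        sub.sizes = self.sizes[start : stop + 1]
        sub.activations = self.activations[start:stop]
        sub.weights = self.weights[start:stop]
        sub.biases = self.biases[start:stop]
        return sub


def _train_net(
    net: FeedForwardNet,
    X: np.ndarray,
    Y: np.ndarray,
    *,
    learning_rate: float,
    lr_decay: float,
    decay_every: int = 1000,
    max_epochs: int,
    tol: float = 1e-6,
    patience: int = 100,
    l2: float = 0.0,
    dropout: float = 0.0,
    drop_layers: tuple[int, ...] = (0,),
    batch_size: int | None = None,
    momentum: float = 0.9,
    optimizer: str = "momentum",
    rng: np.random.Generator | None = None,
) -> dict:
    """Gradient-descent training loop shared by all networks.

    ``optimizer`` selects plain momentum descent or its adaptively scaled
    Adam variant; both use the same stepwise-exponential schedule (the rate
    is multiplied by ``lr_decay`` every ``decay_every`` epochs).  Training
    stops early once the relative improvement of the epoch loss stays below
    ``tol`` for ``patience`` consecutive epochs.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n = X.shape[0]
    rng = rng or np.random.default_rng(0)
    vel_W = [np.zeros_like(W) for W in net.weights]
    vel_b = [np.zeros_like(b) for b in net.biases]
    sq_W = [np.zeros_like(W) for W in net.weights]
    sq_b = [np.zeros_like(b) for b in net.biases]
    adam = optimizer == "adam"
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    step = 0
    best = np.inf
    stall = 0
    lr = learning_rate
    epoch = 0
    loss = np.inf
    for epoch in range(1, max_epochs + 1):
        if epoch > 1 and epoch % decay_every == 1:
            lr *= lr_decay
        if batch_size is None or batch_size >= n:
            batches = [np.arange(n)]
        else:
            order = rng.permutation(n)
            batches = [order[i : i + batch_size] for i in range(0, n, batch_size)]
        for idx in batches:
            acts, pres, masks = net._forward(
                X[idx], dropout, rng if dropout > 0 else None, drop_layers
            )
            # l2 penalty is normalized per training-set sample (penalty
            # l2*||W||^2 / 2n_train), matching the per-sample scale of the
            # data loss and making the coefficient batch-size invariant
            gW, gb = net._backward(acts, pres, masks, Y[idx], l2 / n)
            step += 1
            for li in range(net.n_layers):
                if adam:
                    vel_W[li] = beta1 * vel_W[li] + (1 - beta1) * gW[li]
                    vel_b[li] = beta1 * vel_b[li] + (1 - beta1) * gb[li]
                    sq_W[li] = beta2 * sq_W[li] + (1 - beta2) * gW[li] ** 2
                    sq_b[li] = beta2 * sq_b[li] + (1 - beta2) * gb[li] ** 2
                    c1, c2 = 1 - beta1**step, 1 - beta2**step
                    net.weights[li] -= lr * (vel_W[li] / c1) / (np.sqrt(sq_W[li] / c2) + eps)
                    net.biases[li] -= lr * (vel_b[li] / c1) / (np.sqrt(sq_b[li] / c2) + eps)
                else:
                    vel_W[li] = momentum * vel_W[li] - lr * gW[li]
                    vel_b[li] = momentum * vel_b[li] - lr * gb[li]
                    net.weights[li] += vel_W[li]
                    net.biases[li] += vel_b[li]
        resid = net.predict(X) - Y
        with np.errstate(over="ignore"):
            loss = float(np.mean(resid**2))
        if not np.isfinite(loss):
            raise DivergenceError(
                "training loss became non-finite; try a lower learning rate"
            )
        if not np.isfinite(best) or best - loss > tol * max(best, 1e-12):
            best = loss
            stall = 0
        else:
            stall += 1
            if stall >= patience:
                break
    return {"epochs": epoch, "final_mse": loss, "final_lr": lr}


def evaluate(net_or_fn, X: np.ndarray, Y: np.ndarray) -> tuple[float, float]:
    """(MSE, R^2) of predictions against labels.

    R^2 is computed against the evaluation set's own mean.  A constant
    target makes R^2 undefined (NaN).
    """
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    pred = net_or_fn.predict(X) if hasattr(net_or_fn, "predict") else net_or_fn(X)
    pred = np.asarray(pred, dtype=float).reshape(Y.shape)
    sse = float(np.sum((pred - Y) ** 2))
    sst = float(np.sum((Y - Y.mean(axis=0)) ** 2))
    mse = sse / Y.size
    r2 = 1.0 - sse / sst if sst > 0 else float("nan")
    return mse, r2


# ---------------------------------------------------------------------------
# autoencoder


@dataclass(frozen=True)
class AutoencoderConfig:
    """Architecture and training schedule of the augmentation autoencoder.

    Defaults follow the selected architecture of the study: elu hidden
    activation, sigmoid output, four-neuron embedding, initial learning rate
    0.03 decayed by 0.8, at most 50,000 epochs with an early stop on
    stagnating loss.
    """

    encoder_hidden: tuple[int, ...] = (16, 16)
    embedding_dim: int = 4
    decoder_hidden: tuple[int, ...] = (16, 16)
    activation: str = "elu"
    learning_rate: float = 0.03
    lr_decay: float = 0.8
    decay_every: int = 10_000
    max_epochs: int = 50_000
    tol: float = 1e-8
    patience: int = 2_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.embedding_dim < 1:
            raise ValidationError("embedding_dim must be >= 1")
        if self.activation not in ("elu", "relu", "sigmoid"):
            raise ValidationError(f"unsupported hidden activation {self.activation!r}")


@dataclass(frozen=True)
class AugmentationConfig:
    """How many samples to decode and from which embedding interval."""

    n_samples: int = 10_000
    interval: tuple[float, float] = (-1.0, 2.5)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValidationError("n_samples must be >= 1")
        if not self.interval[0] < self.interval[1]:
            raise ValidationError("sampling interval low must be < high")


@dataclass(frozen=True)
class AugmentedDataset:
    """Decoder-generated normalized samples standing in for experimental rows."""

    data: pd.DataFrame
    decoder_id: str
    interval: tuple[float, float]
    seed: int

    def __post_init__(self) -> None:
        vals = self.data.to_numpy(dtype=float)
        if np.any(vals < 0) or np.any(vals > 1):
            raise ValidationError("augmented samples must lie in [0, 1]")


class CalibratedDecoder:
    """Decoder with an affine input calibration for embedding sampling.

    The scale of an autoencoder embedding is an arbitrary convention: any
    invertible affine change of the embedding, undone inside the decoder,
    leaves the autoencoder unchanged.  This wrapper fixes the convention so
    that the fixed sampling interval of :func:`augment` maps exactly onto
    the per-dimension span of the training-data embeddings — sampled
    vectors therefore decode onto the learned data manifold rather than far
    outside it.
    """

    def __init__(
        self,
        net: FeedForwardNet,
        z_low: np.ndarray,
        z_high: np.ndarray,
        interval: tuple[float, float] = (-1.0, 2.5),
    ):
        self.net = net
        self.z_low = np.asarray(z_low, dtype=float)
        self.z_high = np.asarray(z_high, dtype=float)
        self.interval = interval
        lo, hi = interval
        self._scale = (self.z_high - self.z_low) / (hi - lo)
        self._shift = self.z_low - lo * self._scale

    @property
    def sizes(self) -> list[int]:
        return self.net.sizes

    def predict(self, Z: np.ndarray) -> np.ndarray:
        Z = np.asarray(Z, dtype=float)
        return self.net.predict(Z * self._scale + self._shift)


def train_autoencoder(
    data: pd.DataFrame | np.ndarray,
    config: AutoencoderConfig,
) -> tuple[FeedForwardNet, CalibratedDecoder, dict]:
    """Train the encoder/decoder pair on normalized rows.

    The two networks are trained jointly end-to-end to minimize mean squared
    reconstruction error; the returned encoder and decoder share the trained
    weights.  The embedding layer uses the hidden activation, the output
    layer a sigmoid (so decoded samples always lie in [0, 1]).  The returned
    decoder carries the affine input calibration that aligns the embedding
    sampling interval with the span of the training embeddings.
    """
    X = np.asarray(data, dtype=float)
    if X.ndim != 2 or X.shape[0] < 8:
        raise ValidationError("autoencoder training needs a 2-D array with >= 8 rows")
    if np.any(X < 0) or np.any(X > 1):
        raise ValidationError("autoencoder inputs must be normalized to [0, 1]")
    d = X.shape[1]
    sizes = [d, *config.encoder_hidden, config.embedding_dim, *config.decoder_hidden, d]
    acts = [config.activation] * (len(sizes) - 2) + ["sigmoid"]
    rng = np.random.default_rng(config.seed)
    net = FeedForwardNet(sizes, acts, rng)
    report = _train_net(
        net,
        X,
        X,
        learning_rate=config.learning_rate,
        lr_decay=config.lr_decay,
        decay_every=config.decay_every,
        max_epochs=config.max_epochs,
        tol=config.tol,
        patience=config.patience,
        rng=rng,
    )
    n_enc = len(config.encoder_hidden) + 1
    encoder = net.slice(0, n_enc)
    Z = encoder.predict(X)
    decoder = CalibratedDecoder(net.slice(n_enc, net.n_layers), Z.min(axis=0), Z.max(axis=0))
    mse, r2 = evaluate(net, X, X)
    report.update({"reconstruction_mse": mse, "reconstruction_r2": r2, "config": config})
    return encoder, decoder, report


def search_autoencoder(
    data: pd.DataFrame | np.ndarray,
    search_space: list[AutoencoderConfig],
    seed: int,
) -> tuple[AutoencoderConfig, pd.DataFrame]:
    """Grid search over autoencoder configurations by reconstruction MSE.

    Each candidate is trained with a seed derived deterministically from
    ``seed`` and its grid position; the configuration with the smallest
    reconstruction MSE wins, ties going to the earlier grid entry.
    """
    if not search_space:
        raise ValidationError("empty autoencoder search grid")
    records = []
    for pos, cfg in enumerate(search_space):
        cfg = replace(cfg, seed=int(np.random.default_rng([seed, pos]).integers(2**31)))
        _, _, report = train_autoencoder(data, cfg)
        records.append((pos, cfg, report["reconstruction_mse"], report["reconstruction_r2"]))
    table = pd.DataFrame(
        [(p, m, r2) for p, _, m, r2 in records],
        columns=["grid_index", "reconstruction_mse", "reconstruction_r2"],
    )
    best = min(records, key=lambda r: (r[2], r[0]))
    return best[1], table


def augment(
    decoder: FeedForwardNet,
    config: AugmentationConfig,
    columns: list[str] | None = None,
) -> AugmentedDataset:
    """Decode uniformly sampled embedding vectors into new samples.

    Embedding vectors are i.i.d. uniform over ``config.interval`` in each of
    the decoder's input dimensions; the decoder's sigmoid output keeps every
    generated attribute inside [0, 1].
    """
    lo, hi = config.interval
    rng = np.random.default_rng(config.seed)
    Z = rng.uniform(lo, hi, size=(config.n_samples, decoder.sizes[0]))
    out = decoder.predict(Z)
    if columns is None:
        columns = [f"attr{i}" for i in range(out.shape[1])]
    return AugmentedDataset(
        data=pd.DataFrame(out, columns=columns),
        decoder_id=f"decoder-{decoder.sizes}",
        interval=config.interval,
        seed=config.seed,
    )


# ---------------------------------------------------------------------------
# predictor


@dataclass(frozen=True)
class PredictorConfig:
    """Three-hidden-layer MLP hyperparameters.

    ``hidden_width`` is the neuron count of each of the three hidden layers.
    Regularization is a dropout layer (probability 0.05, applied after the
    hidden layers listed in ``drop_layers``) plus an l2 penalty with
    coefficient 0.01 under the per-training-sample convention
    (penalty = l2 * ||W||^2 / 2n_train, the same per-sample scale as the
    mean-squared data loss).
    """

    hidden_width: int = 16
    activation: str = "elu"
    learning_rate: float = 0.003
    lr_decay: float = 0.9
    decay_every: int = 200
    dropout: float = 0.05
    drop_layers: tuple[int, ...] = (0,)
    l2: float = 0.01
    max_epochs: int = 400
    batch_size: int = 256
    optimizer: str = "adam"
    tol: float = 1e-9
    patience: int = 400
    seed: int = 0

    @property
    def hidden_layers(self) -> tuple[int, int, int]:
        # exactly three hidden layers by construction
        return (self.hidden_width,) * 3

    @property
    def total_neurons(self) -> int:
        return 3 * self.hidden_width


def train_predictor(
    X: np.ndarray | pd.DataFrame,
    y: np.ndarray | pd.Series,
    config: PredictorConfig,
) -> tuple[FeedForwardNet, dict]:
    """Train the 3-hidden-layer perceptron on normalized inputs/target.

    Hidden layers use the configured activation with dropout; the output
    layer is a single sigmoid unit, matching targets normalized to [0, 1].
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).reshape(-1, 1)
    sizes = [X.shape[1], *config.hidden_layers, 1]
    acts = [config.activation] * 3 + ["sigmoid"]
    rng = np.random.default_rng(config.seed)
    net = FeedForwardNet(sizes, acts, rng)
    report = _train_net(
        net,
        X,
        y,
        learning_rate=config.learning_rate,
        lr_decay=config.lr_decay,
        decay_every=config.decay_every,
        max_epochs=config.max_epochs,
        tol=config.tol,
        patience=config.patience,
        l2=config.l2,
        dropout=config.dropout,
        drop_layers=config.drop_layers,
        batch_size=config.batch_size,
        optimizer=config.optimizer,
        rng=rng,
    )
    mse, r2 = evaluate(net, X, y)
    report.update({"train_mse": mse, "train_r2": r2, "config": config})
    return net, report


def cross_validate_predictor(
    X: np.ndarray | pd.DataFrame,
    y: np.ndarray | pd.Series,
    search_space: list[PredictorConfig],
    folds: int = 5,
    seed: int = 0,
) -> tuple[PredictorConfig, pd.DataFrame]:
    """Select predictor hyperparameters by seeded k-fold cross-validation.

    Fold assignment is a seeded shuffle split into ``folds`` disjoint parts
    covering every row.  The configuration minimizing mean validation MSE
    wins; exact ties are broken by the smaller total neuron count, then grid
    order.
    """
    if folds < 2:
        raise ValidationError("folds must be >= 2")
    if not search_space:
        raise ValidationError("empty predictor search grid")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).reshape(-1)
    if len(X) < 2 * folds:
        raise ValidationError("each fold needs at least 2 rows")
    splitter = KFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(splitter.split(X))
    records = []
    for pos, cfg in enumerate(search_space):
        for fold, (tr, va) in enumerate(splits):
            fold_seed = int(np.random.default_rng([seed, pos, fold]).integers(2**31))
            net, _ = train_predictor(X[tr], y[tr], replace(cfg, seed=fold_seed))
            mse, r2 = evaluate(net, X[va], y[va])
            records.append((pos, fold, mse, r2))
    table = pd.DataFrame(records, columns=["grid_index", "fold", "val_mse", "val_r2"])
    mean_mse = table.groupby("grid_index")["val_mse"].mean()
    best_pos = min(
        mean_mse.index,
        key=lambda p: (mean_mse[p], search_space[p].total_neurons, p),
    )
    return search_space[best_pos], table


def validate_on_original(
    predictor: FeedForwardNet,
    X_original: np.ndarray | pd.DataFrame,
    y_original: np.ndarray | pd.Series,
) -> tuple[float, float]:
    """Score the augmented-data predictor on the held-out experimental rows.

    This is the augmentation-success check: the original rows never entered
    training, so a high R^2 here means the decoder's samples carried the real
    factor-response structure.
    """
    return evaluate(
        predictor,
        np.asarray(X_original, dtype=float),
        np.asarray(y_original, dtype=float),
    )
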