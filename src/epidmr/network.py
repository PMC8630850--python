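"""The two-block convolutional DMR network, as a scikit-learn estimator.

Architecture (default): a 5 x 1000 one-hot window passes through two
convolutional blocks. Each block holds two convolutions (the first
valid-padded, the second same-padded), each followed by batch normalization
and ReLU; the block ends with max pooling (size 2) and dropout (rate 0.4).
Block 1 has 32 filters of width 20, block 2 has 64. The classifier head
flattens, applies dense layers of 256 and 128 units (ReLU), and ends in a
2-node softmax over {non-DMR, DMR}. The loss is cross-entropy, the
optimizer Adam, and training stops early when validation loss has not
improved for ``patience`` epochs (best-validation weights are restored).

The first convolutional layer doubles as the feature extractor of the
hybrid model: its 32 post-batchnorm/ReLU activation maps, pooled to one
value per kernel, re-express each window as a 32-vector (see
:mod:`epidmr.features`).
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.model_selection import train_test_split
from sklearn.utils.validation import check_is_fitted

from ._nnet import (
    Adam,
    BatchNorm1D,
    Conv1D,
    Dense,
    Dropout,
    Flatten,
    Layer,
    MaxPool1D,
    ReLU,
    Sequential,
    softmax,
    softmax_cross_entropy,
)

logger = logging.getLogger(__name__)

N_ALPHABET = 5


@dataclass
class NetworkSpec:
    """Hyperparameters of the DMR network (defaults = the published design)."""

    n_blocks: int = 2
    block1_filters: int = 32
    kernel_size: int = 20
    convs_per_block: int = 2
    pool_size: int = 2
    dropout_rate: float = 0.4
    dense_sizes: tuple[int, ...] = (256, 128)
    output_nodes: int = 2
    learning_rate: float = 1e-3
    batch_size: int = 64
    max_epochs: int = 100
    early_stop_patience: int = 5
    val_fraction: float = 0.1
    class_weight: str | None = "balanced"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.n_blocks <= 5:
            raise ValueError("n_blocks must be in [1, 5]")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        for name in ("block1_filters", "kernel_size", "pool_size",
                     "convs_per_block", "batch_size", "max_epochs"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")

    def block_filters(self, block: int) -> int:
        """Filters in block ``block`` (0-based): doubles per block (32, 64, ...)."""
        return self.block1_filters * (2 ** block)


def _layer_plan(spec: NetworkSpec, rng: np.random.Generator) -> list[Layer]:
    layers: list[Layer] = []
    in_ch = N_ALPHABET
    for b in range(spec.n_blocks):
        f = spec.block_filters(b)
        for c in range(spec.convs_per_block):
            padding = "valid" if c == 0 else "same"
            layers.append(Conv1D(in_ch, f, spec.kernel_size, padding, rng))
            layers.append(BatchNorm1D(f))
            layers.append(ReLU())
            in_ch = f
        layers.append(MaxPool1D(spec.pool_size))
        layers.append(Dropout(spec.dropout_rate, rng))
    layers.append(Flatten())
    return layers


def _conv_stack_out(spec: NetworkSpec, length: int) -> tuple[int, int]:
    """(channels, length) after the conv blocks, or length -1 if infeasible."""
    L = length
    ch = N_ALPHABET
    for b in range(spec.n_blocks):
        ch = spec.block_filters(b)
        L = L - spec.kernel_size + 1  # valid conv; same conv preserves L
        if L < 1:
            return ch, -1
        L = L // spec.pool_size
        if L < 1:
            return ch, -1
    return ch, L


def minimum_input_length(spec: NetworkSpec) -> int:
    """Smallest window size the conv/pool chain of ``spec`` can accept."""
    lo, hi = 1, 10 ** 6
    while lo < hi:
        mid = (lo + hi) // 2
        if _conv_stack_out(spec, mid)[1] >= 1:
            hi = mid
        else:
            lo = mid + 1
    return lo


def build_network(spec: NetworkSpec, input_length: int,
                  rng: np.random.Generator | None = None) -> Sequential:
    """Instantiate the layer stack of ``spec`` for one-hot input (5, length)."""
    ch, L = _conv_stack_out(spec, input_length)
    if L < 1:
        raise ValueError(
            f"input length {input_length} too short for this architecture; "
            f"minimum is {minimum_input_length(spec)}"
        )
    rng = rng or np.random.default_rng(spec.seed)
    layers = _layer_plan(spec, rng)
    n_in = ch * L
    for size in spec.dense_sizes:
        layers.append(Dense(n_in, size, rng))
        layers.append(ReLU())
        n_in = size
    layers.append(Dense(n_in, spec.output_nodes, rng))
    return Sequential(layers)


class ConvNetClassifier(ClassifierMixin, TransformerMixin, BaseEstimator):
    """CNN classifier for one-hot DNA windows, with conv-1 feature extraction.

    Parameters mirror :class:`NetworkSpec`. ``fit`` expects ``X`` of shape
    (n_windows, 5, window_size) and binary labels ``y`` (1 = DMR). As a
    transformer, :meth:`transform` returns the pooled first-conv-layer
    features (one column per kernel), which is the representation consumed
    by the boosted classifier of the hybrid model.

    Attributes
    ----------
    history_ : dict
        Per-epoch training and validation loss.
    conv1_kernels_ : ndarray of shape (block1_filters, 5, kernel_size)
        First-layer kernel weights after training.
    n_epochs_ : int
        Number of epochs actually run (early stopping included).
    """

    def __init__(self, n_blocks=2, block1_filters=32, kernel_size=20,
                 convs_per_block=2, pool_size=2, dropout_rate=0.4,
                 dense_sizes=(256, 128), learning_rate=1e-3, batch_size=64,
                 max_epochs=100, early_stop_patience=5, val_fraction=0.1,
                 class_weight="balanced", pooling="mean", random_state=0):
        self.n_blocks = n_blocks
        self.block1_filters = block1_filters
        self.kernel_size = kernel_size
        self.convs_per_block = convs_per_block
        self.pool_size = pool_size
        self.dropout_rate = dropout_rate
        self.dense_sizes = dense_sizes
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.early_stop_patience = early_stop_patience
        self.val_fraction = val_fraction
        self.class_weight = class_weight
        self.pooling = pooling
        self.random_state = random_state

    # ------------------------------------------------------------------

    _CAL_SUBSAMPLE = 512  # windows used for per-epoch batchnorm calibration

    def _make_spec(self) -> NetworkSpec:
        return NetworkSpec(
            n_blocks=self.n_blocks,
            block1_filters=self.block1_filters,
            kernel_size=self.kernel_size,
            convs_per_block=self.convs_per_block,
            pool_size=self.pool_size,
            dropout_rate=self.dropout_rate,
            dense_sizes=tuple(self.dense_sizes),
            learning_rate=self.learning_rate,
            batch_size=self.batch_size,
            max_epochs=self.max_epochs,
            early_stop_patience=self.early_stop_patience,
            val_fraction=self.val_fraction,
            class_weight=self.class_weight,
            seed=self.random_state,
        )

    @staticmethod
    def _check_X(X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float32)
        if X.ndim != 3 or X.shape[1] != N_ALPHABET:
            raise ValueError(
                f"X must have shape (n, {N_ALPHABET}, window_size); got {X.shape}"
            )
        return X

    def fit(self, X, y):
        X = self._check_X(X)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise ValueError("training data must contain both classes")
        if len(self.classes_) > 2:
            raise ValueError("binary classification only")
        yi = (y == self.classes_[1]).astype(np.int64)

        spec = self._make_spec()
        self.spec_ = spec
        self.input_length_ = X.shape[2]
        rng = np.random.default_rng(self.random_state)
        self.net_ = build_network(spec, self.input_length_, rng)

        if not 0.0 < self.val_fraction <= 0.5:
            raise ValueError("val_fraction must be in (0, 0.5]")
        idx_tr, idx_val = train_test_split(
            np.arange(len(yi)),
            test_size=self.val_fraction,
            stratify=yi,
            random_state=int(rng.integers(2 ** 31)),
        )
        Xtr, ytr = X[idx_tr], yi[idx_tr]
        Xval, yval = X[idx_val], yi[idx_val]

        if self.class_weight == "balanced":
            counts = np.bincount(ytr, minlength=2)
            cw = len(ytr) / (2.0 * np.maximum(counts, 1))
        elif self.class_weight is None:
            cw = np.ones(2)
        else:
            raise ValueError("class_weight must be 'balanced' or None")
        wtr = cw[ytr]

        opt = Adam(self.net_.params(), lr=self.learning_rate)
        history: dict[str, list[float]] = {"loss": [], "val_loss": []}
        best_val = np.inf
        best_weights = self.net_.get_weights()
        best_epoch = -1

        n = len(ytr)
        for epoch in range(self.max_epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, self.batch_size):
                sel = order[start : start + self.batch_size]
                logits = self.net_.forward(Xtr[sel], train=True)
                loss, dlogits = softmax_cross_entropy(logits, ytr[sel], wtr[sel])
                if not np.isfinite(loss):
                    raise FloatingPointError(
                        f"non-finite training loss at epoch {epoch}"
                    )
                self.net_.backward(dlogits)
                opt.step(self.net_.grads())
                epoch_loss += loss * len(sel)
            epoch_loss /= n

            # calibrate batchnorm on (a subsample of) the training data so
            # the inference-mode validation loss is meaningful from epoch 0
            self._calibrate_batchnorm(Xtr[: self._CAL_SUBSAMPLE])
            val_logits = self._forward_batched(Xval)
            val_loss, _ = softmax_cross_entropy(val_logits, yval, cw[yval])
            if not np.isfinite(val_loss):
                raise FloatingPointError(
                    f"non-finite validation loss at epoch {epoch}"
                )
            history["loss"].append(epoch_loss)
            history["val_loss"].append(val_loss)
            logger.debug("epoch %d: loss %.4f val_loss %.4f",
                         epoch, epoch_loss, val_loss)

            if val_loss < best_val:
                best_val = val_loss
                best_weights = self.net_.get_weights()
                best_epoch = epoch
            elif epoch - best_epoch >= self.early_stop_patience:
                logger.info(
                    "early stop at epoch %d (best epoch %d)", epoch, best_epoch
                )
                break

        self.net_.set_weights(best_weights)
        self._calibrate_batchnorm(Xtr)
        self.history_ = history
        self.n_epochs_ = len(history["loss"])
        self.best_epoch_ = best_epoch
        conv1 = self.net_.layers[0]
        self.conv1_kernels_ = conv1.kernels.copy()
        self.n_features_ = self.block1_filters
        return self

    def _calibrate_batchnorm(self, X: np.ndarray, batch: int = 256) -> None:
        """Replace EMA batchnorm statistics by exact training-set moments.

        With few optimizer steps per epoch the exponential running
        estimates lag badly, which would distort both inference and the
        extracted conv-1 features; one deterministic pass over the
        training data (dropout off) fixes the population statistics.
        """
        bns = [l for l in self.net_.layers if isinstance(l, BatchNorm1D)]
        for bn in bns:
            bn.start_calibration()
        for i in range(0, len(X), batch):
            self.net_.forward(X[i : i + batch], train=False)
        for bn in bns:
            bn.finish_calibration()

    # ------------------------------------------------------------------

    def _forward_batched(self, X: np.ndarray, batch: int = 256) -> np.ndarray:
        outs = [
            self.net_.forward(X[i : i + batch], train=False)
            for i in range(0, len(X), batch)
        ]
        return np.concatenate(outs, axis=0)

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "net_")
        X = self._check_X(X)
        if X.shape[2] != self.input_length_:
            raise ValueError(
                f"window size {X.shape[2]} != fitted size {self.input_length_}"
            )
        return softmax(self._forward_batched(X).astype(np.float64))

    def predict(self, X) -> np.ndarray:
        proba = self.predict_proba(X)[:, 1]
        return self.classes_[(proba >= 0.5).astype(int)]

    def conv1_activations(self, X, batch: int = 256) -> np.ndarray:
        """First-conv-layer activation maps (post-batchnorm, post-ReLU).

        Returns an array of shape (n, block1_filters, L - kernel_size + 1);
        all entries are non-negative.
        """
        check_is_fitted(self, "net_")
        X = self._check_X(X)
        # conv -> batchnorm -> ReLU are the first three layers
        return np.concatenate(
            [
                self.net_.forward_until(X[i : i + batch], 3)
                for i in range(0, len(X), batch)
            ],
            axis=0,
        )

    def transform(self, X) -> np.ndarray:
        """Pooled first-conv-layer features, one column per kernel."""
        from .features import pool_features

        return pool_features(self.conv1_activations(X), method=self.pooling)

    # ------------------------------------------------------------------

    def save(self, path: str) -> None:
        """Save weights (.npz) and a JSON sidecar describing the spec."""
        check_is_fitted(self, "net_")
        arrays = {f"w{i}": w for i, w in enumerate(self.net_.get_weights())}
        running = {}
        for i, layer in enumerate(self.net_.layers):
            if isinstance(layer, BatchNorm1D):
                running[f"rm{i}"] = layer.running_mean
                running[f"rv{i}"] = layer.running_var
        np.savez(path, **arrays, **running)
        sidecar = dict(asdict(self.spec_), input_length=self.input_length_,
                       classes=self.classes_.tolist())
        with open(str(path) + ".json", "w") as fh:
            json.dump(sidecar, fh, indent=2)

    @classmethod
    def load(cls, path: str) -> "ConvNetClassifier":
        with open(str(path) + ".json") as fh:
            sidecar = json.load(fh)
        classes = sidecar.pop("classes")
        input_length = sidecar.pop("input_length")
        sidecar.pop("output_nodes", None)
        seed = sidecar.pop("seed")
        est = cls(random_state=seed, **{
            k: (tuple(v) if isinstance(v, list) else v) for k, v in sidecar.items()
        })
        spec = est._make_spec()
        est.spec_ = spec
        est.input_length_ = input_length
        est.classes_ = np.asarray(classes)
        est.net_ = build_network(spec, input_length)
        data = np.load(path if str(path).endswith(".npz") else str(path) + ".npz")
        n = len(est.net_.params())
        est.net_.set_weights([data[f"w{i}"] for i in range(n)])
        for i, layer in enumerate(est.net_.layers):
            if isinstance(layer, BatchNorm1D):
                layer.running_mean[...] = data[f"rm{i}"]
                layer.running_var[...] = data[f"rv{i}"]
        est.conv1_kernels_ = est.net_.layers[0].kernels.copy()
        est.n_features_ = est.block1_filters
        est.history_ = {"loss": [], "val_loss": []}
        est.n_epochs_ = 0
        return est


def train_network(dataset, val_fraction: float = 0.1, seed: int = 0,
                  **params) -> ConvNetClassifier:
    """Train the DMR network on a :class:`~epidmr.dataset.LabeledDataset`."""
    est = ConvNetClassifier(val_fraction=val_fraction, random_state=seed, **params)
    return est.fit(dataset.encode(), dataset.labels)


def predict_dl(trained: ConvNetClassifier, X) -> np.ndarray:
    """DMR probability (softmax component of the DMR class) per window."""
    return trained.predict_proba(X)[:, 1]
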