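"""Multi-trait densely connected network for genomic prediction.

A feedforward network mapping environment and genomic inputs to all L
traits at once: ``n_layers`` ReLU hidden layers of ``units`` units each,
inverted dropout after every hidden layer during training, and a single
linear head with L outputs.  Trained with mini-batch Adam on the mean
squared error of the standardized traits.

Inputs are encoded from an :class:`~mtmepred.data.MTMEDataset`:

* environment block — I one-hot columns;
* genomic block — row j of a square-root factor ``Lg`` of the GRM
  (``Lg Lg' = G``), so a *linear* network on this block reproduces
  GBLUP's covariance structure;
* optional interaction block — elementwise products of the environment
  indicators with the genomic columns (I*J columns), the network
  analogue of the genotype-by-environment term.

Hyperparameters (units, epochs, layers) are selected on a single
80/20 train/validation split of the training rows, scanning a full
factorial grid; the canonical grid is units, epochs in
{50, 60, 70, 80, 90, 100} and layers in {1, 2, 3} — 108 configurations.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

from .data import MTMEDataset, TraitScaler

__all__ = [
    "MTDLConfig",
    "HyperGrid",
    "FeatureMatrix",
    "MTDLRegressor",
    "encode_features",
    "train_mtdl",
    "predict_mtdl",
    "inner_cv_select",
]


@dataclass(frozen=True)
class MTDLConfig:
    """One hyperparameter configuration of the dense network."""

    units: int = 50
    epochs: int = 50
    n_layers: int = 1
    dropout_rate: float = 0.3
    validation_fraction: float = 0.2

    def __post_init__(self) -> None:
        if self.units < 1 or self.epochs < 1 or self.n_layers < 1:
            raise ValueError("units, epochs and n_layers must be positive")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        if not 0.0 < self.validation_fraction < 1.0:
            raise ValueError("validation_fraction must be in (0, 1)")


@dataclass(frozen=True)
class HyperGrid:
    """Full factorial grid over units x epochs x layers."""

    units_values: tuple[int, ...] = (50, 60, 70, 80, 90, 100)
    epochs_values: tuple[int, ...] = (50, 60, 70, 80, 90, 100)
    layers_values: tuple[int, ...] = (1, 2, 3)

    def __post_init__(self) -> None:
        for vals in (self.units_values, self.epochs_values, self.layers_values):
            if not vals or any(v < 1 for v in vals):
                raise ValueError("grid values must be non-empty positive integers")

    def __len__(self) -> int:
        return len(self.units_values) * len(self.epochs_values) * len(self.layers_values)

    def configs(self, dropout_rate: float = 0.3,
                validation_fraction: float = 0.2) -> list[MTDLConfig]:
        return [
            MTDLConfig(units=u, epochs=e, n_layers=nl,
                       dropout_rate=dropout_rate,
                       validation_fraction=validation_fraction)
            for u, e, nl in itertools.product(
                self.units_values, self.epochs_values, self.layers_values)
        ]


@dataclass
class FeatureMatrix:
    """Network inputs with block provenance, rows in dataset cell order."""

    values: np.ndarray                     # (n, q)
    blocks: dict[str, slice]               # name -> column slice
    cells: list[tuple[str, str]] = field(default_factory=list)

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


def encode_features(ds: MTMEDataset, include_gxe: bool = True) -> FeatureMatrix:
    """Encode a dataset's cells as network inputs.

    The genomic block uses the symmetric eigen square root of the GRM,
    ``Lg = V sqrt(W) V'`` with ``G = V W V'``, so that
    ``Lg Lg' = G`` exactly; the interaction block (when requested)
    contains every product of an environment indicator with a genomic
    column, ordered environment-major to mirror Z2.
    """
    G = ds.grm.values
    w, V = np.linalg.eigh(G)
    if w.min() < -1e-8 * max(w.max(), 1.0):
        raise ValueError("GRM is not positive semi-definite")
    Lg = (V * np.sqrt(np.clip(w, 0.0, None))) @ V.T      # (J, J), symmetric root
    J, I = ds.n_lines, ds.n_envs
    n = ds.n_cells
    env_idx = np.repeat(np.arange(I), J)
    line_idx = np.tile(np.arange(J), I)
    env_block = np.zeros((n, I))
    env_block[np.arange(n), env_idx] = 1.0
    geno_block = Lg[line_idx]
    blocks = {"environment": slice(0, I), "genomic": slice(I, I + J)}
    parts = [env_block, geno_block]
    if include_gxe:
        inter = np.zeros((n, I * J))
        for i in range(I):
            rows = env_idx == i
            inter[rows, i * J:(i + 1) * J] = geno_block[rows]
        blocks["interaction"] = slice(I + J, I + J + I * J)
        parts.append(inter)
    return FeatureMatrix(np.hstack(parts), blocks, list(ds.cells))


# ---------------------------------------------------------------------------
# The network
# ---------------------------------------------------------------------------

class _DenseNet:
    """Plain-numpy MLP: ReLU hidden layers, linear L-output head, Adam."""

    def __init__(self, sizes: list[int], rng: np.random.Generator):
        self.W: list[np.ndarray] = []
        self.b: list[np.ndarray] = []
        for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
            # He initialization, appropriate for ReLU
            self.W.append(rng.standard_normal((fan_in, fan_out)) * np.sqrt(2.0 / fan_in))
            self.b.append(np.zeros(fan_out))

    def forward(self, X: np.ndarray, dropout_rate: float = 0.0,
                rng: np.random.Generator | None = None):
        """Forward pass; returns (output, cache) for backprop."""
        a = X
        cache = []
        n_hidden = len(self.W) - 1
        for k in range(n_hidden):
            z = a @ self.W[k] + self.b[k]
            h = np.maximum(z, 0.0)
            mask = None
            if dropout_rate > 0.0:
                assert rng is not None
                mask = (rng.random(h.shape) >= dropout_rate) / (1.0 - dropout_rate)
                h = h * mask
            cache.append((a, z, mask))
            a = h
        out = a @ self.W[-1] + self.b[-1]
        cache.append((a, None, None))
        return out, cache

    def backward(self, d_out: np.ndarray, cache) -> list[tuple[np.ndarray, np.ndarray]]:
        grads: list[tuple[np.ndarray, np.ndarray]] = [None] * len(self.W)  # type: ignore
        a_last, _, _ = cache[-1]
        grads[-1] = (a_last.T @ d_out, d_out.sum(axis=0))
        delta = d_out @ self.W[-1].T
        for k in range(len(self.W) - 2, -1, -1):
            a_in, z, mask = cache[k]
            if mask is not None:
                delta = delta * mask
            delta = delta * (z > 0.0)
            grads[k] = (a_in.T @ delta, delta.sum(axis=0))
            if k > 0:
                delta = delta @ self.W[k].T
        return grads


class MTDLRegressor(RegressorMixin, BaseEstimator):
    """Multi-trait dense network regressor (numpy implementation).

    Parameters
    ----------
    units : int
        Hidden-layer width (the same for every hidden layer).
    epochs : int
        Exact number of full passes over the training data.
    n_layers : int
        Number of ReLU hidden layers.
    dropout_rate : float, default 0.3
        Inverted-dropout rate applied after each hidden layer during
        training only.
    learning_rate, batch_size :
        Adam step size and mini-batch size; ``batch_size=None`` uses
        ``min(32, n_train)``.
    standardize_y : bool, default True
        Fit a :class:`TraitScaler` on the training responses and learn on
        the standardized scale; predictions are back-transformed.
    random_state : int or None
        Seeds initialization, batch shuffling and dropout masks.

    Attributes
    ----------
    net_ : the trained network
    scaler_ : TraitScaler or None
    loss_history_ : per-epoch mean training loss (standardized scale)
    """

    def __init__(
        self,
        units: int = 50,
        epochs: int = 50,
        n_layers: int = 1,
        dropout_rate: float = 0.3,
        learning_rate: float = 1e-3,
        batch_size: int | None = None,
        standardize_y: bool = True,
        random_state: int | None = None,
    ):
        self.units = units
        self.epochs = epochs
        self.n_layers = n_layers
        self.dropout_rate = dropout_rate
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.standardize_y = standardize_y
        self.random_state = random_state

    def fit(self, X: np.ndarray, y: np.ndarray) -> "MTDLRegressor":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if y.ndim == 1:
            y = y[:, None]
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ValueError("X and y must be 2-D with matching row counts")
        if np.isnan(y).any():
            raise ValueError("training responses must not contain missing values")
        cfg = MTDLConfig(self.units, self.epochs, self.n_layers,
                         self.dropout_rate)  # validates hyperparameters
        if self.standardize_y:
            self.scaler_ = TraitScaler().fit(y)
            T = self.scaler_.transform(y)
        else:
            self.scaler_ = None
            T = y
        n, q = X.shape
        L = T.shape[1]
        rng = np.random.default_rng(self.random_state)
        sizes = [q] + [cfg.units] * cfg.n_layers + [L]
        net = _DenseNet(sizes, rng)
        bs = self.batch_size or min(32, n)
        lr, b1m, b2m, eps = self.learning_rate, 0.9, 0.999, 1e-8
        mW = [np.zeros_like(w) for w in net.W]
        vW = [np.zeros_like(w) for w in net.W]
        mb = [np.zeros_like(b) for b in net.b]
        vb = [np.zeros_like(b) for b in net.b]
        t = 0
        self.loss_history_ = []
        for _ in range(cfg.epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, bs):
                idx = order[start:start + bs]
                xb, tb = X[idx], T[idx]
                out, cache = net.forward(xb, self.dropout_rate, rng)
                resid = out - tb
                loss = float(np.mean(resid ** 2))
                if not np.isfinite(loss):
                    raise FloatingPointError(
                        f"non-finite training loss at epoch {len(self.loss_history_)}"
                    )
                epoch_loss += loss * len(idx)
                d_out = 2.0 * resid / resid.size
                grads = net.backward(d_out, cache)
                t += 1
                for k, (gW, gb) in enumerate(grads):
                    mW[k] = b1m * mW[k] + (1 - b1m) * gW
                    vW[k] = b2m * vW[k] + (1 - b2m) * gW ** 2
                    mb[k] = b1m * mb[k] + (1 - b1m) * gb
                    vb[k] = b2m * vb[k] + (1 - b2m) * gb ** 2
                    mhW = mW[k] / (1 - b1m ** t)
                    vhW = vW[k] / (1 - b2m ** t)
                    mhb = mb[k] / (1 - b1m ** t)
                    vhb = vb[k] / (1 - b2m ** t)
                    net.W[k] -= lr * mhW / (np.sqrt(vhW) + eps)
                    net.b[k] -= lr * mhb / (np.sqrt(vhb) + eps)
            self.loss_history_.append(epoch_loss / n)
        self.net_ = net
        self.n_features_in_ = q
        self.n_outputs_ = L
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Deterministic forward pass (dropout off), back-transformed."""
        if not hasattr(self, "net_"):
            raise AttributeError("fit the model before predicting")
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"expected {self.n_features_in_} features, got {X.shape[1]}"
            )
        out, _ = self.net_.forward(X, dropout_rate=0.0)
        if self.scaler_ is not None:
            out = self.scaler_.inverse_transform(out)
        return out

    def training_loss(self, X: np.ndarray, y: np.ndarray) -> float:
        """MSE on the standardized scale, dropout off."""
        T = self.scaler_.transform(y) if self.scaler_ is not None else y
        out, _ = self.net_.forward(np.asarray(X, float), dropout_rate=0.0)
        return float(np.mean((out - np.asarray(T, float)) ** 2))


def train_mtdl(
    features: np.ndarray | FeatureMatrix,
    Y_train: np.ndarray,
    config: MTDLConfig,
    seed: int | None = None,
    **kwargs,
) -> MTDLRegressor:
    """Train one network with the given configuration (thin wrapper)."""
    X = features.values if isinstance(features, FeatureMatrix) else features
    model = MTDLRegressor(
        units=config.units, epochs=config.epochs, n_layers=config.n_layers,
        dropout_rate=config.dropout_rate, random_state=seed, **kwargs,
    )
    return model.fit(X, Y_train)


def predict_mtdl(model: MTDLRegressor, features_test: np.ndarray | FeatureMatrix) -> np.ndarray:
    X = features_test.values if isinstance(features_test, FeatureMatrix) else features_test
    return model.predict(X)


def inner_cv_select(
    features: np.ndarray | FeatureMatrix,
    Y_train: np.ndarray,
    grid: HyperGrid,
    validation_fraction: float = 0.2,
    dropout_rate: float = 0.3,
    seed: int | None = None,
    return_table: bool = False,
):
    """Pick hyperparameters on one 80/20 inner train/validation split.

    The training rows are split once; every grid configuration is trained
    on the inner-train part (all from the same seed, so the comparison is
    paired) and scored by validation MSE on the standardized scale.  Ties
    are broken toward the simplest model: fewest layers, then fewest
    units, then fewest epochs.
    """
    X = features.values if isinstance(features, FeatureMatrix) else np.asarray(features, float)
    Y = np.asarray(Y_train, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n = X.shape[0]
    n_val = int(round(validation_fraction * n))
    if n_val < 1 or n - n_val < 2:
        raise ValueError("training set too small for the inner split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    val_idx, tr_idx = perm[:n_val], perm[n_val:]
    scaler = TraitScaler().fit(Y[tr_idx])
    results = []
    for cfg in grid.configs(dropout_rate=dropout_rate,
                            validation_fraction=validation_fraction):
        model = train_mtdl(X[tr_idx], Y[tr_idx], cfg, seed=seed)
        pred = model.predict(X[val_idx])
        val_loss = float(np.mean((scaler.transform(pred) - scaler.transform(Y[val_idx])) ** 2))
        results.append((cfg, val_loss))
    best_cfg, _ = min(
        results,
        key=lambda r: (r[1], r[0].n_layers, r[0].units, r[0].epochs),
    )
    if return_table:
        import pandas as pd

        table = pd.DataFrame(
            [(c.units, c.epochs, c.n_layers, v) for c, v in results],
            columns=["units", "epochs", "n_layers", "val_loss"],
        )
        return best_cfg, table
    return best_cfg
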