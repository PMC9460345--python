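"""Single-hidden-layer GRU one-step weight predictor.

:class:`GRUForecaster` is a scikit-learn-style regressor operating on
scaled lag-window tensors ``(n_samples, k, p)``; :class:`TrainedForecaster`
binds a fitted estimator to its scaler, lookback and feature order so the
walk-forward routines can feed it raw daily rows in physical units.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from ._gru_kernels import ACTIVATIONS, gru_forward, gru_train
from .framing import ScalerParams, SupervisedDataset

__all__ = [
    "GRUForecaster",
    "TrainedForecaster",
    "TrainingDivergedError",
    "ForecastResult",
    "rmse",
    "build_and_train",
]


class TrainingDivergedError(RuntimeError):
    """Loss became non-finite during training."""


def rmse(y: np.ndarray, y_hat: np.ndarray) -> float:
    """Root-mean-square error ``sqrt(sum((y_hat - y)^2) / n)`` in kg."""
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.shape != y_hat.shape:
        raise ValueError(f"length mismatch: {y.shape} vs {y_hat.shape}")
    if y.size == 0:
        raise ValueError("rmse undefined for empty vectors")
    return float(np.sqrt(np.mean((y_hat - y) ** 2)))


class GRUForecaster(RegressorMixin, BaseEstimator):
    """One-step-ahead GRU regressor on lag windows.

    Architecture: input ``(k, p)`` -> GRU(``n_units``, ``activation``)
    -> dropout(``dropout``) -> dense(1).  Trained with mini-batch Adam on
    mean absolute error for exactly ``epochs`` epochs (no early stopping;
    the epoch count is a tuned hyperparameter), batches in time order by
    default.  Dropout is active only during training, so ``predict`` is
    deterministic.

    Parameters
    ----------
    n_units : hidden state size.
    activation : candidate-state activation, one of
        tanh/relu/sigmoid/softplus/softsign/selu/elu/exponential
        (gate activations are always sigmoid).
    batch_size, epochs, dropout : optimization settings.
    learning_rate : Adam step size.
    shuffle : permute sample order each epoch (on by default, as in
        standard deep-learning fit loops; supervised windows are i.i.d.
        rows once framed, so shuffling only affects optimization, not
        information flow).  Set False for strict time-ordered batches.
    seed : seeds both weight initialization and dropout masks.
    """

    def __init__(
        self,
        n_units: int = 100,
        activation: str = "relu",
        batch_size: int = 32,
        epochs: int = 50,
        dropout: float = 0.2,
        learning_rate: float = 1e-3,
        shuffle: bool = True,
        seed: int = 0,
    ):
        self.n_units = n_units
        self.activation = activation
        self.batch_size = batch_size
        self.epochs = epochs
        self.dropout = dropout
        self.learning_rate = learning_rate
        self.shuffle = shuffle
        self.seed = seed

    def _init_weights(self, p: int, rng: np.random.Generator):
        h = self.n_units
        lim_w = np.sqrt(6.0 / (p + 3 * h))
        W = rng.uniform(-lim_w, lim_w, size=(p, 3 * h))
        # orthogonal recurrent kernels, one per gate
        mats = []
        for _ in range(3):
            A = rng.normal(size=(h, h))
            Q, R = np.linalg.qr(A)
            mats.append(Q * np.sign(np.diag(R)))
        U = np.hstack(mats[:2])
        Uc = mats[2]
        b = np.zeros(3 * h)
        lim_o = np.sqrt(6.0 / (h + 1))
        Wo = rng.uniform(-lim_o, lim_o, size=h)
        bo = np.zeros(1)
        return [np.ascontiguousarray(a, dtype=np.float32) for a in (W, U, Uc, b, Wo, bo)]

    def fit(self, X, y, validation_data=None):
        """Fit on scaled windows ``X (n, k, p)`` and targets ``y (n,)``.

        ``validation_data=(X_val, y_val)`` is used only to log a per-epoch
        validation MAE curve (never for weight updates).
        """
        X = np.ascontiguousarray(X, dtype=np.float32)
        y = np.ascontiguousarray(y, dtype=np.float32)
        if X.ndim != 3:
            raise ValueError(f"X must be (n_samples, k, p), got shape {X.shape}")
        if len(X) != len(y):
            raise ValueError("X and y lengths differ")
        if self.activation not in ACTIVATIONS:
            raise ValueError(f"unknown activation {self.activation!r}; choose from {ACTIVATIONS}")
        if not (0.0 <= self.dropout < 1.0):
            raise ValueError("dropout must be in [0, 1)")
        n, k, p = X.shape
        rng = np.random.default_rng(self.seed)
        W, U, Uc, b, Wo, bo = self._init_weights(p, rng)
        if validation_data is not None:
            Xv = np.ascontiguousarray(validation_data[0], dtype=np.float32)
            yv = np.ascontiguousarray(validation_data[1], dtype=np.float32)
        else:
            Xv = np.zeros((0, k, p), dtype=np.float32)
            yv = np.zeros(0, dtype=np.float32)
        history = np.full((2, self.epochs), np.nan)
        status = gru_train(
            X, y, Xv, yv, W, U, Uc, b, Wo, bo,
            ACTIVATIONS.index(self.activation),
            int(self.epochs), int(self.batch_size), float(self.learning_rate),
            float(self.dropout), int(np.uint32(self.seed * 2654435761 % (2**31))),
            bool(self.shuffle), history,
        )
        if status != 0:
            raise TrainingDivergedError(
                f"training diverged (non-finite loss) at hp: {self.get_params()}"
            )
        self.weights_ = {"W": W, "U": U, "Uc": Uc, "b": b, "Wo": Wo, "bo": bo}
        self.history_ = pd.DataFrame(
            {"epoch": np.arange(self.epochs), "train_mae": history[0], "val_mae": history[1]}
        )
        self.n_features_in_ = k * p
        self.lookback_ = k
        self.n_feature_cols_ = p
        return self

    def predict(self, X) -> np.ndarray:
        """Predict scaled next-day weight for each window (deterministic)."""
        check_is_fitted(self, "weights_")
        X = np.ascontiguousarray(X, dtype=np.float32)
        if X.ndim == 2:
            X = X[None, :, :]
        if X.ndim != 3 or X.shape[1] != self.lookback_ or X.shape[2] != self.n_feature_cols_:
            raise ValueError(
                f"window shape {X.shape[1:]} does not match model "
                f"({self.lookback_}, {self.n_feature_cols_})"
            )
        w = self.weights_
        out = gru_forward(
            X, w["W"], w["U"], w["Uc"], w["b"], w["Wo"], w["bo"],
            ACTIVATIONS.index(self.activation),
        )
        return out.astype(float)


@dataclass
class ForecastResult:
    """Actual vs predicted weights over a test window."""

    y: np.ndarray
    y_hat: np.ndarray
    day_index: np.ndarray

    @property
    def n(self) -> int:
        return len(self.y)

    @property
    def rmse(self) -> float:
        return rmse(self.y, self.y_hat)

    @property
    def residuals(self) -> np.ndarray:
        return self.y_hat - self.y

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"day": self.day_index, "actual_kg": self.y, "predicted_kg": self.y_hat}
        )


@dataclass
class TrainedForecaster:
    """A fitted GRU bound to its scaler, lookback and feature order.

    ``predict_next`` consumes the last ``k`` daily feature rows in
    physical units and returns next-day weight in kg, which is the whole
    interface the walk-forward routines need.
    """

    estimator: GRUForecaster
    scaler: ScalerParams
    feature_names: list[str]
    lookback: int

    def predict_next(self, window: np.ndarray | pd.DataFrame) -> float:
        if isinstance(window, pd.DataFrame):
            window = window[self.feature_names].to_numpy(float)
        window = np.asarray(window, dtype=float)
        if window.shape != (self.lookback, len(self.feature_names)):
            raise ValueError(
                f"window must be ({self.lookback}, {len(self.feature_names)}), "
                f"got {window.shape}"
            )
        xs = self.scaler.transform(window)
        y_scaled = self.estimator.predict(xs[None, :, :])[0]
        val = float(self.scaler.inverse_y(y_scaled))
        if not np.isfinite(val):
            raise FloatingPointError("non-finite prediction")
        return val

    def refit(self, dataset: SupervisedDataset) -> "TrainedForecaster":
        """Retrain from scratch on a (re-)framed dataset (same hp/seed)."""
        est = GRUForecaster(**self.estimator.get_params())
        n_val = max(0, dataset.n_samples - (dataset.train_end or dataset.n_samples))
        if n_val > 0:
            est.fit(
                dataset.X[: dataset.train_end], dataset.y[: dataset.train_end],
                validation_data=(dataset.X[dataset.train_end :], dataset.y[dataset.train_end :]),
            )
        else:
            est.fit(dataset.X, dataset.y)
        return TrainedForecaster(
            estimator=est, scaler=dataset.scaler,
            feature_names=list(dataset.feature_names), lookback=dataset.k,
        )

    def save(self, stem) -> None:
        """Persist as ``<stem>.npz`` (weights) + ``<stem>.json`` (metadata)."""
        np.savez(f"{stem}.npz", **self.estimator.weights_)
        meta = {
            "hyperparameters": self.estimator.get_params(),
            "feature_names": self.feature_names,
            "lookback": self.lookback,
            "scaler": {
                "feature_names": self.scaler.feature_names,
                "data_min": self.scaler.data_min.tolist(),
                "data_max": self.scaler.data_max.tolist(),
            },
        }
        with open(f"{stem}.json", "w") as fh:
            json.dump(meta, fh, indent=2)

    @classmethod
    def load(cls, stem) -> "TrainedForecaster":
        with open(f"{stem}.json") as fh:
            meta = json.load(fh)
        est = GRUForecaster(**meta["hyperparameters"])
        wz = np.load(f"{stem}.npz")
        est.weights_ = {k: wz[k] for k in wz.files}
        est.lookback_ = meta["lookback"]
        est.n_feature_cols_ = len(meta["feature_names"])
        est.n_features_in_ = est.lookback_ * est.n_feature_cols_
        sc = meta["scaler"]
        scaler = ScalerParams(
            feature_names=sc["feature_names"],
            data_min=np.array(sc["data_min"]),
            data_max=np.array(sc["data_max"]),
        )
        return cls(
            estimator=est, scaler=scaler,
            feature_names=meta["feature_names"], lookback=meta["lookback"],
        )


def build_and_train(dataset: SupervisedDataset, hp: "HyperParams") -> TrainedForecaster:
    """Frame-to-model convenience: train a GRU from a scaled dataset.

    ``dataset`` must already be framed with ``hp.lookback``/``hp.seasonal``
    and scaled; training uses rows ``< dataset.train_end`` and logs the
    held-out rows as the validation curve.
    """
    from .tuning import HyperParams  # circular-import guard

    if dataset.scaler is None or dataset.X is None:
        raise ValueError("dataset must be scaled (fit_apply_scaler) before training")
    if dataset.k != hp.lookback:
        raise ValueError(f"dataset lookback {dataset.k} != hp.lookback {hp.lookback}")
    est = GRUForecaster(
        n_units=hp.n_neurons, activation=hp.activation, batch_size=hp.batch_size,
        epochs=hp.epochs, dropout=hp.dropout, seed=hp.seed,
    )
    cut = dataset.train_end if dataset.train_end is not None else dataset.n_samples
    val = None
    if cut < dataset.n_samples:
        val = (dataset.X[cut:], dataset.y[cut:])
    est.fit(dataset.X[:cut], dataset.y[:cut], validation_data=val)
    return TrainedForecaster(
        estimator=est, scaler=dataset.scaler,
        feature_names=list(dataset.feature_names), lookback=dataset.k,
    )
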