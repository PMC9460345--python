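"""Reframe a daily series as a lagged supervised-learning dataset.

One sample predicts the weight on day ``t`` from the ``k`` preceding
days' feature rows (days ``t-k .. t-1``).  Feature order is fixed:

    eb_kcal, carb_g, protein_g, lipid_g, weight_kg [, week_cos, week_sin]

Scaling is min-max to [0, 1] per feature, fitted on the training days
only; test-day values may fall outside [0, 1] (no clipping).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.preprocessing import MinMaxScaler, StandardScaler

from .energy import UserSeries

__all__ = [
    "BASE_FEATURES",
    "SEASONAL_FEATURES",
    "feature_names",
    "ScalerParams",
    "SupervisedDataset",
    "make_supervised",
    "fit_apply_scaler",
]

BASE_FEATURES = ["eb_kcal", "carb_g", "protein_g", "lipid_g", "weight_kg"]
SEASONAL_FEATURES = ["week_cos", "week_sin"]

#: Lookbacks considered standard for tuning; larger values only warn.
STANDARD_LOOKBACKS = range(3, 8)


def feature_names(include_seasonal: bool) -> list[str]:
    return BASE_FEATURES + (SEASONAL_FEATURES if include_seasonal else [])


@dataclass
class ScalerParams:
    """Per-feature affine scaling ``(x - data_min) / (data_max - data_min)``
    fitted on training rows only.

    With ``method="minmax"`` (default) the bounds are the training min/max
    (features land in [0, 1]); with ``method="standard"`` they are
    ``mean`` and ``mean + sd``, which makes the same affine form a
    z-score.  ``transform``/``inverse`` act on the last axis of any
    window stack; the target (weight) shares the weight feature's
    parameters so predictions invert back to kg.
    """

    feature_names: list[str]
    data_min: np.ndarray
    data_max: np.ndarray
    method: str = "minmax"

    @property
    def weight_index(self) -> int:
        return self.feature_names.index("weight_kg")

    @property
    def _scale(self) -> np.ndarray:
        rng = self.data_max - self.data_min
        # Constant features map to 0 rather than dividing by zero.
        return np.where(rng > 0, rng, 1.0)

    @classmethod
    def fit(cls, rows: np.ndarray, names: list[str], method: str = "minmax") -> "ScalerParams":
        if method == "minmax":
            sk = MinMaxScaler().fit(rows)
            lo, hi = sk.data_min_.copy(), sk.data_max_.copy()
        elif method == "standard":
            sk = StandardScaler().fit(rows)
            lo = sk.mean_.copy()
            hi = sk.mean_ + np.sqrt(sk.var_)
        else:
            raise ValueError(f"unknown scaling method {method!r}")
        if np.any(hi - lo <= 0):
            flat = [names[i] for i in np.flatnonzero(hi - lo <= 0)]
            warnings.warn(f"constant feature(s) {flat} scaled to 0", stacklevel=2)
        return cls(feature_names=list(names), data_min=lo, data_max=hi, method=method)

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (X - self.data_min) / self._scale

    def inverse(self, X: np.ndarray) -> np.ndarray:
        return X * self._scale + self.data_min

    def transform_y(self, y: np.ndarray | float) -> np.ndarray | float:
        i = self.weight_index
        return (y - self.data_min[i]) / self._scale[i]

    def inverse_y(self, y: np.ndarray | float) -> np.ndarray | float:
        i = self.weight_index
        return y * self._scale[i] + self.data_min[i]


@dataclass
class SupervisedDataset:
    """Lagged windows ``X[i] = days (t_i - k .. t_i - 1)`` and targets
    ``y[i] = weight(t_i)``; ``X``/``y`` are the scaled views once
    :func:`fit_apply_scaler` ran, with raw copies kept alongside."""

    X_raw: np.ndarray  # (n_samples, k, p)
    y_raw: np.ndarray  # (n_samples,)
    k: int
    feature_names: list[str]
    sample_day_index: np.ndarray  # target day t of each sample
    scaler: ScalerParams | None = None
    X: np.ndarray | None = None
    y: np.ndarray | None = None
    train_end: int | None = None  # sample count in the training part

    @property
    def n_samples(self) -> int:
        return len(self.y_raw)

    @property
    def p(self) -> int:
        return self.X_raw.shape[2]

    def to_flat_frame(self) -> pd.DataFrame:
        """Flat var_j(t-k) .. var_j(t-1), target(t) layout for inspection."""
        cols, data = [], []
        for lag in range(self.k, 0, -1):
            for j, name in enumerate(self.feature_names):
                cols.append(f"{name}(t-{lag})")
                data.append(self.X_raw[:, self.k - lag, j])
        cols.append("weight_kg(t)")
        data.append(self.y_raw)
        return pd.DataFrame(dict(zip(cols, data)), index=self.sample_day_index)


def make_supervised(
    series: UserSeries | pd.DataFrame,
    k: int,
    include_seasonal: bool = False,
) -> SupervisedDataset:
    """Build contiguous, ordered (non-shuffled) lag windows from a series.

    Requires ``len(series) > k``; lookbacks outside 3..7 are allowed with
    a warning (they fall outside the standard tuning range).
    """
    df = series.data if isinstance(series, UserSeries) else series
    if not isinstance(k, (int, np.integer)) or k < 1:
        raise ValueError(f"lookback k must be a positive integer, got {k!r}")
    if k not in STANDARD_LOOKBACKS:
        warnings.warn(f"lookback {k} outside the standard range 3..7", stacklevel=2)
    names = feature_names(include_seasonal)
    missing = [c for c in names if c not in df.columns]
    if missing:
        raise ValueError(f"series lacks feature columns {missing}; prepare it first")
    n_days = len(df)
    if n_days <= k:
        raise ValueError(
            f"series length {n_days} too short for lookback {k}; need at least {k + 1} days"
        )
    F = df[names].to_numpy(float)
    if np.isnan(F).any():
        raise ValueError("feature matrix contains missing values; impute first")
    n_samples = n_days - k
    X = np.empty((n_samples, k, len(names)))
    for i in range(n_samples):
        X[i] = F[i : i + k]
    y = F[k:, names.index("weight_kg")].copy()
    return SupervisedDataset(
        X_raw=X,
        y_raw=y,
        k=k,
        feature_names=names,
        sample_day_index=np.arange(k, n_days),
    )


def fit_apply_scaler(
    dataset: SupervisedDataset,
    split: int | float,
    min_train: int = 30,
    series_rows: np.ndarray | None = None,
    method: str = "minmax",
) -> SupervisedDataset:
    """Fit min-max parameters on the training portion and scale in place.

    ``split`` is either a training fraction in (0, 1) or an absolute count
    of training samples.  The scaler sees only feature rows belonging to
    training days (days ``< sample_day_index[cut]``), so test rows cannot
    influence the statistics.
    """
    n = dataset.n_samples
    cut = int(round(split * n)) if isinstance(split, float) and 0 < split < 1 else int(split)
    if not (0 < cut <= n):
        raise ValueError(f"split must leave between 1 and {n} training samples, got {cut}")
    if cut < min_train:
        raise ValueError(f"split leaves {cut} training samples; need >= {min_train}")
    if series_rows is None:
        # Training windows cover days 0 .. sample_day_index[cut-1] inclusive
        # (the last training target day); reconstruct those rows from X/y.
        rows = dataset.X_raw[:cut].reshape(-1, dataset.p)
        last = dataset.X_raw[cut - 1, -1:, :]
        rows = np.vstack([rows, last])
    else:
        rows = series_rows
    scaler = ScalerParams.fit(rows, dataset.feature_names, method=method)
    dataset.scaler = scaler
    dataset.X = scaler.transform(dataset.X_raw)
    dataset.y = np.asarray(scaler.transform_y(dataset.y_raw))
    dataset.train_end = cut
    return dataset
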