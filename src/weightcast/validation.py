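"""Train/test forecasting and walk-forward validation / simulation.

Three evaluation regimes for a one-step forecaster:

* **train/test forecast** — train once, then predict a test window
  recursively, feeding the model its own weight predictions while
  covariates stay actual;
* **walk-forward validation (WFV)** — predict each test day from the
  last ``k`` *actual* days, then (by default) retrain with that day's
  actual row appended, mimicking deployment where data arrive daily;
* **walk-forward simulation (WFS)** — windows are filled with *planned*
  covariates and the model's own predicted weights; used to play out
  hypothetical diet plans.  Plan covariates take effect from the last
  observed day onward (starting a plan redefines "today's" intake), so a
  constant-EB plan drives every simulated step.  A no-retraining variant
  can start from any historical day, not just the series end.

All routines talk to a model through a minimal protocol: ``lookback``,
``feature_names`` and ``predict_next(last k feature rows) -> kg``, so
closed-form reference models can stand in for a trained network.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Protocol, runtime_checkable

import numpy as np
import pandas as pd

from .energy import UserSeries
from .forecaster import ForecastResult, TrainedForecaster, build_and_train
from .framing import SEASONAL_FEATURES, fit_apply_scaler, make_supervised

__all__ = [
    "OneStepModel",
    "WalkForwardConfig",
    "SimulationResult",
    "train_test_forecast",
    "recursive_forecast",
    "walk_forward_validate",
    "walk_forward_simulate",
    "simulate_without_retraining",
    "LinearEBStub",
    "PersistenceStub",
]

#: Hard physiological bounds on simulated weight; hitting them is logged
#: and treated as a failed run during tuning.
WEIGHT_CLAMP = (30.0, 250.0)


@runtime_checkable
class OneStepModel(Protocol):
    lookback: int
    feature_names: list[str]

    def predict_next(self, window) -> float: ...


@dataclass
class WalkForwardConfig:
    horizon: int = 7
    retrain: str = "every_step"  # or "frozen"
    mode: str = "validate"  # or "simulate"
    covariate_source: str = "actual"  # or "plan"

    def __post_init__(self) -> None:
        if self.horizon < 0:
            raise ValueError("horizon must be >= 0")
        if self.retrain not in ("every_step", "frozen"):
            raise ValueError(f"unknown retrain policy {self.retrain!r}")
        if self.mode not in ("validate", "simulate"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "validate" and self.covariate_source != "actual":
            raise ValueError("mode=validate requires covariate_source=actual")


@dataclass
class SimulationResult:
    """Daily simulated weights plus a per-step provenance ledger."""

    weights: np.ndarray
    ledger: pd.DataFrame
    retrain: str
    n_clamped: int = 0

    def __len__(self) -> int:
        return len(self.weights)


# ---------------------------------------------------------------------------
# reference stub models (closed-form oracles for tests and examples)


@dataclass
class LinearEBStub:
    """``w(t+1) = w(t) + m * EB(t)`` read off the window's last row."""

    m: float
    feature_names: list[str] = field(
        default_factory=lambda: ["eb_kcal", "carb_g", "protein_g", "lipid_g", "weight_kg"]
    )
    lookback: int = 5

    def predict_next(self, window) -> float:
        arr = window[self.feature_names].to_numpy(float) if isinstance(window, pd.DataFrame) else np.asarray(window, float)
        w = arr[-1, self.feature_names.index("weight_kg")]
        eb = arr[-1, self.feature_names.index("eb_kcal")]
        return float(w + self.m * eb)

    def retrained(self, df) -> "LinearEBStub":
        return self


@dataclass
class PersistenceStub:
    """``w(t+1) = w(t)``: carries the last weight forward."""

    feature_names: list[str] = field(
        default_factory=lambda: ["eb_kcal", "carb_g", "protein_g", "lipid_g", "weight_kg"]
    )
    lookback: int = 5

    def predict_next(self, window) -> float:
        arr = window[self.feature_names].to_numpy(float) if isinstance(window, pd.DataFrame) else np.asarray(window, float)
        return float(arr[-1, self.feature_names.index("weight_kg")])

    def retrained(self, df) -> "PersistenceStub":
        return self


# ---------------------------------------------------------------------------
# helpers


def _as_frame(series) -> pd.DataFrame:
    return series.data if isinstance(series, UserSeries) else series


def _fit_model(df: pd.DataFrame, hp, train_end_day: int, test_end_day: int | None = None,
               min_train: int = 1) -> TrainedForecaster:
    """Frame days ``[0, test_end_day)``, scale on days ``< train_end_day``,
    train on the training samples."""
    sub = df.iloc[: test_end_day if test_end_day is not None else len(df)]
    ds = make_supervised(sub, hp.lookback, include_seasonal=hp.seasonal)
    cut = train_end_day - hp.lookback
    if cut < 1:
        raise ValueError(
            f"series too short: need > lookback + test days "
            f"(train_end_day={train_end_day}, lookback={hp.lookback})"
        )
    fit_apply_scaler(ds, cut, min_train=min_train)
    return build_and_train(ds, hp)


def _retrain(model, df: pd.DataFrame):
    """Full refit on all rows of ``df`` (fresh scaler and weights)."""
    if hasattr(model, "retrained"):
        return model.retrained(df)
    seasonal = any(c in model.feature_names for c in SEASONAL_FEATURES)
    ds = make_supervised(df, model.lookback, include_seasonal=seasonal)
    fit_apply_scaler(ds, ds.n_samples, min_train=1)
    return model.refit(ds)


def _extend_seasonal(df: pd.DataFrame, n_future: int) -> pd.DataFrame:
    """Rows of week_cos/week_sin continuing the weekly phase past ``df``."""
    if not all(c in df.columns for c in SEASONAL_FEATURES):
        return pd.DataFrame(index=range(n_future))
    theta = np.arctan2(df["week_sin"].iloc[-1], df["week_cos"].iloc[-1])
    step = 2.0 * np.pi / 7.0
    ang = theta + step * np.arange(1, n_future + 1)
    return pd.DataFrame({"week_cos": np.cos(ang), "week_sin": np.sin(ang)})


# ---------------------------------------------------------------------------
# train/test forecasting


def recursive_forecast(model: OneStepModel, df: pd.DataFrame, start_day: int,
                       horizon: int) -> ForecastResult:
    """Predict days ``start_day .. start_day+horizon-1`` recursively:
    actual covariates, own weight predictions fed back into windows."""
    k = model.lookback
    if start_day < k:
        raise ValueError(f"start_day must be >= lookback ({k})")
    if start_day + horizon > len(df):
        raise ValueError("forecast window extends past the series")
    work = df[model.feature_names].copy()
    preds = np.empty(horizon)
    for j in range(horizon):
        d = start_day + j
        window = work.iloc[d - k : d]
        preds[j] = model.predict_next(window)
        work.iloc[d, work.columns.get_loc("weight_kg")] = preds[j]
    actual = df["weight_kg"].to_numpy(float)[start_day : start_day + horizon]
    return ForecastResult(y=actual, y_hat=preds, day_index=np.arange(start_day, start_day + horizon))


def train_test_forecast(series, hp, test_len: int = 7) -> ForecastResult:
    """Train once on all but the last ``test_len`` days, then predict the
    test window recursively (actual covariates, own weight predictions)."""
    df = _as_frame(series)
    n = len(df)
    if test_len < 1:
        raise ValueError("test_len must be >= 1")
    if n <= hp.lookback + test_len:
        raise ValueError(
            f"series length {n} too short for lookback {hp.lookback} + {test_len} test days"
        )
    cut = n - test_len
    model = _fit_model(df, hp, train_end_day=cut)
    return recursive_forecast(model, df, cut, test_len)


# ---------------------------------------------------------------------------
# walk-forward validation


def walk_forward_validate(series, hp, config: WalkForwardConfig,
                          model: TrainedForecaster | None = None) -> ForecastResult:
    """Day-by-day evaluation over the last ``config.horizon`` days.

    Each prediction uses the last ``k`` *actual* rows; with
    ``retrain="every_step"`` the just-revealed actual day is appended and
    the model refit from scratch before the next prediction.
    """
    if config.mode != "validate":
        raise ValueError("config.mode must be 'validate'")
    df = _as_frame(series)
    n = len(df)
    H = config.horizon
    if n <= hp.lookback + H:
        raise ValueError(f"series length {n} too short for lookback {hp.lookback} + horizon {H}")
    cut = n - H
    if model is None:
        model = _fit_model(df, hp, train_end_day=cut)
    k = model.lookback
    preds = np.empty(H)
    feats = df[model.feature_names]
    for j in range(H):
        d = cut + j
        preds[j] = model.predict_next(feats.iloc[d - k : d])
        if config.retrain == "every_step" and j < H - 1:
            model = _retrain(model, df.iloc[: d + 1])
    actual = df["weight_kg"].to_numpy(float)[cut:n]
    return ForecastResult(y=actual, y_hat=preds, day_index=np.arange(cut, n))


# ---------------------------------------------------------------------------
# walk-forward simulation


def _require_plan(plan: pd.DataFrame, horizon: int) -> pd.DataFrame:
    needed = ["eb_kcal", "carb_g", "protein_g", "lipid_g"]
    if hasattr(plan, "frame"):  # DietPlan
        plan = plan.frame
    missing = [c for c in needed if c not in plan.columns]
    if missing:
        raise ValueError(f"plan lacks covariate columns {missing}")
    if len(plan) < horizon:
        raise ValueError(f"plan provides {len(plan)} days but horizon is {horizon}")
    return plan.reset_index(drop=True)


def _simulate_core(model: OneStepModel, df: pd.DataFrame, start_day: int,
                   plan: pd.DataFrame, horizon: int, retrain: str) -> SimulationResult:
    """Shared WFS loop.

    Simulated days are ``start_day .. start_day+horizon-1``; plan row ``j``
    supplies covariates for day ``start_day-1+j`` (the plan starts on the
    last observed day).  Weights for days ``< start_day`` are actual
    ("known"); later ones are the model's own predictions.
    """
    k = model.lookback
    if start_day < k:
        raise ValueError(f"start_day ({start_day}) must be >= lookback ({k})")
    if start_day > len(df):
        raise ValueError(f"start_day ({start_day}) out of range for series of {len(df)} days")
    if horizon == 0:
        return SimulationResult(weights=np.empty(0), ledger=pd.DataFrame(), retrain=retrain)
    plan = _require_plan(plan, horizon)

    names = model.feature_names
    hist = df.iloc[:start_day]
    work = hist[[c for c in df.columns if c in set(names) | {"eb_kcal", "carb_g", "protein_g", "lipid_g", "weight_kg"}]].copy()
    # future rows: planned covariates + extrapolated seasonal phase
    future = plan.iloc[1:horizon][["eb_kcal", "carb_g", "protein_g", "lipid_g"]].copy()
    seas = _extend_seasonal(hist, horizon - 1)
    for c in seas.columns:
        if c in work.columns:
            future[c] = seas[c].to_numpy()
    future["weight_kg"] = np.nan
    work = pd.concat([work, future], ignore_index=True)
    # plan day 0 overrides the last observed day's covariates
    for c in ["eb_kcal", "carb_g", "protein_g", "lipid_g"]:
        work.iloc[start_day - 1, work.columns.get_loc(c)] = plan[c].iloc[0]

    weights = np.empty(horizon)
    rows = []
    n_clamped = 0
    wcol = work.columns.get_loc("weight_kg")
    for j in range(horizon):
        d = start_day + j
        window = work.iloc[d - k : d]
        w = model.predict_next(window[names])
        if not (WEIGHT_CLAMP[0] <= w <= WEIGHT_CLAMP[1]):
            w = float(np.clip(w, *WEIGHT_CLAMP))
            n_clamped += 1
        weights[j] = w
        if d < len(work):  # the final day's prediction enters no window
            work.iloc[d, wcol] = w
        rows.append(
            {
                "day": d,
                "weight_source": "predict",
                "covariate_source": "simulated",
                "eb_kcal": plan["eb_kcal"].iloc[j],
                "carb_g": plan["carb_g"].iloc[j],
                "protein_g": plan["protein_g"].iloc[j],
                "lipid_g": plan["lipid_g"].iloc[j],
                "weight_kg": w,
                "n_known_weight_rows_in_window": int(sum(1 for dd in range(d - k, d) if dd < start_day)),
                "n_predicted_weight_rows_in_window": int(sum(1 for dd in range(d - k, d) if dd >= start_day)),
                "n_planned_covariate_rows_in_window": int(sum(1 for dd in range(d - k, d) if dd >= start_day - 1)),
            }
        )
        if retrain == "every_step" and j < horizon - 1:
            model = _retrain(model, work.iloc[: d + 1])
    return SimulationResult(
        weights=weights, ledger=pd.DataFrame(rows), retrain=retrain, n_clamped=n_clamped
    )


def walk_forward_simulate(model: OneStepModel, series, plan,
                          config: WalkForwardConfig) -> SimulationResult:
    """Simulate ``config.horizon`` days past the end of ``series`` under a
    diet plan.  With the default ``retrain="every_step"`` the predicted/
    planned row is appended to the training data before each next step."""
    if config.mode != "simulate":
        raise ValueError("config.mode must be 'simulate'")
    df = _as_frame(series)
    return _simulate_core(model, df, len(df), plan, config.horizon, config.retrain)


def simulate_without_retraining(model: OneStepModel, series, start_day: int,
                                plan, horizon: int = 7) -> SimulationResult:
    """Frozen-model WFS seeded from an arbitrary historical ``start_day``
    (window built from days ``start_day-k .. start_day-1``)."""
    df = _as_frame(series)
    return _simulate_core(model, df, int(start_day), plan, horizon, retrain="frozen")
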