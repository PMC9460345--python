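"""Constraint-filtered hyperparameter grid search.

The grid spans neurons x activation x batch x epochs x dropout x
lookback x seasonal (19,200 points).  Before a candidate competes on
forecast error it must behave physiologically: a 7-day frozen-model diet
simulation at EB = -1000, -500, 0, +500, +1000 kcal/day (50/20/30 macro
split) has to

1. gain weight under a +1000 kcal/day surplus,
2. lose weight under a -1000 kcal/day deficit,
3. keep the day-7 spread between the two extremes below 10 kg, and
4. respond monotonically (non-decreasing weight change in EB).

Points failing any condition are discarded regardless of their RMSE;
among the survivors, the 7-day held-out test RMSE is minimized.  Ties
prefer the simpler model (fewer neurons, then smaller lookback, then
smaller batch).
"""

from __future__ import annotations

import itertools
import time
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .dietplan import STANDARD_EB_LEVELS, STANDARD_SPLIT, baseline_expenditure, simulate_diet_response
from .energy import UserSeries
from .forecaster import TrainedForecaster, TrainingDivergedError, build_and_train
from .framing import fit_apply_scaler, make_supervised
from .validation import OneStepModel, recursive_forecast

__all__ = [
    "GRID",
    "HyperParams",
    "ConstraintReport",
    "TuningResult",
    "NoPassingPointError",
    "anchor_point",
    "sample_grid",
    "check_constraints",
    "grid_search",
]

GRID = {
    "n_neurons": (50, 100, 150, 200),
    "activation": ("tanh", "relu", "sigmoid", "softplus", "softsign", "selu", "elu", "exponential"),
    "batch_size": (8, 16, 32, 64, 128),
    "epochs": (50, 100, 150, 200),
    "dropout": (0.2, 0.4, 0.6),
    "lookback": (3, 4, 5, 6, 7),
    "seasonal": (False, True),
}

#: Day-7 spread bound between the +1000 and -1000 kcal/day simulations (kg).
MAX_EXTREME_SPREAD_KG = 10.0
MONOTONE_TOL_KG = 1e-6


@dataclass(frozen=True)
class HyperParams:
    """One point of the tuning grid."""

    n_neurons: int = 100
    activation: str = "relu"
    batch_size: int = 32
    epochs: int = 50
    dropout: float = 0.2
    lookback: int = 5
    seasonal: bool = False
    seed: int = 0

    def validate(self, unsafe_grid: bool = False) -> None:
        if unsafe_grid:
            return
        for name, choices in GRID.items():
            if getattr(self, name) not in choices:
                raise ValueError(
                    f"hyperparameter {name}={getattr(self, name)!r} outside the grid "
                    f"{choices} (pass unsafe_grid=True to override)"
                )

    def to_dict(self) -> dict:
        return {
            "n_neurons": self.n_neurons, "activation": self.activation,
            "batch_size": self.batch_size, "epochs": self.epochs,
            "dropout": self.dropout, "lookback": self.lookback,
            "seasonal": self.seasonal, "seed": self.seed,
        }


def anchor_point(seed: int = 0) -> HyperParams:
    """Sane default candidate always included in the search (ReLU with
    light dropout, mid-sized layer, short training)."""
    return HyperParams(n_neurons=100, activation="relu", batch_size=32, epochs=50,
                       dropout=0.2, lookback=5, seasonal=False, seed=seed)


def full_grid() -> list[HyperParams]:
    keys = list(GRID)
    return [HyperParams(**dict(zip(keys, combo))) for combo in itertools.product(*GRID.values())]


def sample_grid(budget: int, seed: int, include_anchor: bool = True) -> list[HyperParams]:
    """Uniform seeded subsample of the full grid (exhaustive if it fits),
    with the anchor point prepended."""
    sizes = [len(v) for v in GRID.values()]
    total = int(np.prod(sizes))
    rng = np.random.default_rng(seed)
    n = min(budget, total)
    idx = rng.choice(total, size=n, replace=False)
    keys = list(GRID)
    pts = []
    for flat in idx:
        combo = {}
        rem = int(flat)
        for name, size in zip(reversed(keys), reversed(sizes)):
            combo[name] = GRID[name][rem % size]
            rem //= size
        pts.append(HyperParams(**combo))
    if include_anchor:
        a = anchor_point()
        pts = [a] + [p for p in pts if p != a]
    return pts


@dataclass
class ConstraintReport:
    """Measured behaviour of one candidate under the 5-level EB sweep."""

    delta_w_surplus: float  # w(t+7) - w(t) at EB = +1000
    delta_w_deficit: float  # w(t+7) - w(t) at EB = -1000
    spread: float  # w(t+7)|+1000 - w(t+7)|-1000
    monotonicity_violations: int
    gains_on_surplus: bool = field(init=False)
    loses_on_deficit: bool = field(init=False)
    spread_bounded: bool = field(init=False)
    monotone: bool = field(init=False)
    failure_reason: str | None = None

    def __post_init__(self) -> None:
        self.gains_on_surplus = self.delta_w_surplus > 0
        self.loses_on_deficit = self.delta_w_deficit < 0
        self.spread_bounded = self.spread < MAX_EXTREME_SPREAD_KG
        self.monotone = self.monotonicity_violations == 0

    @property
    def passed(self) -> bool:
        return (
            self.failure_reason is None
            and self.gains_on_surplus
            and self.loses_on_deficit
            and self.spread_bounded
            and self.monotone
        )

    @classmethod
    def failed(cls, reason: str) -> "ConstraintReport":
        rep = cls(np.nan, np.nan, np.nan, 0)
        rep.failure_reason = reason
        rep.gains_on_surplus = rep.loses_on_deficit = rep.spread_bounded = rep.monotone = False
        return rep


def check_constraints(
    model: OneStepModel,
    series,
    baseline_B: float | None = None,
    train_days: int | None = None,
    horizon: int = 7,
    eb_levels=STANDARD_EB_LEVELS,
    split=STANDARD_SPLIT,
) -> ConstraintReport:
    """Run the 5-level frozen-model diet simulation and grade the four
    physiological conditions."""
    df = series.data if isinstance(series, UserSeries) else series
    if baseline_B is None:
        baseline_B = baseline_expenditure(df, train_days)
    start = train_days if train_days is not None else len(df)
    try:
        sims = simulate_diet_response(
            model, df, eb_levels=sorted(eb_levels), split=split, horizon=horizon,
            baseline_B=baseline_B, retrain="frozen", start_day=start,
        )
    except Exception as exc:  # noqa: BLE001 - report, don't crash the search
        return ConstraintReport.failed(f"simulation failed: {exc}")
    if any(s.n_clamped > 0 for s in sims.values()):
        return ConstraintReport.failed("simulated weight left physiological bounds")
    w0 = float(df["weight_kg"].iloc[start - 1])
    levels = sorted(float(l) for l in eb_levels)
    endpoints = {lv: float(sims[lv].weights[-1]) for lv in levels}
    dws = np.array([endpoints[lv] - w0 for lv in levels])
    violations = int(np.sum(np.diff(dws) < -MONOTONE_TOL_KG))
    return ConstraintReport(
        delta_w_surplus=endpoints[1000.0] - w0 if 1000.0 in endpoints else np.nan,
        delta_w_deficit=endpoints[-1000.0] - w0 if -1000.0 in endpoints else np.nan,
        spread=endpoints[1000.0] - endpoints[-1000.0]
        if (1000.0 in endpoints and -1000.0 in endpoints)
        else np.nan,
        monotonicity_violations=violations,
    )


class NoPassingPointError(RuntimeError):
    """Every evaluated candidate failed the physiological constraints."""

    def __init__(self, ledger: pd.DataFrame):
        super().__init__("no hyperparameter point passed the constraint filter")
        self.ledger = ledger


@dataclass
class TuningResult:
    best_hp: HyperParams
    best_model: OneStepModel
    best_rmse: float
    ledger: pd.DataFrame
    n_discarded_by_constraints: int

    def ledger_to_csv(self, path, user: str = "") -> None:
        df = self.ledger.copy()
        df.insert(0, "user", user)
        df.to_csv(path, index=False)


def _default_train(dataset, hp) -> TrainedForecaster:
    return build_and_train(dataset, hp)


def grid_search(
    series,
    space: list[HyperParams] | None = None,
    budget: int = 60,
    seed: int = 0,
    test_len: int = 7,
    train_fn=None,
    unsafe_grid: bool = False,
) -> TuningResult:
    """Evaluate candidates (frame -> train -> constraint check -> test
    RMSE) and return the best constraint-passing point.

    ``space=None`` draws ``budget`` uniform points from the full grid
    (seeded) plus the anchor; an explicit ``space`` is truncated to
    ``budget`` by seeded subsampling if longer.  ``train_fn(dataset, hp)``
    may replace the default GRU trainer (e.g. with a reference model) and
    must return an object satisfying the one-step-model protocol.
    """
    df = series.data if isinstance(series, UserSeries) else series
    if space is None:
        space = sample_grid(budget, seed)
    elif len(space) == 0:
        raise ValueError("empty hyperparameter space")
    elif len(space) > budget:
        rng = np.random.default_rng(seed)
        keep = rng.choice(len(space), size=budget, replace=False)
        space = [space[i] for i in sorted(keep)]
    train_fn = train_fn or _default_train
    n = len(df)
    max_k = max(hp.lookback for hp in space)
    if n <= max_k + test_len + 1:
        raise ValueError(f"series of {n} days too short for lookback {max_k} + {test_len} test days")
    cut = n - test_len
    baseline_B = baseline_expenditure(df, cut)
    master = np.random.default_rng(seed)
    rows = []
    best = None  # (rmse, n_neurons, lookback, batch, idx, hp, model)
    n_discarded = 0
    for i, hp in enumerate(space):
        hp = replace(hp, seed=int(master.integers(2**31)))
        hp.validate(unsafe_grid=unsafe_grid)
        t0 = time.perf_counter()
        row = {**hp.to_dict(), "status": "ok", "rmse": np.nan}
        model = None
        try:
            ds = make_supervised(df, hp.lookback, include_seasonal=hp.seasonal)
            fit_apply_scaler(ds, cut - hp.lookback, min_train=1)
            model = train_fn(ds, hp)
            report = check_constraints(
                model, df, baseline_B=baseline_B, train_days=cut,
            )
        except TrainingDivergedError:
            row["status"] = "diverged"
            report = ConstraintReport.failed("training diverged")
        row.update(
            constraints_passed=report.passed,
            delta_w_surplus=report.delta_w_surplus,
            delta_w_deficit=report.delta_w_deficit,
            spread=report.spread,
            monotonicity_violations=report.monotonicity_violations,
            constraint_failure=report.failure_reason or "",
        )
        if report.passed:
            result = recursive_forecast(model, df, cut, test_len)
            row["rmse"] = result.rmse
            key = (result.rmse, hp.n_neurons, hp.lookback, hp.batch_size, i)
            if best is None or key < best[0]:
                best = (key, hp, model)
        else:
            n_discarded += 1
        row["wall_time_s"] = time.perf_counter() - t0
        rows.append(row)
    ledger = pd.DataFrame(rows)
    if best is None:
        raise NoPassingPointError(ledger)
    key, best_hp, best_model = best
    return TuningResult(
        best_hp=best_hp, best_model=best_model, best_rmse=float(key[0]),
        ledger=ledger, n_discarded_by_constraints=n_discarded,
    )
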