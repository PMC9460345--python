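"""Diet-plan construction, response simulation and plasticity extraction.

A diet plan fixes the daily energy balance at ``eb_target`` with a given
macronutrient energy split (default 50/20/30% carbohydrate/protein/lipid,
within acceptable macronutrient distribution ranges).  Because the
thermic effect of food itself depends on intake, the gross energy intake
realizing the target is obtained in closed form by inverting the ledger:

    EI = (eb_target + B) / (1 - 0.095*p_c - 0.015*p_l - 0.25*p_p)

with ``B`` the user's habitual non-food expenditure (mean RMR + activity
over the training window), and grams follow from the energy densities
3.75/4/9 kcal/g.

Simulating the tuned forecaster under a sweep of EB levels, smoothing
each 7-day trajectory with a parabola (to cancel day-scale artifacts such
as water retention), and regressing the fitted weekly weight change on EB
yields the per-user line

    dw = m * EB + q

whose slope ``m`` (kg/kcal) is the user's *metabolic plasticity* — the
weight response per daily unbalanced kilocalorie — and whose intercept
``q`` (kg, the weight change at EB=0) is a quality factor for the
energy-balance accounting: nonzero ``q`` flags residual reporting bias.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .energy import (
    KCAL_PER_G_CARB,
    KCAL_PER_G_LIPID,
    KCAL_PER_G_PROTEIN,
    UserSeries,
)
from .synthetic import tef_denominator
from .validation import OneStepModel, SimulationResult, _simulate_core

__all__ = [
    "STANDARD_EB_LEVELS",
    "STANDARD_SPLIT",
    "DietPlan",
    "PlasticityFit",
    "InfeasiblePlanError",
    "plan_to_covariates",
    "simulate_diet_response",
    "parabolic_delta_w",
    "fit_plasticity",
    "extract_plasticity",
    "baseline_expenditure",
]

#: EB sweep used for constraint filtering and plasticity extraction (kcal/day).
STANDARD_EB_LEVELS = (-1000.0, -500.0, 0.0, 500.0, 1000.0)
#: Standard macronutrient energy fractions (carb, protein, lipid).
STANDARD_SPLIT = (0.5, 0.2, 0.3)


class InfeasiblePlanError(ValueError):
    """The requested energy balance cannot be realized with positive intake."""


@dataclass
class DietPlan:
    """A constant-EB plan resolved into per-day covariates."""

    eb_target: float
    macro_split: tuple[float, float, float]
    horizon: int
    frame: pd.DataFrame  # day, eb_kcal, carb_g, protein_g, lipid_g, ei_kcal

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "DietPlan":
        df = pd.read_csv(path)
        needed = ["eb_kcal", "carb_g", "protein_g", "lipid_g"]
        missing = [c for c in needed if c not in df.columns]
        if missing:
            raise ValueError(f"plan CSV lacks columns {missing}")
        return cls(
            eb_target=float(df["eb_kcal"].mean()),
            macro_split=(np.nan, np.nan, np.nan),
            horizon=len(df),
            frame=df,
        )


def baseline_expenditure(series, train_days: int | None = None) -> float:
    """Mean non-food expenditure RMR + TEA (kcal/day) over the training
    window — the personal constant entering the plan inversion."""
    df = series.data if isinstance(series, UserSeries) else series
    sub = df.iloc[:train_days] if train_days is not None else df
    return float((sub["rmr_kcal"] + sub["tea_kcal"]).mean())


def plan_to_covariates(
    eb_target: float,
    split: tuple[float, float, float] = STANDARD_SPLIT,
    baseline_B: float = 2000.0,
    horizon: int = 7,
) -> DietPlan:
    """Resolve a constant-EB plan into daily intake covariates.

    The returned grams and energy intake satisfy
    ``EI - (baseline_B + TEF(grams)) = eb_target`` exactly.
    """
    p_c, p_p, p_l = split
    if abs(p_c + p_p + p_l - 1.0) > 1e-9 or min(split) < 0:
        raise ValueError(f"macro split must be non-negative fractions summing to 1, got {split}")
    if baseline_B <= 0:
        raise ValueError("baseline_B must be positive")
    denom = tef_denominator(split)
    if denom <= 0:
        raise InfeasiblePlanError(f"TEF fractions leave no net energy (denominator {denom})")
    ei = (eb_target + baseline_B) / denom
    if ei <= 0:
        raise InfeasiblePlanError(
            f"EB target {eb_target} kcal vs baseline {baseline_B} kcal requires "
            f"non-positive intake ({ei:.1f} kcal)"
        )
    row = {
        "eb_kcal": float(eb_target),
        "carb_g": p_c * ei / KCAL_PER_G_CARB,
        "protein_g": p_p * ei / KCAL_PER_G_PROTEIN,
        "lipid_g": p_l * ei / KCAL_PER_G_LIPID,
        "ei_kcal": ei,
    }
    frame = pd.DataFrame([{"day": d, **row} for d in range(horizon)])
    return DietPlan(eb_target=float(eb_target), macro_split=tuple(split), horizon=horizon,
                    frame=frame)


def simulate_diet_response(
    model: OneStepModel,
    series,
    eb_levels=STANDARD_EB_LEVELS,
    split: tuple[float, float, float] = STANDARD_SPLIT,
    horizon: int = 7,
    baseline_B: float | None = None,
    retrain: str = "frozen",
    start_day: int | None = None,
) -> dict[float, SimulationResult]:
    """One WFS trajectory per EB level, all from the same starting state.

    Default ``retrain="frozen"``: the sweep reads out the tuned model's
    EB response without re-training on its own simulated rows (the
    retraining variant is available via ``retrain="every_step"``); every
    result records the policy used.
    """
    df = series.data if isinstance(series, UserSeries) else series
    if baseline_B is None:
        baseline_B = baseline_expenditure(df)
    T = len(df) if start_day is None else int(start_day)
    out: dict[float, SimulationResult] = {}
    for level in eb_levels:
        plan = plan_to_covariates(level, split, baseline_B, horizon=horizon + 1)
        out[float(level)] = _simulate_core(model, df, T, plan.frame, horizon, retrain)
    return out


def parabolic_delta_w(weights, days=None) -> float:
    """Weekly weight change from a parabolic fit of a trajectory.

    ``weights`` should include the day-0 anchor (last actual weight)
    followed by the simulated days; the change is the fitted polynomial
    evaluated at the last day minus the first day.
    """
    w = np.asarray(weights, dtype=float)
    if w.ndim != 1 or len(w) < 3:
        raise ValueError("parabolic fit needs at least 3 trajectory points")
    d = np.arange(len(w), dtype=float) if days is None else np.asarray(days, dtype=float)
    if len(d) != len(w):
        raise ValueError("days and weights lengths differ")
    coef = np.polyfit(d, w, deg=2)
    poly = np.poly1d(coef)
    return float(poly(d[-1]) - poly(d[0]))


@dataclass
class PlasticityFit:
    """Least-squares line ``dw = m * EB + q`` over an EB sweep."""

    m: float  # kg per kcal/day of imbalance
    q: float  # kg, weight change at EB = 0
    eb_levels: np.ndarray
    delta_w: np.ndarray
    residuals: np.ndarray = field(default=None)  # type: ignore[assignment]

    def predict(self, eb) -> np.ndarray:
        return self.m * np.asarray(eb, dtype=float) + self.q


#: Sanity band on tissue energy density: weekly kg per weekly kcal should
#: stay within ~5x the 3500 kcal/lb scale (~7700 kcal/kg).
MAX_PLAUSIBLE_KG_PER_KCAL = 5.0 / 3500.0


def fit_plasticity(eb_levels, delta_ws) -> PlasticityFit:
    """Ordinary least squares of weekly weight change on daily EB.

    Warns (without failing) when the fitted slope implies a tissue energy
    density far outside the physiological ~7700 kcal/kg scale.
    """
    eb = np.asarray(eb_levels, dtype=float)
    dw = np.asarray(delta_ws, dtype=float)
    if eb.shape != dw.shape or eb.ndim != 1:
        raise ValueError("eb_levels and delta_ws must be 1-D of equal length")
    if len(eb) < 2:
        raise ValueError("need at least 2 (EB, dw) points")
    if np.ptp(eb) == 0:
        raise np.linalg.LinAlgError("all EB levels identical: singular design")
    m, q = np.polyfit(eb, dw, deg=1)
    if abs(m) / 7.0 > MAX_PLAUSIBLE_KG_PER_KCAL:
        warnings.warn(
            f"plasticity m={m:.3g} kg/kcal implies weight change per kcal beyond "
            "the plausible tissue-energy scale; inspect the simulations",
            stacklevel=2,
        )
    fit = PlasticityFit(m=float(m), q=float(q), eb_levels=eb, delta_w=dw)
    fit.residuals = dw - fit.predict(eb)
    return fit


def extract_plasticity(
    model: OneStepModel,
    series,
    eb_levels=STANDARD_EB_LEVELS,
    split: tuple[float, float, float] = STANDARD_SPLIT,
    horizon: int = 7,
    baseline_B: float | None = None,
    retrain: str = "frozen",
) -> tuple[PlasticityFit, dict[float, SimulationResult]]:
    """EB sweep -> parabolic smoothing -> plasticity line, end to end.

    Each trajectory is anchored at the user's last actual weight before
    fitting the parabola, so the fit starts from the current state.
    """
    df = series.data if isinstance(series, UserSeries) else series
    sims = simulate_diet_response(
        model, df, eb_levels=eb_levels, split=split, horizon=horizon,
        baseline_B=baseline_B, retrain=retrain,
    )
    w0 = float(df["weight_kg"].iloc[-1])
    dws = [
        parabolic_delta_w(np.concatenate([[w0], sims[float(lv)].weights]))
        for lv in eb_levels
    ]
    return fit_plasticity(np.asarray(eb_levels, float), dws), sims
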