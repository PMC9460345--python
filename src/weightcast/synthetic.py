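"""Synthetic daily-diary generator with known metabolic ground truth.

Emulates the kind of ~300-day self-monitoring diary a single user
produces (daily weight, macronutrient grams, energy intake, resting and
activity expenditure), with the statistical features that matter for
testing the forecasting pipeline:

* latent weight follows a linear energy-partition rule
  ``w(t+1) = w(t) + (m_true / 7) * EB_true(t) + process noise``, so the
  plasticity slope of a downstream diet-response fit is exactly
  recoverable.  ``m_true`` is the *weekly* metabolic plasticity (kg of
  weekly weight change per kcal/day of sustained imbalance, the scale on
  which per-user plasticity is reported); the daily update slope is
  ``m_true / 7``.  At ``m_true = 1.5e-3`` a sustained 500 kcal/day
  surplus gains ~0.75 kg/week, i.e. ~7000 kcal per kg of tissue;
* the true daily energy balance carries a weekly cycle
  (weekend/weekday eating habits) plus day-to-day variability;
* observed energy intake is shifted by a constant reporting bias
  (chronic under/over-reporting), leaving observed EB = true EB + bias;
* observed weight adds i.i.d. measurement noise (scale repeatability);
* a small fraction of cells is missing at random (never day 0).

Macronutrient grams are derived from energy intake and the configured
energy-fraction split using densities 3.75/4/9 kcal/g, and the thermic
effect of food is accounted for by closed-form inversion, so all
generated columns are mutually consistent under the ledger equations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .energy import (
    KCAL_PER_G_CARB,
    KCAL_PER_G_LIPID,
    KCAL_PER_G_PROTEIN,
    TEF_COEF_CARB,
    TEF_COEF_LIPID,
    TEF_COEF_PROTEIN,
    UserSeries,
    VALUE_COLUMNS,
)

__all__ = ["GeneratorConfig", "GroundTruth", "generate_user_series", "tef_denominator"]


def tef_denominator(macro_split: tuple[float, float, float]) -> float:
    """``1 - 0.095*p_c - 0.015*p_l - 0.25*p_p`` for energy fractions
    ``(p_c, p_p, p_l)``: the factor converting net-of-TEF energy into
    gross intake, shared with the diet-plan inversion."""
    p_c, p_p, p_l = macro_split
    return 1.0 - TEF_COEF_CARB * p_c - TEF_COEF_LIPID * p_l - TEF_COEF_PROTEIN * p_p


@dataclass
class GeneratorConfig:
    """Study conditions for one synthetic user.

    Defaults emulate a weight-stable adult logging for ~11 months:
    330 days, mean energy balance 0 kcal/day with 300 kcal/day scatter and
    a ±150 kcal weekly cycle, plasticity 1.5e-3 kg/kcal (mid-range of
    observed per-user values, 0.3-2.0e-3), scale repeatability 0.15 kg,
    physiological day-to-day weight drift 0.05 kg, 1% missing cells.
    """

    n_days: int = 330
    w0: float = 75.0
    m_true: float = 1.5e-3  # weekly plasticity, kg per kcal/day of imbalance
    bias_kcal: float = 0.0
    baseline_B: float = 2000.0
    eb_mean: float = 0.0
    eb_sd: float = 300.0
    macro_split: tuple[float, float, float] = (0.5, 0.2, 0.3)
    weekday_amplitude: float = 150.0
    weight_noise_sd: float = 0.15
    process_noise_sd: float = 0.05
    missing_frac: float = 0.01
    rmr_fraction: float = 0.85
    tea_sd: float = 50.0
    start_date: str = "2023-01-02"  # a Monday: seasonal phase 0 on day 0
    seed: int = 0
    nonlinear_saturation: float = 0.0  # kcal scale of optional tanh saturation; 0 = linear

    def validate(self) -> None:
        problems = []
        if self.n_days < 30:
            problems.append(f"n_days must be >= 30 (got {self.n_days})")
        if not (0.0 <= self.missing_frac <= 0.03):
            problems.append(f"missing_frac must be in [0, 0.03] (got {self.missing_frac})")
        if abs(sum(self.macro_split) - 1.0) > 1e-9:
            problems.append(f"macro_split must sum to 1 (got {self.macro_split})")
        if any(p < 0 for p in self.macro_split):
            problems.append("macro_split fractions must be non-negative")
        if self.w0 <= 0:
            problems.append("w0 must be positive")
        if self.eb_sd < 0 or self.weight_noise_sd < 0 or self.process_noise_sd < 0:
            problems.append("noise scales must be non-negative")
        if problems:
            raise ValueError("invalid GeneratorConfig: " + "; ".join(problems))

    @property
    def daily_slope(self) -> float:
        """Latent per-day weight response, kg per kcal: ``m_true / 7``."""
        return self.m_true / 7.0


@dataclass
class GroundTruth:
    """Hidden state of a generated user (sidecar, never fed to models)."""

    m_true: float
    bias_kcal: float
    latent_weight: np.ndarray
    eb_true: np.ndarray
    baseline_B: float

    def to_frame(self) -> pd.DataFrame:
        n = len(self.latent_weight)
        return pd.DataFrame(
            {
                "t": np.arange(n),
                "latent_weight_kg": self.latent_weight,
                "eb_true_kcal": np.append(self.eb_true, np.nan)[:n]
                if len(self.eb_true) < n
                else self.eb_true[:n],
                "m_true": self.m_true,
                "m_daily": self.m_true / 7.0,
                "bias_kcal": self.bias_kcal,
            }
        )


def generate_user_series(
    config: GeneratorConfig, user_id: str | None = None
) -> tuple[UserSeries, GroundTruth]:
    """Generate one user's observable diary plus its hidden ground truth.

    Identical config (including seed) yields byte-identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_days
    t = np.arange(n)

    # True daily energy balance: weekly cycle + i.i.d. scatter.
    level = config.eb_mean + config.weekday_amplitude * np.cos(2.0 * np.pi * t / 7.0)
    eb_true = level + rng.normal(0.0, config.eb_sd, size=n)

    # Latent weight: linear energy partition (optionally saturating).
    latent = np.empty(n)
    latent[0] = config.w0
    proc = rng.normal(0.0, config.process_noise_sd, size=n - 1) if n > 1 else np.empty(0)
    for i in range(n - 1):
        drive = eb_true[i]
        if config.nonlinear_saturation > 0:
            s = config.nonlinear_saturation
            drive = s * np.tanh(drive / s)
        latent[i + 1] = latent[i] + config.daily_slope * drive + proc[i]

    # Non-food expenditure split into a constant RMR and variable activity.
    rmr = np.full(n, config.rmr_fraction * config.baseline_B)
    tea = (1.0 - config.rmr_fraction) * config.baseline_B + rng.normal(
        0.0, config.tea_sd, size=n
    )
    tea = np.clip(tea, 0.0, None)
    B = rmr + tea

    # Invert the ledger: gross intake that realizes eb_true given TEF.
    denom = tef_denominator(config.macro_split)
    ei_true = (eb_true + B) / denom
    ei_true = np.clip(ei_true, 0.0, None)
    p_c, p_p, p_l = config.macro_split
    carb = p_c * ei_true / KCAL_PER_G_CARB
    prot = p_p * ei_true / KCAL_PER_G_PROTEIN
    lip = p_l * ei_true / KCAL_PER_G_LIPID

    # Observation layer: reporting bias on intake, measurement noise on weight.
    ei_obs = ei_true + config.bias_kcal
    w_obs = latent + rng.normal(0.0, config.weight_noise_sd, size=n)

    df = pd.DataFrame(
        {
            "date": pd.date_range(config.start_date, periods=n, freq="D"),
            "weight_kg": w_obs,
            "carb_g": carb,
            "protein_g": prot,
            "lipid_g": lip,
            "energy_intake_kcal": ei_obs,
            "rmr_kcal": rmr,
            "tea_kcal": tea,
        }
    )

    if config.missing_frac > 0:
        mask = rng.random((n, len(VALUE_COLUMNS))) < config.missing_frac
        mask[0, :] = False  # day 0 must stay observed (pad imputation anchor)
        for j, c in enumerate(VALUE_COLUMNS):
            df.loc[mask[:, j], c] = np.nan

    uid = user_id if user_id is not None else f"synth-{config.seed}"
    series = UserSeries(user_id=uid, data=df)
    truth = GroundTruth(
        m_true=config.m_true,
        bias_kcal=config.bias_kcal,
        latent_weight=latent,
        eb_true=eb_true,
        baseline_B=float(B.mean()),
    )
    return series, truth
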