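"""Daily energy-balance accounting and series preparation.

The daily ledger decomposes energy flux as

    EB  = EI - TEE                  (energy balance, kcal/day)
    TEE = RMR + TEA + TEF           (total energy expenditure)
    TEF = 0.095*(m_C*3.75) + 0.015*(m_L*9) + 0.25*(m_P*4)

where ``m_C``, ``m_P``, ``m_L`` are daily carbohydrate / protein / lipid
masses in grams and the energy densities are 3.75, 4 and 9 kcal/g.  The
thermic effect of food (TEF) is the energy cost of digesting and storing
each macronutrient class, a fixed linear function of intake masses.

Besides the arithmetic, this module prepares a raw daily diary for
modelling: forward-fill ("pad") imputation of sparse gaps, correction of
systematic energy-intake misreporting via a weekly regression
``EB_week = a * dw_week + b`` (the intercept ``b`` is the mean daily
reporting bias and is subtracted from daily EB), and day-of-week harmonic
features ``cos(2*pi*t/7)``, ``sin(2*pi*t/7)``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "KCAL_PER_G_CARB",
    "KCAL_PER_G_PROTEIN",
    "KCAL_PER_G_LIPID",
    "TEF_COEF_CARB",
    "TEF_COEF_PROTEIN",
    "TEF_COEF_LIPID",
    "VALUE_COLUMNS",
    "UserSeries",
    "BiasFit",
    "MissingFieldError",
    "compute_tef",
    "compute_energy_balance",
    "impute_pad",
    "fit_eb_bias",
    "apply_eb_bias_correction",
    "add_seasonal_features",
    "read_daily_csv",
    "write_daily_csv",
]

# Energy densities (kcal per gram) and TEF fractions per macronutrient class.
KCAL_PER_G_CARB = 3.75
KCAL_PER_G_PROTEIN = 4.0
KCAL_PER_G_LIPID = 9.0
TEF_COEF_CARB = 0.095
TEF_COEF_PROTEIN = 0.25
TEF_COEF_LIPID = 0.015

#: Observable diary columns, in canonical order.
VALUE_COLUMNS = [
    "weight_kg",
    "carb_g",
    "protein_g",
    "lipid_g",
    "energy_intake_kcal",
    "rmr_kcal",
    "tea_kcal",
]

DERIVED_COLUMNS = ["tef_kcal", "tee_kcal", "eb_kcal", "week_cos", "week_sin"]


class MissingFieldError(ValueError):
    """A required diary field is absent where the computation needs it."""


@dataclass
class BiasFit:
    """Weekly regression ``EB_week = a * dw_week + b``.

    ``b`` is the mean daily bias of the reported energy balance in kcal/day
    (chronic misreporting shifts every weekly mean by the same amount while
    weight responds only to the true balance, so the intercept isolates it);
    ``a`` is in kcal/day per kg of weekly weight change.
    """

    a: float
    b: float
    n_weeks: int
    r_squared: float

    def __post_init__(self) -> None:
        if self.n_weeks < 2:
            raise ValueError("BiasFit requires at least 2 weekly points")


@dataclass
class UserSeries:
    """One user's daily diary, indexed by day ``t = 0..n-1``.

    ``data`` holds one row per day with the columns of
    :data:`VALUE_COLUMNS` plus derived columns once computed.
    ``provenance`` mirrors the observable columns cell-by-cell with values
    ``"observed"`` / ``"missing"`` / ``"imputed"``.
    """

    user_id: str
    data: pd.DataFrame
    provenance: pd.DataFrame = field(default=None)  # type: ignore[assignment]
    bias_corrected: bool = False

    def __post_init__(self) -> None:
        if len(self.data) < 1:
            raise ValueError("UserSeries must contain at least one day")
        self.data = self.data.reset_index(drop=True)
        if "date" in self.data.columns:
            dates = pd.to_datetime(self.data["date"])
            deltas = dates.diff().dropna().dt.days
            if len(deltas) and not (deltas == 1).all():
                raise ValueError("day indices must increase by exactly 1 (no gaps)")
            self.data["date"] = dates
        if self.provenance is None:
            cols = [c for c in VALUE_COLUMNS if c in self.data.columns]
            prov = pd.DataFrame("observed", index=self.data.index, columns=cols)
            for c in cols:
                prov.loc[self.data[c].isna(), c] = "missing"
            self.provenance = prov

    def __len__(self) -> int:
        return len(self.data)

    def copy(self) -> "UserSeries":
        return UserSeries(
            user_id=self.user_id,
            data=self.data.copy(),
            provenance=self.provenance.copy(),
            bias_corrected=self.bias_corrected,
        )

    @property
    def t(self) -> np.ndarray:
        """0-based day index."""
        return np.arange(len(self.data))


def compute_tef(m_c: float, m_p: float, m_l: float) -> float:
    """Thermic effect of food in kcal for one day's macronutrient masses.

    Parameters
    ----------
    m_c, m_p, m_l : float
        Carbohydrate, protein and lipid intake in grams.
    """
    m_c, m_p, m_l = float(m_c), float(m_p), float(m_l)
    if m_c < 0 or m_p < 0 or m_l < 0:
        raise ValueError("macronutrient masses must be non-negative")
    return (
        TEF_COEF_CARB * (m_c * KCAL_PER_G_CARB)
        + TEF_COEF_LIPID * (m_l * KCAL_PER_G_LIPID)
        + TEF_COEF_PROTEIN * (m_p * KCAL_PER_G_PROTEIN)
    )


def _tef_array(m_c: np.ndarray, m_p: np.ndarray, m_l: np.ndarray) -> np.ndarray:
    return (
        TEF_COEF_CARB * (m_c * KCAL_PER_G_CARB)
        + TEF_COEF_LIPID * (m_l * KCAL_PER_G_LIPID)
        + TEF_COEF_PROTEIN * (m_p * KCAL_PER_G_PROTEIN)
    )


def compute_energy_balance(series: UserSeries) -> UserSeries:
    """Fill ``tef_kcal``, ``tee_kcal`` and ``eb_kcal`` from components.

    If the input CSV supplied ``eb_kcal`` directly it is left untouched.
    Raises :class:`MissingFieldError` if any required component contains
    missing values (imputation is a separate, explicit step).
    """
    out = series.copy()
    df = out.data
    if "eb_kcal" in df.columns and not df["eb_kcal"].isna().any():
        return out
    required = ["energy_intake_kcal", "rmr_kcal", "tea_kcal", "carb_g", "protein_g", "lipid_g"]
    for col in required:
        if col not in df.columns:
            raise MissingFieldError(f"column {col!r} is required to compute energy balance")
        if df[col].isna().any():
            day = int(df.index[df[col].isna()][0])
            raise MissingFieldError(f"missing {col!r} on day {day}; impute before computing EB")
    if (df[["carb_g", "protein_g", "lipid_g"]].to_numpy() < 0).any():
        raise ValueError("macronutrient masses must be non-negative")
    df["tef_kcal"] = _tef_array(
        df["carb_g"].to_numpy(), df["protein_g"].to_numpy(), df["lipid_g"].to_numpy()
    )
    df["tee_kcal"] = df["rmr_kcal"] + df["tea_kcal"] + df["tef_kcal"]
    df["eb_kcal"] = df["energy_intake_kcal"] - df["tee_kcal"]
    return out


def impute_pad(
    series: UserSeries, segment_boundary: int | None = None, strict: bool = True
) -> UserSeries:
    """Forward-fill missing diary cells from the previous day.

    ``segment_boundary`` splits the series into a training segment
    ``[0, boundary)`` and a test segment ``[boundary, n)`` that are imputed
    independently, so no training value leaks forward into the test segment's
    first days and vice versa.  A missing value at a segment start (no
    predecessor within the segment) is an error; with ``strict=False`` a
    missing *test*-segment start is seeded from the last observation before
    the boundary instead (the causally available value at deployment) —
    only the series start has no fallback.
    """
    out = series.copy()
    cols = [c for c in VALUE_COLUMNS if c in out.data.columns]
    n = len(out)
    boundaries = [0, n] if segment_boundary is None else [0, int(segment_boundary), n]
    if segment_boundary is not None and not (0 < segment_boundary < n):
        raise ValueError(f"segment_boundary must be in (0, {n})")
    for lo, hi in zip(boundaries[:-1], boundaries[1:]):
        seg = out.data.loc[lo : hi - 1, cols]
        for c in cols:
            if pd.isna(seg[c].iloc[0]):
                if strict or lo == 0:
                    raise ValueError(
                        f"field {c!r} is missing on day {lo} with no predecessor in its segment"
                    )
                seg.loc[lo, c] = out.data.loc[lo - 1, c]
        filled = seg.ffill()
        was_missing = out.data.loc[lo : hi - 1, cols].isna()
        out.data.loc[lo : hi - 1, cols] = filled
        for c in cols:
            idx = was_missing.index[was_missing[c]]
            out.provenance.loc[idx, c] = "imputed"
    return out


def fit_eb_bias(
    series: UserSeries,
    end_day: int | None = None,
    stride: int = 7,
) -> BiasFit:
    """Regress weekly energy balance on weekly weight change.

    For each admissible day ``t`` (multiples of ``stride`` by default, i.e.
    non-overlapping weeks), the weekly point is

        EB_week(t) = mean(EB(t-6 .. t))          [kcal/day]
        dw_week(t) = w(t) - w(t-7)               [kg]

    and the least-squares line ``EB_week = a * dw_week + b`` is returned.
    ``end_day`` restricts the fit to days ``< end_day`` (the training
    segment).  Requires at least two weekly points (15 days).
    """
    df = series.data if end_day is None else series.data.iloc[:end_day]
    if "eb_kcal" not in df.columns or df["eb_kcal"].isna().any():
        raise MissingFieldError("eb_kcal must be computed and complete before fitting bias")
    if df["weight_kg"].isna().any():
        raise MissingFieldError("weight_kg must be complete before fitting bias")
    n = len(df)
    if n < 15:
        raise ValueError(f"need >= 15 days of contiguous EB and weight data, got {n}")
    eb = df["eb_kcal"].to_numpy(float)
    w = df["weight_kg"].to_numpy(float)
    ts = np.arange(7, n, stride)
    eb_week = np.array([eb[t - 6 : t + 1].mean() for t in ts])
    dw_week = np.array([w[t] - w[t - 7] for t in ts])
    if len(ts) < 2:
        raise ValueError("insufficient span for weekly regression (need >= 2 weekly points)")
    res = stats.linregress(dw_week, eb_week)
    return BiasFit(a=float(res.slope), b=float(res.intercept), n_weeks=len(ts),
                   r_squared=float(res.rvalue) ** 2)


def apply_eb_bias_correction(series: UserSeries, fit: BiasFit) -> UserSeries:
    """Subtract the mean daily reporting bias ``fit.b`` from every day's EB.

    Guarded against double application: re-applying to an already corrected
    series raises, since that would shift EB by ``2b``.
    """
    if series.bias_corrected:
        raise ValueError("series is already bias-corrected; refusing to re-apply")
    out = series.copy()
    out.data["eb_kcal"] = out.data["eb_kcal"] - fit.b
    out.bias_corrected = True
    return out


def add_seasonal_features(series: UserSeries, anchor_weekday: bool = True) -> UserSeries:
    """Attach weekly harmonics ``week_cos``/``week_sin`` with period 7 days.

    With ``anchor_weekday`` (default) and a ``date`` column present, the
    phase is shifted so the harmonics encode the calendar day of week
    (Monday -> phase 0); otherwise phase 0 falls on the first record.
    """
    out = series.copy()
    t = out.t.astype(float)
    if anchor_weekday and "date" in out.data.columns:
        t = t + pd.to_datetime(out.data["date"].iloc[0]).weekday()
    out.data["week_cos"] = np.cos(2.0 * np.pi * t / 7.0)
    out.data["week_sin"] = np.sin(2.0 * np.pi * t / 7.0)
    return out


def read_daily_csv(path, user_id: str | None = None) -> UserSeries:
    """Read a daily diary CSV (one row per day, empty cell = missing).

    Expected columns: ``date`` plus any of :data:`VALUE_COLUMNS`;
    ``eb_kcal`` may be supplied precomputed, in which case the component
    columns are optional.  Days absent from the file are inserted as fully
    missing rows so the day index is gapless.
    """
    df = pd.read_csv(path)
    if "date" in df.columns:
        df["date"] = pd.to_datetime(df["date"])
        full = pd.date_range(df["date"].iloc[0], df["date"].iloc[-1], freq="D")
        df = df.set_index("date").reindex(full).rename_axis("date").reset_index()
    uid = user_id if user_id is not None else str(getattr(path, "stem", path))
    return UserSeries(user_id=uid, data=df)


def write_daily_csv(series: UserSeries, path) -> None:
    """Write the diary plus derived and provenance columns."""
    df = series.data.copy()
    for c in series.provenance.columns:
        df[f"{c}_src"] = series.provenance[c]
    if series.bias_corrected and "eb_kcal" in df.columns:
        df["eb_kcal_src"] = "bias-corrected"
    df.to_csv(path, index=False)


def prepare_series(
    series: UserSeries,
    train_days: int,
    anchor_weekday: bool = True,
    correct_bias: bool = True,
) -> tuple[UserSeries, BiasFit | None]:
    """Standard preprocessing: impute per segment, compute EB, correct
    reporting bias (fit on the training segment only), attach seasonal
    features.  Returns the prepared series and the bias fit (``None`` when
    ``correct_bias`` is off)."""
    s = impute_pad(series, segment_boundary=train_days, strict=False)
    s = compute_energy_balance(s)
    fit = None
    if correct_bias:
        fit = fit_eb_bias(s, end_day=train_days)
        s = apply_eb_bias_correction(s, fit)
    s = add_seasonal_features(s, anchor_weekday=anchor_weekday)
    return s, fit
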