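"""Energy-ledger arithmetic, imputation, bias correction, seasonality."""

import numpy as np
import pandas as pd
import pytest

from weightcast.energy import (
    BiasFit,
    MissingFieldError,
    UserSeries,
    add_seasonal_features,
    apply_eb_bias_correction,
    compute_energy_balance,
    compute_tef,
    fit_eb_bias,
    impute_pad,
    read_daily_csv,
    write_daily_csv,
)
from weightcast.synthetic import GeneratorConfig, generate_user_series


def make_series(**cols):
    n = len(next(iter(cols.values())))
    base = {
        "weight_kg": [70.0] * n,
        "carb_g": [200.0] * n,
        "protein_g": [80.0] * n,
        "lipid_g": [60.0] * n,
        "energy_intake_kcal": [2000.0] * n,
        "rmr_kcal": [1700.0] * n,
        "tea_kcal": [300.0] * n,
    }
    base.update(cols)
    return UserSeries(user_id="u", data=pd.DataFrame(base))


class TestTEF:
    @pytest.mark.parametrize(
        "mc,mp,ml,expected",
        [
            (0, 0, 0, 0.0),
            (100, 0, 0, 35.625),
            (250, 100, 70, 198.5125),
        ],
    )
    def test_known_values(self, mc, mp, ml, expected):
        assert compute_tef(mc, mp, ml) == pytest.approx(expected, abs=1e-9)

    def test_negative_mass_rejected(self):
        with pytest.raises(ValueError):
            compute_tef(-1, 0, 0)

    def test_matches_componentwise_arithmetic(self):
        # independent oracle: each macronutrient term computed separately
        rng = np.random.default_rng(0)
        for _ in range(100):
            mc, mp, ml = rng.uniform(0, 500, 3)
            expected = 0.095 * mc * 3.75
            expected += 0.25 * mp * 4.0
            expected += 0.015 * ml * 9.0
            assert compute_tef(mc, mp, ml) == pytest.approx(expected, abs=1e-9)


class TestEnergyBalance:
    def test_balanced_day(self):
        s = make_series(energy_intake_kcal=[2000.0], rmr_kcal=[2000.0], tea_kcal=[0.0],
                        carb_g=[0.0], protein_g=[0.0], lipid_g=[0.0])
        out = compute_energy_balance(s)
        assert out.data["eb_kcal"].iloc[0] == pytest.approx(0.0)

    def test_deficit_day_hand_arithmetic(self):
        s = make_series(energy_intake_kcal=[1800.0], rmr_kcal=[1600.0], tea_kcal=[250.0],
                        carb_g=[250.0], protein_g=[100.0], lipid_g=[70.0])
        out = compute_energy_balance(s)
        assert out.data["eb_kcal"].iloc[0] == pytest.approx(-248.5125, abs=1e-9)
        assert out.data["tee_kcal"].iloc[0] == pytest.approx(1600 + 250 + 198.5125, abs=1e-9)

    def test_missing_component_is_explicit_error(self):
        s = make_series(energy_intake_kcal=[2000.0, np.nan])
        with pytest.raises(MissingFieldError, match="energy_intake_kcal"):
            compute_energy_balance(s)

    def test_identities_on_random_inputs(self):
        rng = np.random.default_rng(1)
        n = 100
        s = make_series(
            weight_kg=rng.uniform(50, 100, n),
            carb_g=rng.uniform(0, 400, n),
            protein_g=rng.uniform(0, 200, n),
            lipid_g=rng.uniform(0, 150, n),
            energy_intake_kcal=rng.uniform(1000, 3500, n),
            rmr_kcal=rng.uniform(1200, 2000, n),
            tea_kcal=rng.uniform(0, 800, n),
        )
        out = compute_energy_balance(s).data
        tee = out["rmr_kcal"] + out["tea_kcal"] + out["tef_kcal"]
        assert np.allclose(out["tee_kcal"], tee, atol=1e-9)
        assert np.allclose(out["eb_kcal"], out["energy_intake_kcal"] - tee, atol=1e-9)

    def test_precomputed_eb_passthrough(self):
        df = pd.DataFrame({"weight_kg": [70.0, 70.2], "eb_kcal": [100.0, -50.0]})
        out = compute_energy_balance(UserSeries("u", df))
        assert list(out.data["eb_kcal"]) == [100.0, -50.0]


class TestImputation:
    def test_pad_semantics(self):
        s = make_series(weight_kg=[70.0, np.nan, np.nan])
        out = impute_pad(s)
        assert list(out.data["weight_kg"]) == [70.0, 70.0, 70.0]
        assert list(out.provenance["weight_kg"]) == ["observed", "imputed", "imputed"]

    def test_fully_observed_unchanged(self):
        s = make_series(weight_kg=[70.0, 71.0, 72.0])
        out = impute_pad(s)
        pd.testing.assert_frame_equal(out.data, s.data)

    def test_no_predecessor_is_error(self):
        s = make_series(weight_kg=[np.nan, 70.0])
        with pytest.raises(ValueError, match="weight_kg"):
            impute_pad(s)

    def test_segments_imputed_independently(self):
        s = make_series(weight_kg=[70.0, np.nan, np.nan, 71.0, np.nan, np.nan])
        out = impute_pad(s, segment_boundary=3)
        assert list(out.data["weight_kg"]) == [70.0, 70.0, 70.0, 71.0, 71.0, 71.0]
        # strict: missing at test-segment start must not be filled from train
        s2 = make_series(weight_kg=[70.0, 70.5, np.nan, np.nan, 71.0, 71.5])
        with pytest.raises(ValueError):
            impute_pad(s2, segment_boundary=2)
        # non-strict: seeded from last pre-boundary observation
        out2 = impute_pad(s2, segment_boundary=2, strict=False)
        assert list(out2.data["weight_kg"]) == [70.0, 70.5, 70.5, 70.5, 71.0, 71.5]

    def test_observed_values_never_altered(self):
        series, _ = generate_user_series(GeneratorConfig(seed=4, missing_frac=0.03))
        out = impute_pad(series, segment_boundary=300, strict=False)
        for c in out.provenance.columns:
            obs = series.provenance[c] == "observed"
            assert np.array_equal(
                out.data.loc[obs, c].to_numpy(), series.data.loc[obs, c].to_numpy()
            )


class TestBiasRegression:
    def test_short_series_rejected(self):
        s = compute_energy_balance(make_series(weight_kg=[70.0] * 10))
        with pytest.raises(ValueError):
            fit_eb_bias(s)

    def test_known_bias_recovered(self):
        # weight responds to true EB; reported EB carries +300 kcal/day
        series, _ = generate_user_series(GeneratorConfig(seed=0, bias_kcal=300.0, missing_frac=0.0))
        s = compute_energy_balance(series)
        fit = fit_eb_bias(s, end_day=323)
        assert fit.b == pytest.approx(300.0, abs=30.0)
        assert fit.n_weeks >= 2

    def test_null_bias(self):
        series, _ = generate_user_series(GeneratorConfig(seed=0, bias_kcal=0.0, missing_frac=0.0))
        s = compute_energy_balance(series)
        assert abs(fit_eb_bias(s, end_day=323).b) < 30.0

    def test_correction_subtracts_b(self):
        s = compute_energy_balance(make_series(weight_kg=[70.0, 70.1]))
        s.data["eb_kcal"] = [100.0, -50.0]
        out = apply_eb_bias_correction(s, BiasFit(a=0.0, b=300.0, n_weeks=5, r_squared=0.5))
        assert list(out.data["eb_kcal"]) == [-200.0, -350.0]

    def test_zero_bias_identity(self):
        s = compute_energy_balance(make_series(weight_kg=[70.0, 70.1]))
        out = apply_eb_bias_correction(s, BiasFit(a=0.0, b=0.0, n_weeks=5, r_squared=0.5))
        assert np.array_equal(out.data["eb_kcal"], s.data["eb_kcal"])

    def test_reapplication_guarded(self):
        s = compute_energy_balance(make_series(weight_kg=[70.0, 70.1]))
        fit = BiasFit(a=0.0, b=300.0, n_weeks=5, r_squared=0.5)
        out = apply_eb_bias_correction(s, fit)
        with pytest.raises(ValueError, match="already"):
            apply_eb_bias_correction(out, fit)

    def test_daily_differences_preserved(self):
        series, _ = generate_user_series(GeneratorConfig(seed=2, missing_frac=0.0))
        s = compute_energy_balance(series)
        fit = fit_eb_bias(s)
        out = apply_eb_bias_correction(s, fit)
        assert np.allclose(
            np.diff(out.data["eb_kcal"]), np.diff(s.data["eb_kcal"]), atol=1e-12
        )


class TestSeasonalFeatures:
    def test_phase_and_period(self):
        s = make_series(weight_kg=[70.0] * 15)
        out = add_seasonal_features(s, anchor_weekday=False)
        assert out.data["week_cos"].iloc[0] == pytest.approx(1.0, abs=1e-12)
        assert out.data["week_sin"].iloc[0] == pytest.approx(0.0, abs=1e-12)
        assert out.data["week_cos"].iloc[7] == pytest.approx(1.0, abs=1e-12)
        assert out.data["week_sin"].iloc[7] == pytest.approx(0.0, abs=1e-12)
        assert out.data["week_cos"].iloc[14] == pytest.approx(1.0, abs=1e-12)

    def test_unit_circle(self):
        s = make_series(weight_kg=[70.0] * 30)
        out = add_seasonal_features(s, anchor_weekday=False)
        norm = out.data["week_cos"] ** 2 + out.data["week_sin"] ** 2
        assert np.allclose(norm, 1.0, atol=1e-9)

    def test_weekday_anchor(self):
        df = pd.DataFrame(
            {"date": pd.date_range("2023-01-04", periods=8), "weight_kg": [70.0] * 8}
        )  # starts on a Wednesday (weekday 2)
        out = add_seasonal_features(UserSeries("u", df))
        assert out.data["week_cos"].iloc[0] == pytest.approx(np.cos(2 * np.pi * 2 / 7))


class TestCSVRoundTrip:
    def test_round_trip_and_gap_filling(self, tmp_path):
        df = pd.DataFrame(
            {
                "date": ["2023-01-02", "2023-01-03", "2023-01-05"],
                "weight_kg": [70.0, 70.5, 70.2],
                "carb_g": [200.0, None, 190.0],
                "protein_g": [80.0, 85.0, 80.0],
                "lipid_g": [60.0, 65.0, 60.0],
                "energy_intake_kcal": [2000.0, 2100.0, 1900.0],
                "rmr_kcal": [1700.0] * 3,
                "tea_kcal": [300.0] * 3,
            }
        )
        p = tmp_path / "diary.csv"
        df.to_csv(p, index=False)
        series = read_daily_csv(p, user_id="u")
        assert len(series) == 4  # missing calendar day inserted
        assert series.data["weight_kg"].isna().iloc[2]
        out = impute_pad(series)
        out = compute_energy_balance(out)
        write_daily_csv(out, tmp_path / "out.csv")
        back = pd.read_csv(tmp_path / "out.csv")
        assert "eb_kcal" in back.columns and "weight_kg_src" in back.columns
        assert back["weight_kg_src"].iloc[2] == "imputed"

    def test_gapless_invariant(self):
        df = pd.DataFrame({"date": ["2023-01-01", "2023-01-03"], "weight_kg": [70.0, 70.1]})
        with pytest.raises(ValueError, match="no gaps"):
            UserSeries("u", df)
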