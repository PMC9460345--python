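import numpy as np
import pandas as pd
import pytest

from weightcast import GeneratorConfig, generate_user_series
from weightcast.energy import prepare_series


@pytest.fixture(scope="session")
def std_user():
    """330-day default-conditions user (weekly plasticity 1.5e-3 kg/kcal)."""
    series, truth = generate_user_series(GeneratorConfig(seed=1))
    return series, truth


@pytest.fixture(scope="session")
def prepared_std(std_user):
    series, truth = std_user
    prepared, bias = prepare_series(series, train_days=len(series) - 7)
    return prepared, truth


@pytest.fixture(scope="session")
def noise_free_user():
    """Short fully deterministic user: weight is an exact function of EB."""
    cfg = GeneratorConfig(
        seed=3, n_days=120, eb_sd=250, weight_noise_sd=0.0, process_noise_sd=0.0,
        missing_frac=0.0, tea_sd=0.0,
    )
    series, truth = generate_user_series(cfg)
    prepared, _ = prepare_series(series, train_days=len(series) - 7, correct_bias=False)
    return prepared, truth


def make_plain_frame(n, w0=70.0, eb=0.0, seed=0, noise=0.0):
    """Minimal prepared feature frame with constant covariates."""
    rng = np.random.default_rng(seed)
    w = w0 + noise * rng.normal(size=n)
    t = np.arange(n)
    return pd.DataFrame(
        {
            "eb_kcal": np.full(n, float(eb)),
            "carb_g": np.full(n, 250.0),
            "protein_g": np.full(n, 100.0),
            "lipid_g": np.full(n, 70.0),
            "weight_kg": w,
            "rmr_kcal": np.full(n, 1700.0),
            "tea_kcal": np.full(n, 300.0),
            "week_cos": np.cos(2 * np.pi * t / 7),
            "week_sin": np.sin(2 * np.pi * t / 7),
        }
    )
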