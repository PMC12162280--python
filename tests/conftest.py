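import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from mksvrb import GeneratorConfig, generate_cohort
from mksvrb.cohort import Cohort, bcs_schema

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


def toy_frame() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "age_group": ["<=50", ">50", "<=50", ">50"],
            "occupation": ["others", "farmer_or_worker", "others", "farmer_or_worker"],
            "bcs_type": ["inferior_vena_cava", "hepatic_vein", "mixed", "inferior_vena_cava"],
            "intervention": [
                "balloon_dilation",
                "stent_implantation",
                "catheter_thrombolysis",
                "tips",
            ],
            "NEU": [3.2, 4.1, 5.0, 2.8],
            "PLT": [150.0, 210.0, 180.0, 120.0],
            "PT": [12.5, 13.1, 14.0, 12.0],
            "ALB": [40.0, 35.5, 38.0, 42.0],
            "GLU": [5.1, 6.0, 5.5, 4.9],
            "AFP": [6.0, 9.5, 7.2, 5.8],
        }
    )


@pytest.fixture
def toy_cohort() -> Cohort:
    return Cohort(toy_frame(), np.array([1, -1, 1, -1]), bcs_schema())


@pytest.fixture(scope="session")
def small_cohort() -> Cohort:
    """A 200-patient synthetic cohort with the default study conditions."""
    return generate_cohort(GeneratorConfig(n=200, seed=7))


def strong_signal_config(n: int = 522, seed: int = 0) -> GeneratorConfig:
    """Study conditions with tripled log-odds: a clearly learnable signal.

    The published effect sizes are modest; tripling them on the log-odds scale
    gives a cohort where a working classifier must reach a clearly
    above-chance AUC, which is what the end-to-end smoke checks need.
    """
    base = GeneratorConfig(n=n, seed=seed)
    return GeneratorConfig(
        n=n,
        seed=seed,
        log_odds={k: 3.0 * v for k, v in base.log_odds.items()},
    )


@pytest.fixture
def separable_xy() -> tuple[np.ndarray, np.ndarray]:
    """1-D linearly separable toy: positives near +1, negatives near -1."""
    rng = np.random.default_rng(42)
    x = np.concatenate([1.0 + 0.1 * rng.standard_normal(10), -1.0 + 0.1 * rng.standard_normal(10)])
    y = np.array([1] * 10 + [-1] * 10)
    return x[:, None], y
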