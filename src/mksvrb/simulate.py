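"""Seeded synthetic Budd-Chiari-style cohort generator.

The private hospital cohort behind the study schema is not publicly available,
so every downstream stage is exercised on cohorts drawn from a generator with
the statistical structure the analysis assumes: categorical covariates drawn
from configurable multinomials, Gaussian laboratory values with a deliberate
NEU-PLT correlation (so the collinearity filter has a true positive to find),
and a Bernoulli outcome from a logistic model whose default coefficients are
the natural logs of the published multivariate odds ratios.  The intercept is
calibrated by Monte-Carlo root finding so realized prevalence matches the
study's 169/522 relapse fraction.

Category probabilities and laboratory means/sds are configuration defaults
chosen as clinically plausible placeholders, not estimates of the source data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .cohort import Cohort, bcs_schema

# Natural logs of the published multivariate odds ratios; keys are encoded
# covariate names (categorical "column=level", continuous per natural unit).
DEFAULT_LOG_ODDS: dict[str, float] = {
    "age_group=>50": math.log(0.419),
    "intervention=stent_implantation": math.log(0.419),
    "intervention=catheter_thrombolysis": math.log(2.57),
    "intervention=tips": math.log(0.809),
    "NEU": math.log(1.197),
    "ALB": math.log(0.967),
    "AFP": math.log(0.92),
}

DEFAULT_PREVALENCE = 169 / 522


class ConfigError(ValueError):
    """Invalid generator configuration."""


def _default_category_probs() -> dict[str, dict[str, float]]:
    return {
        "age_group": {"<=50": 0.5, ">50": 0.5},
        "occupation": {"others": 0.4, "farmer_or_worker": 0.6},
        "bcs_type": {"inferior_vena_cava": 0.45, "hepatic_vein": 0.35, "mixed": 0.20},
        "intervention": {
            "balloon_dilation": 0.55,
            "stent_implantation": 0.15,
            "catheter_thrombolysis": 0.20,
            "tips": 0.10,
        },
    }


def _default_lab_means() -> dict[str, float]:
    return {"NEU": 4.2, "PLT": 180.0, "PT": 13.5, "ALB": 38.0, "GLU": 5.6, "AFP": 8.0}


def _default_lab_sds() -> dict[str, float]:
    return {"NEU": 1.8, "PLT": 60.0, "PT": 2.5, "ALB": 5.0, "GLU": 1.4, "AFP": 4.0}


@dataclass
class GeneratorConfig:
    """Full description of one synthetic cohort draw.

    ``log_odds`` maps encoded covariate names to logistic coefficients on the
    natural covariate scale; any covariate not listed has coefficient zero.
    ``intercept`` overrides calibration when set (used e.g. to study how a
    single coefficient shifts prevalence with everything else fixed).
    """

    n: int = 522
    category_probs: dict[str, dict[str, float]] = field(default_factory=_default_category_probs)
    lab_means: dict[str, float] = field(default_factory=_default_lab_means)
    lab_sds: dict[str, float] = field(default_factory=_default_lab_sds)
    neu_plt_correlation: float = 0.8
    log_odds: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_LOG_ODDS))
    target_prevalence: float = DEFAULT_PREVALENCE
    afp_lognormal: bool = False
    intercept: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ConfigError("cohort size n must be >= 2")
        if not -1.0 < self.neu_plt_correlation < 1.0:
            raise ConfigError("|neu_plt_correlation| must be < 1")
        if not 0.0 < self.target_prevalence < 1.0:
            raise ConfigError("target_prevalence must lie in (0, 1)")
        for col, probs in self.category_probs.items():
            p = np.array(list(probs.values()), dtype=float)
            if (p < 0).any() or (p > 1).any() or abs(p.sum() - 1.0) > 1e-9:
                raise ConfigError(f"category probabilities for {col!r} must sum to 1 in [0,1]")
        for lab, sd in self.lab_sds.items():
            if sd <= 0:
                raise ConfigError(f"lab sd for {lab!r} must be positive")

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "category_probs": self.category_probs,
            "lab_means": self.lab_means,
            "lab_sds": self.lab_sds,
            "neu_plt_correlation": self.neu_plt_correlation,
            "log_odds": self.log_odds,
            "target_prevalence": self.target_prevalence,
            "afp_lognormal": self.afp_lognormal,
            "intercept": self.intercept,
            "seed": self.seed,
        }


def _draw_covariates(config: GeneratorConfig, n: int, rng: np.random.Generator) -> pd.DataFrame:
    cols: dict[str, np.ndarray] = {}
    for name, probs in config.category_probs.items():
        levels = list(probs.keys())
        p = np.array([probs[lvl] for lvl in levels], dtype=float)
        cols[name] = rng.choice(levels, size=n, p=p)
    # NEU and PLT: bivariate Gaussian with the configured correlation.
    r = config.neu_plt_correlation
    z1 = rng.standard_normal(n)
    z2 = r * z1 + math.sqrt(1.0 - r * r) * rng.standard_normal(n)
    cols["NEU"] = config.lab_means["NEU"] + config.lab_sds["NEU"] * z1
    cols["PLT"] = config.lab_means["PLT"] + config.lab_sds["PLT"] * z2
    for lab in ("PT", "ALB", "GLU", "AFP"):
        mu, sd = config.lab_means[lab], config.lab_sds[lab]
        if lab == "AFP" and config.afp_lognormal:
            # match the requested mean/sd on the natural scale
            s2 = math.log(1.0 + (sd / mu) ** 2)
            cols[lab] = rng.lognormal(math.log(mu) - s2 / 2.0, math.sqrt(s2), size=n)
        else:
            cols[lab] = mu + sd * rng.standard_normal(n)
    return pd.DataFrame(cols)


def _linear_predictor(config: GeneratorConfig, frame: pd.DataFrame) -> np.ndarray:
    lp = np.zeros(len(frame))
    for key, beta in config.log_odds.items():
        if beta == 0.0:
            continue
        if "=" in key:
            col, lvl = key.split("=", 1)
            lp += beta * (frame[col].astype(str).to_numpy() == lvl)
        else:
            lp += beta * frame[key].to_numpy(dtype=float)
    return lp


def calibrate_intercept(config: GeneratorConfig, sample_size: int = 200_000) -> float:
    """Logistic intercept hitting the target prevalence by Monte-Carlo root finding.

    Draws ``sample_size`` covariate vectors (stream derived from the config
    seed, independent of the cohort draw) and solves
    ``mean(expit(b0 + lp)) = target_prevalence`` for ``b0`` on [−20, 20].
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed) & 0x7FFFFFFF, 911]))
    lp = _linear_predictor(config, _draw_covariates(config, sample_size, rng))

    def excess(b0: float) -> float:
        return float(np.mean(expit(b0 + lp))) - config.target_prevalence

    lo, hi = -20.0, 20.0
    if excess(lo) > 0 or excess(hi) < 0:
        raise ConfigError("intercept root not bracketed within [-20, 20]")
    return float(brentq(excess, lo, hi, xtol=1e-6))


def generate_cohort(config: GeneratorConfig) -> Cohort:
    """Draw one cohort: covariates, calibrated logistic outcome, ±1 labels.

    Bit-identical output for identical configs (all randomness flows from
    ``config.seed`` through fixed substreams).
    """
    b0 = config.intercept if config.intercept is not None else calibrate_intercept(config)
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed) & 0x7FFFFFFF, 1]))
    frame = _draw_covariates(config, config.n, rng)
    p = expit(b0 + _linear_predictor(config, frame))
    labels = np.where(rng.random(config.n) < p, 1, -1)
    return Cohort(frame, labels, bcs_schema())


def with_coefficient(config: GeneratorConfig, name: str, log_or: float) -> GeneratorConfig:
    """Copy of ``config`` with one logistic coefficient replaced."""
    lo = dict(config.log_odds)
    lo[name] = log_or
    return replace(config, log_odds=lo)
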