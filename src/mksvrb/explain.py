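"""Model-agnostic Shapley attributions for multi-kernel risk predictions.

Attributions are computed on the risk scale (0-1) at the level of the
original clinical variables: a categorical variable's one-hot block moves as
a single player, so importance lands on e.g. "intervention", not on a dummy
column.  The estimator is permutation sampling with background-marginal
imputation: for each sampled feature ordering and background patient, walk
the ordering replacing background values by the explained patient's values
and accumulate the marginal change in model risk.  The estimator is exactly
efficient in expectation (base value + attributions = predicted risk); an
exact enumeration over all 2^d coalitions is provided for small d.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd

from .cohort import Preprocessor
from .easymkl import MkModel, risk


@dataclass
class Attribution:
    """Per-variable Shapley attribution of one predicted risk."""

    features: list[str]
    values: np.ndarray  # one attribution per schema column
    standard_errors: np.ndarray  # Monte-Carlo SEs (zero for exact computation)
    base_value: float  # mean model risk over the background sample
    prediction: float  # model risk of the explained instance
    n_permutations: int
    seed: int | None

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"feature": self.features, "attribution": self.values, "se": self.standard_errors}
        )


def _risk_of_rows(model: MkModel, preprocessor: Preprocessor, rows: pd.DataFrame) -> np.ndarray:
    return risk(model, preprocessor.transform(rows))


def shapley_attribution(
    model: MkModel,
    preprocessor: Preprocessor,
    instance: pd.Series | pd.DataFrame,
    background: pd.DataFrame,
    n_permutations: int = 200,
    seed: int = 0,
) -> Attribution:
    """Monte-Carlo permutation-sampling Shapley attribution of one prediction.

    Each sample draws a feature ordering and one background patient; features
    of the explained instance replace the background values in order, and the
    risk increments are credited to the feature just inserted.  Deterministic
    given ``seed``.
    """
    if isinstance(instance, pd.DataFrame):
        if len(instance) != 1:
            raise ValueError("explain exactly one row at a time")
        instance = instance.iloc[0]
    if len(background) == 0:
        raise ValueError("background sample must be non-empty")
    features = [c.name for c in preprocessor.schema]
    d = len(features)
    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(d) for _ in range(n_permutations)])
    bg_rows = rng.integers(0, len(background), size=n_permutations)

    # build every chain row, then evaluate risks in one batch
    chains = []
    for k in range(n_permutations):
        row = background.iloc[bg_rows[k]][features].copy()
        chains.append(row.copy())
        for j in perms[k]:
            row[features[j]] = instance[features[j]]
            chains.append(row.copy())
    chain_frame = pd.DataFrame(chains).reset_index(drop=True)
    risks = _risk_of_rows(model, preprocessor, chain_frame)

    marginals = np.zeros((n_permutations, d))
    step = d + 1
    for k in range(n_permutations):
        chain = risks[k * step : (k + 1) * step]
        marginals[k, perms[k]] = np.diff(chain)
    values = marginals.mean(axis=0)
    se = marginals.std(axis=0, ddof=1) / np.sqrt(n_permutations) if n_permutations > 1 else np.zeros(d)
    base_value = float(np.mean(_risk_of_rows(model, preprocessor, background[features])))
    prediction = float(_risk_of_rows(model, preprocessor, instance[features].to_frame().T)[0])
    return Attribution(
        features=features,
        values=values,
        standard_errors=se,
        base_value=base_value,
        prediction=prediction,
        n_permutations=n_permutations,
        seed=seed,
    )


def exact_shapley_attribution(
    model: MkModel,
    preprocessor: Preprocessor,
    instance: pd.Series | pd.DataFrame,
    background: pd.DataFrame,
    max_features: int = 12,
) -> Attribution:
    """Exact Shapley values by enumeration of all 2^d coalitions (small d).

    The value of a coalition S is the mean model risk over background rows
    with the instance's values substituted on S.  Cost grows as 2^d · |background|;
    intended as a verification oracle for the sampling estimator.
    """
    if isinstance(instance, pd.DataFrame):
        instance = instance.iloc[0]
    features = [c.name for c in preprocessor.schema]
    d = len(features)
    if d > max_features:
        raise ValueError(f"exact enumeration limited to {max_features} features")
    values_of: dict[frozenset, float] = {}
    for size in range(d + 1):
        for S in combinations(range(d), size):
            rows = background[features].copy()
            for j in S:
                rows[features[j]] = instance[features[j]]
            values_of[frozenset(S)] = float(np.mean(_risk_of_rows(model, preprocessor, rows)))
    phi = np.zeros(d)
    for j in range(d):
        others = [k for k in range(d) if k != j]
        for size in range(d):
            w = 1.0 / (d * comb(d - 1, size))
            for S in combinations(others, size):
                fs = frozenset(S)
                phi[j] += w * (values_of[fs | {j}] - values_of[fs])
    base_value = values_of[frozenset()]
    return Attribution(
        features=features,
        values=phi,
        standard_errors=np.zeros(d),
        base_value=base_value,
        prediction=values_of[frozenset(range(d))],
        n_permutations=0,
        seed=None,
    )


def mean_abs_attribution(attributions: list[Attribution]) -> pd.DataFrame:
    """Mean |attribution| per feature over instances, ranked descending.

    Ties are broken alphabetically by feature name so the ranking is
    deterministic.
    """
    if not attributions:
        raise ValueError("need at least one attribution")
    features = attributions[0].features
    for a in attributions[1:]:
        if a.features != features:
            raise ValueError("attributions computed over different schemas")
    stacked = np.abs(np.vstack([a.values for a in attributions]))
    importance = stacked.mean(axis=0)
    out = pd.DataFrame({"feature": features, "importance": importance})
    return out.sort_values(["importance", "feature"], ascending=[False, True]).reset_index(drop=True)
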