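"""Study-design protocol: splits, metrics, repeated validation, baselines.

The protocol randomly divides a cohort into training/validation/test folds in
a 6:2:2 ratio (stratified by outcome by default), tunes each kernel subset by
PSO on train/validation, fits on the training fold and evaluates on the test
fold: AUC from decision scores (Mann-Whitney rank form), and sensitivity,
specificity and accuracy at a Youden-optimal risk threshold chosen on the
validation fold.  Repeating over seeded rounds yields mean ± sd per kernel
configuration; external baseline learners can be run through an adapter
contract on the identical splits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .cohort import Cohort, fit_preprocessor
from .easymkl import decision_scores, fit_mkmodel, risk
from .kernels import enumerate_kernel_subsets, subset_label
from .pso import SwarmConfig, tune_kernel_hyperparams

log = logging.getLogger(__name__)


@dataclass
class SplitScheme:
    train: np.ndarray
    validation: np.ndarray
    test: np.ndarray
    seed: int

    def parts(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return self.train, self.validation, self.test


def _largest_remainder(total: int, fractions: np.ndarray) -> np.ndarray:
    """Integer allocation of ``total`` by quotas; ties broken toward later parts."""
    quotas = total * fractions
    base = np.floor(quotas).astype(int)
    short = total - base.sum()
    # stable sort on (-remainder, -part index): later parts win remainder ties
    order = sorted(range(len(fractions)), key=lambda j: (-(quotas[j] - base[j]), -j))
    for j in order[:short]:
        base[j] += 1
    return base


def split_622(cohort: Cohort, seed: int = 0, stratified: bool = True) -> SplitScheme:
    """Seeded 6:2:2 train/validation/test partition.

    Unstratified: sizes (⌊0.6n⌋, ⌊0.2n⌋, remainder).  Stratified (default):
    per-class largest-remainder allocation of the same ratios, erroring if any
    part would miss a class.
    """
    n = cohort.n
    if n < 5:
        raise ValueError("cohort too small for a 6:2:2 split")
    rng = np.random.default_rng(seed)
    fractions = np.array([0.6, 0.2, 0.2])
    if not stratified:
        perm = rng.permutation(n)
        n_tr, n_va = int(np.floor(0.6 * n)), int(np.floor(0.2 * n))
        return SplitScheme(
            np.sort(perm[:n_tr]), np.sort(perm[n_tr : n_tr + n_va]), np.sort(perm[n_tr + n_va :]), seed
        )
    # global sizes first (floors to train and validation, remainder to test),
    # then a largest-remainder share of each part for the positive class; the
    # negative class takes the complement so part totals hold exactly
    n_tr, n_va = int(np.floor(0.6 * n)), int(np.floor(0.2 * n))
    global_sizes = np.array([n_tr, n_va, n - n_tr - n_va])
    pos_idx = rng.permutation(np.flatnonzero(cohort.labels == 1))
    neg_idx = rng.permutation(np.flatnonzero(cohort.labels == -1))
    pos_sizes = _largest_remainder(len(pos_idx), global_sizes / n)
    neg_sizes = global_sizes - pos_sizes
    if (pos_sizes == 0).any() or (neg_sizes <= 0).any():
        raise ValueError("a class would be absent from a fold; cohort too small to stratify")
    parts: list[np.ndarray] = []
    p_stop, n_stop = np.cumsum(pos_sizes), np.cumsum(neg_sizes)
    for k in range(3):
        p0 = 0 if k == 0 else p_stop[k - 1]
        n0 = 0 if k == 0 else n_stop[k - 1]
        parts.append(np.sort(np.concatenate([pos_idx[p0 : p_stop[k]], neg_idx[n0 : n_stop[k]]])))
    return SplitScheme(*parts, seed=seed)


def auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC in the Mann-Whitney rank form: P(score⁺ > score⁻) + ½·P(tie)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = labels == 1
    neg = labels == -1
    n_pos, n_neg = int(pos.sum()), int(neg.sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC requires both classes")
    ranks = rankdata(scores)
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


@dataclass
class MetricSet:
    sensitivity: float
    specificity: float
    accuracy: float
    auc: float | None = None


def confusion_metrics(risks: np.ndarray, labels: np.ndarray, threshold: float) -> MetricSet:
    """Sensitivity/specificity/accuracy at the rule "predict + when risk ≥ t".

    A metric with an empty denominator (single-class labels) is reported as
    NaN rather than silently zero.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    risks = np.asarray(risks, dtype=float)
    labels = np.asarray(labels)
    pred = risks >= threshold
    pos = labels == 1
    tp = int(np.sum(pred & pos))
    tn = int(np.sum(~pred & ~pos))
    n_pos = int(pos.sum())
    n_neg = len(labels) - n_pos
    sens = tp / n_pos if n_pos else float("nan")
    spec = tn / n_neg if n_neg else float("nan")
    acc = (tp + tn) / len(labels)
    return MetricSet(sensitivity=sens, specificity=spec, accuracy=acc)


def select_threshold_youden(risks: np.ndarray, labels: np.ndarray) -> float:
    """Observed risk value maximizing Youden's J = sens + spec − 1.

    Ties on J are broken toward higher specificity, then toward the higher
    threshold, so the choice is deterministic.
    """
    risks = np.asarray(risks, dtype=float)
    labels = np.asarray(labels)
    if not ((labels == 1).any() and (labels == -1).any()):
        raise ValueError("threshold selection requires both classes")
    best = None
    for t in np.unique(risks):
        m = confusion_metrics(risks, labels, float(np.clip(t, 0.0, 1.0)))
        key = (m.sensitivity + m.specificity - 1.0, m.specificity, t)
        if best is None or key > best[0]:
            best = (key, float(np.clip(t, 0.0, 1.0)))
    return best[1]


@dataclass
class ValidationReport:
    """Per-configuration aggregate of repeated validation rounds."""

    summary: pd.DataFrame  # one row per configuration: metric mean/sd columns
    per_round: pd.DataFrame  # raw per-round metric values
    seeds: list[int]

    def to_csv(self, path) -> None:
        self.summary.to_csv(path, index=False)


_METRICS = ("auc", "sensitivity", "specificity", "accuracy")


def _aggregate(per_round: pd.DataFrame, order: list[str], seeds: list[int]) -> ValidationReport:
    rows = []
    for name in order:
        sub = per_round[per_round["configuration"] == name]
        row: dict = {"configuration": name}
        if not sub.empty:
            row["kernels"] = sub["kernels"].iloc[0]
        for metric in _METRICS:
            vals = sub[metric].dropna().to_numpy()
            row[f"{metric}_mean"] = float(np.mean(vals)) if len(vals) else float("nan")
            row[f"{metric}_sd"] = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
        row["rounds_completed"] = len(sub)
        rows.append(row)
    return ValidationReport(summary=pd.DataFrame(rows), per_round=per_round, seeds=seeds)


def _evaluate_round(
    cohort: Cohort,
    subsets: list[tuple[str, ...]],
    adapters: dict,
    round_index: int,
    base_seed: int,
    swarm_config: SwarmConfig | None,
    stratified: bool,
    trace_normalized: bool,
) -> list[dict]:
    seed = base_seed + round_index
    scheme = split_622(cohort, seed=seed, stratified=stratified)
    pre = fit_preprocessor(cohort, scheme.train)
    X = {part: pre.transform(cohort.frame.iloc[idx]) for part, idx in
         zip(("train", "val", "test"), scheme.parts())}
    y = {part: cohort.labels[idx] for part, idx in
         zip(("train", "val", "test"), scheme.parts())}
    records = []
    for k, subset in enumerate(subsets):
        name = f"Config {k + 1}" if len(subsets) > 1 else subset_label(subset)
        try:
            sc = swarm_config or SwarmConfig()
            tuned = tune_kernel_hyperparams(
                X["train"], y["train"], X["val"], y["val"], subset,
                config=SwarmConfig(
                    n_particles=sc.n_particles, n_iterations=sc.n_iterations,
                    inertia=sc.inertia, cognitive=sc.cognitive, social=sc.social,
                    seed=(seed * 131 + k) % (2**31),
                ),
                trace_normalized=trace_normalized,
            )
            model = fit_mkmodel(
                X["train"], y["train"], subset, specs=tuned.specs, phi=tuned.phi,
                trace_normalized=trace_normalized,
            )
            threshold = select_threshold_youden(risk(model, X["val"]), y["val"])
            test_risks = risk(model, X["test"])
            m = confusion_metrics(test_risks, y["test"], threshold)
            records.append({
                "round": round_index, "configuration": name, "kernels": subset_label(subset),
                "auc": auc(decision_scores(model, X["test"]), y["test"]),
                "sensitivity": m.sensitivity, "specificity": m.specificity,
                "accuracy": m.accuracy, "validation_auc": tuned.best_value,
                "threshold": threshold,
            })
        except (ValueError, RuntimeError, np.linalg.LinAlgError) as exc:
            log.warning("round %d, %s failed: %s; excluded from aggregate",
                        round_index, name, exc)
    for name, make_adapter in adapters.items():
        try:
            adapter = make_adapter() if callable(make_adapter) else make_adapter
            adapter.fit(X["train"], y["train"])
            val_scores = np.asarray(adapter.score(X["val"]), dtype=float)
            test_scores = np.asarray(adapter.score(X["test"]), dtype=float)
            lo, hi = min(val_scores.min(), test_scores.min()), max(val_scores.max(), test_scores.max())
            span = hi - lo if hi > lo else 1.0
            threshold = select_threshold_youden((val_scores - lo) / span, y["val"])
            m = confusion_metrics((test_scores - lo) / span, y["test"], threshold)
            records.append({
                "round": round_index, "configuration": name, "kernels": "",
                "auc": auc(test_scores, y["test"]),
                "sensitivity": m.sensitivity, "specificity": m.specificity,
                "accuracy": m.accuracy, "validation_auc": float("nan"),
                "threshold": threshold,
            })
        except Exception as exc:  # adapters are third-party; never kill the run
            log.warning("round %d, baseline %s failed: %s; excluded", round_index, name, exc)
    return records


def repeated_validation(
    cohort: Cohort,
    subsets: list[tuple[str, ...]] | None = None,
    rounds: int = 10,
    base_seed: int = 0,
    swarm_config: SwarmConfig | None = None,
    stratified: bool = True,
    trace_normalized: bool = True,
) -> ValidationReport:
    """Repeated-rounds protocol over kernel subsets.

    Round r re-splits with seed ``base_seed + r``, preprocesses on the train
    fold, PSO-tunes each subset on train/validation, fits on train and
    evaluates on test.  A failed subset-round is logged and excluded from that
    subset's aggregate rather than aborting the experiment.
    """
    if rounds < 1:
        raise ValueError("rounds must be >= 1")
    if subsets is None:
        subsets = enumerate_kernel_subsets()
    per_round = []
    seeds = []
    for r in range(rounds):
        seeds.append(base_seed + r)
        per_round.extend(
            _evaluate_round(cohort, subsets, {}, r, base_seed, swarm_config,
                            stratified, trace_normalized)
        )
    order = [f"Config {k + 1}" if len(subsets) > 1 else subset_label(s)
             for k, s in enumerate(subsets)]
    return _aggregate(pd.DataFrame(per_round), order, seeds)


def compare_with_baselines(
    cohort: Cohort,
    rounds: int = 10,
    adapters: dict | None = None,
    subsets: list[tuple[str, ...]] | None = None,
    base_seed: int = 0,
    swarm_config: SwarmConfig | None = None,
    stratified: bool = True,
    trace_normalized: bool = True,
) -> ValidationReport:
    """Kernel configurations plus external baselines on identical splits.

    ``adapters`` maps a display name to an object (or zero-argument factory)
    exposing ``fit(X, y)`` and ``score(X) -> real vector``; baselines are
    thresholded by the same validation-fold Youden rule after min-max mapping
    of scores to [0, 1].
    """
    if subsets is None:
        subsets = enumerate_kernel_subsets()
    adapters = adapters or {}
    per_round = []
    seeds = []
    for r in range(rounds):
        seeds.append(base_seed + r)
        per_round.extend(
            _evaluate_round(cohort, subsets, adapters, r, base_seed, swarm_config,
                            stratified, trace_normalized)
        )
    order = [f"Config {k + 1}" if len(subsets) > 1 else subset_label(s)
             for k, s in enumerate(subsets)] + list(adapters)
    return _aggregate(pd.DataFrame(per_round), order, seeds)


class SklearnAdapter:
    """Wrap any scikit-learn-style classifier into the fit/score contract."""

    def __init__(self, estimator):
        self.estimator = estimator

    def fit(self, X, y):
        self.estimator.fit(X, (np.asarray(y) == 1).astype(int))
        return self

    def score(self, X):
        return self.estimator.predict_proba(X)[:, 1]


def default_baseline_adapters(seed: int = 0) -> dict:
    """The three classical comparators: random forest, XGBoost, k-NN."""

    def rf():
        from sklearn.ensemble import RandomForestClassifier

        return SklearnAdapter(RandomForestClassifier(n_estimators=200, random_state=seed))

    def xgb():
        from xgboost import XGBClassifier

        return SklearnAdapter(
            XGBClassifier(n_estimators=200, random_state=seed, verbosity=0, eval_metric="logloss")
        )

    def knn():
        from sklearn.neighbors import KNeighborsClassifier

        return SklearnAdapter(KNeighborsClassifier(n_neighbors=15))

    return {"RF": rf, "XGBoost": xgb, "KNN": knn}
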