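"""Decision curve analysis: net benefit across threshold probabilities.

Net benefit of treating patients whose predicted risk is at or above a
threshold probability p_t is TP/N − (FP/N) · p_t/(1 − p_t): true positives
gained minus false positives penalized at the odds of the threshold.  The two
reference strategies are "treat all" (every patient positive) and "treat
none" (net benefit identically zero); a useful model beats both over a range
of clinically relevant thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


def net_benefit(risks: np.ndarray, labels: np.ndarray, p_t: float) -> float:
    """Net benefit at threshold probability ``p_t`` (ties count as positive)."""
    if not 0.0 < p_t < 1.0:
        raise ValueError("threshold probability must lie strictly in (0, 1)")
    risks = np.asarray(risks, dtype=float)
    labels = np.asarray(labels)
    n = len(labels)
    pred = risks >= p_t
    tp = float(np.sum(pred & (labels == 1)))
    fp = float(np.sum(pred & (labels == -1)))
    return tp / n - (fp / n) * p_t / (1.0 - p_t)


@dataclass
class DcaCurve:
    thresholds: np.ndarray
    curves: pd.DataFrame  # tidy: model, threshold, net_benefit
    prevalence: float
    n: int

    def to_csv(self, path) -> None:
        self.curves.to_csv(path, index=False)

    def model_curve(self, model: str) -> np.ndarray:
        sub = self.curves[self.curves["model"] == model].sort_values("threshold")
        return sub["net_benefit"].to_numpy()


def dca_curve(
    models: dict[str, np.ndarray],
    labels: np.ndarray,
    grid: np.ndarray | None = None,
) -> DcaCurve:
    """Net-benefit curves for named risk vectors plus the reference strategies.

    Default grid 0.01..0.99 in steps of 0.01 — the open interval avoids the
    degenerate odds factor at 0 and 1.  "Treat all" equals
    prevalence − (1 − prevalence)·p_t/(1 − p_t) and crosses zero exactly at
    the prevalence; "Treat none" is identically zero.
    """
    labels = np.asarray(labels)
    if grid is None:
        grid = np.round(np.arange(0.01, 1.0, 0.01), 10)
    grid = np.asarray(grid, dtype=float)
    n = len(labels)
    prevalence = float(np.mean(labels == 1))
    rows = []
    for name, risks in models.items():
        risks = np.asarray(risks, dtype=float)
        if len(risks) != n:
            raise ValueError(f"risk vector for {name!r} does not match the labels")
        for t in grid:
            rows.append({"model": name, "threshold": float(t),
                         "net_benefit": net_benefit(risks, labels, float(t))})
    for t in grid:
        rows.append({"model": "Treat all", "threshold": float(t),
                     "net_benefit": prevalence - (1.0 - prevalence) * t / (1.0 - t)})
        rows.append({"model": "Treat none", "threshold": float(t), "net_benefit": 0.0})
    return DcaCurve(thresholds=grid, curves=pd.DataFrame(rows), prevalence=prevalence, n=n)
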