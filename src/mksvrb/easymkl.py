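"""EasyMKL-style multiple kernel learner.

The learner solves, for a fixed composite kernel K and trade-off φ ∈ [0, 1],

    min_γ  (1 − φ) γᵀ Ŷ K Ŷ γ + φ ‖γ‖²      Ŷ = diag(y)

over the product of the two per-class probability simplices
(γ ≥ 0, Σ_{i∈⊕} γᵢ = Σ_{i∈⊖} γᵢ = 1, hence ‖γ‖₁ = 2).  The solver is a
pairwise coordinate descent: a same-class pair (r, q) moves mass
γr ← γr + ε, γq ← γq − ε, with the stationarity-optimal step
ε* = −(g_r − g_q)/(A_rr + A_qq − 2A_rq), A = (1 − φ) Ŷ K Ŷ + φ I, g = Aγ,
clipped to [−γr, γq] to preserve feasibility.  Kernel weights follow the
EasyMKL two-stage rule: solve γ on the unweighted average Gram, set
ηₘ ∝ γᵀ Ŷ Kₘ Ŷ γ, then re-solve γ on the η-weighted composite.

The final classifier scores a point as Σᵢ yᵢ γᵢ k_η(x, xᵢ) − b, with a
KOMD-style midpoint bias, and maps scores to recurrence risks in (0, 1) by
Platt scaling fitted on the training fold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .kernels import KernelSpec, composite_gram, default_kernel_spec, gram, trace_normalize

try:  # optional JIT of the sweep loop; the pure-Python path is identical
    from numba import njit as _njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - exercised only without numba
    _HAVE_NUMBA = False

    def _njit(*args, **kwargs):
        def deco(f):
            return f

        return deco if not (args and callable(args[0])) else args[0]


@_njit
def _sweep(A, gamma, g, ridx, qidx):  # pragma: no cover - measured via solve_gamma
    """One pass over the given same-class pairs; returns total objective change."""
    n = gamma.shape[0]
    total = 0.0
    for t in range(ridx.shape[0]):
        r = ridx[t]
        q = qidx[t]
        diff = g[r] - g[q]
        D = A[r, r] + A[q, q] - 2.0 * A[r, q]
        lo = -gamma[r]
        hi = gamma[q]
        if D > 0.0:
            eps = -diff / D
            if eps < lo:
                eps = lo
            elif eps > hi:
                eps = hi
        else:
            # non-convex direction (indefinite kernel): best feasible endpoint
            d_lo = 2.0 * lo * diff + lo * lo * D
            d_hi = 2.0 * hi * diff + hi * hi * D
            if d_lo < d_hi and d_lo < 0.0:
                eps = lo
            elif d_hi < 0.0:
                eps = hi
            else:
                eps = 0.0
        if eps != 0.0:
            delta = 2.0 * eps * diff + eps * eps * D
            if delta < 0.0:
                gamma[r] += eps
                gamma[q] -= eps
                for i in range(n):
                    g[i] += eps * (A[i, r] - A[i, q])
                total += delta
    return total


@dataclass
class GammaResult:
    """Solver output: the per-class probability vector and its trace."""

    gamma: np.ndarray
    objective_trace: list[float]
    sweeps: int
    converged: bool

    @property
    def objective(self) -> float:
        return self.objective_trace[-1]


def _class_masks(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    labels = np.asarray(labels)
    pos = labels == 1
    neg = labels == -1
    if not pos.any() or not neg.any():
        raise ValueError("both classes must be present")
    return pos, neg


def _same_class_pairs(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # index-ordered (not class-ordered) so the sweep is invariant under a
    # global label flip, which makes mirrored problems solve identically
    n = len(labels)
    ridx, qidx = [], []
    for a in range(n):
        for b in range(a + 1, n):
            if labels[a] == labels[b]:
                ridx.append(a)
                qidx.append(b)
    return np.asarray(ridx, dtype=np.int64), np.asarray(qidx, dtype=np.int64)


def solve_gamma(
    K: np.ndarray,
    labels: np.ndarray,
    phi: float = 0.5,
    tol: float = 1e-7,
    max_sweeps: int = 500,
    seed: int = 0,
) -> GammaResult:
    """Pairwise coordinate descent for the per-class simplex QP.

    Sweeps all same-class pairs in a seeded shuffled order; terminates when a
    full sweep improves the objective by less than ``tol`` or ``max_sweeps``
    is reached.  The objective trace is non-increasing by construction.
    """
    K = np.asarray(K, dtype=float)
    if K.ndim != 2 or K.shape[0] != K.shape[1]:
        raise ValueError("K must be a square training Gram")
    if not np.isfinite(K).all():
        raise ValueError("kernel matrix contains non-finite entries")
    if not 0.0 <= phi <= 1.0:
        raise ValueError("phi must lie in [0, 1]")
    labels = np.asarray(labels)
    pos, neg = _class_masks(labels)
    n = K.shape[0]
    y = labels.astype(float)
    A = (1.0 - phi) * (y[:, None] * K * y[None, :]) + phi * np.eye(n)
    A = np.ascontiguousarray(0.5 * (A + A.T))  # symmetrize against round-off

    gamma = np.zeros(n)
    gamma[pos] = 1.0 / pos.sum()
    gamma[neg] = 1.0 / neg.sum()
    g = A @ gamma
    trace = [float(gamma @ g)]
    ridx, qidx = _same_class_pairs(labels)
    rng = np.random.default_rng(seed)
    converged = False
    sweeps = 0
    for sweeps in range(1, max_sweeps + 1):
        perm = rng.permutation(ridx.shape[0])
        _sweep(A, gamma, g, ridx[perm], qidx[perm])
        g = A @ gamma  # refresh against incremental round-off
        trace.append(float(gamma @ g))
        if trace[-2] - trace[-1] < tol:
            converged = True
            break
    np.clip(gamma, 0.0, None, out=gamma)
    return GammaResult(gamma=gamma, objective_trace=trace, sweeps=sweeps, converged=converged)


def kernel_weights(gamma: np.ndarray, labels: np.ndarray, grams: list[np.ndarray]) -> np.ndarray:
    """Kernel weights ηₘ ∝ per-kernel margin γᵀ Ŷ Kₘ Ŷ γ, on the simplex.

    Negative margins (possible with the indefinite sigmoid kernel) are clipped
    to zero; a degenerate all-zero margin vector falls back to uniform weights.
    """
    if not grams:
        raise ValueError("at least one Gram required")
    gamma = np.asarray(gamma, dtype=float)
    y = np.asarray(labels, dtype=float)
    v = y * gamma
    d = np.array([max(float(v @ K @ v), 0.0) for K in grams])
    if d.sum() <= 0.0:
        return np.full(len(grams), 1.0 / len(grams))
    return d / d.sum()


@dataclass
class MkModel:
    """Fitted multi-kernel classifier.

    Holds the encoded training fold, the learned γ and kernel weights η, the
    trace-normalization scale of each base Gram (reused for test cross-Grams),
    the midpoint bias, Platt risk-calibration coefficients and the operating
    risk threshold.
    """

    X_train: np.ndarray
    y_train: np.ndarray
    specs: list[KernelSpec]
    eta: np.ndarray
    gamma: np.ndarray
    bias: float
    kernel_scales: np.ndarray
    platt_a: float | None = None
    platt_b: float | None = None
    operating_threshold: float = 0.59
    phi: float = 0.5
    solver_info: dict = field(default_factory=dict)

    @property
    def subset(self) -> tuple[str, ...]:
        return tuple(s.kind for s in self.specs)


def _train_grams(
    X: np.ndarray, specs: list[KernelSpec], trace_normalized: bool
) -> tuple[list[np.ndarray], np.ndarray]:
    grams, scales = [], []
    for spec in specs:
        K = gram(spec, X, X)
        if trace_normalized:
            # |trace| keeps scaling meaningful for the indefinite sigmoid kernel,
            # whose diagonal can be negative
            tr = abs(float(np.trace(K)))
            if tr <= 1e-300:
                raise ValueError(f"zero trace for {spec.kind} Gram")
            scale = K.shape[0] / tr
        else:
            scale = 1.0
        grams.append(K * scale)
        scales.append(scale)
    return grams, np.asarray(scales)


def _platt_fit(scores: np.ndarray, labels: np.ndarray, max_iter: int = 200) -> tuple[float, float]:
    """Fit risk = 1/(1 + exp(a·s + b)) by bounded Newton on the training fold.

    Parameterized internally as p(+1|s) = expit(c0 + c1·s); a = −c1, b = −c0.
    Separable score distributions drive the MLE to infinity, so coefficients
    are capped at ±15, keeping risks strictly inside (0, 1) in floating point
    over the training score range; a non-positive slope is clamped so risk
    stays increasing in score (a < 0).
    """
    s = np.asarray(scores, dtype=float)
    t = (np.asarray(labels) == 1).astype(float)
    c = np.zeros(2)
    X = np.column_stack([np.ones_like(s), s])
    for _ in range(max_iter):
        p = expit(X @ c)
        w = np.clip(p * (1.0 - p), 1e-12, None)
        grad = X.T @ (t - p)
        H = (X.T * w) @ X
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            break
        c = np.clip(c + step, -15.0, 15.0)
        if np.abs(step).max() < 1e-10 or np.abs(c).max() >= 15.0:
            break
    if c[1] <= 0.0:
        c[1] = 1e-6
    return -float(c[1]), -float(c[0])


def fit_mkmodel(
    X: np.ndarray,
    labels: np.ndarray,
    subset: tuple[str, ...],
    specs: dict[str, KernelSpec] | None = None,
    phi: float = 0.5,
    trace_normalized: bool = True,
    tol: float = 1e-7,
    max_sweeps: int = 500,
    seed: int = 0,
    operating_threshold: float = 0.59,
) -> MkModel:
    """Fit the multi-kernel classifier on one encoded training fold.

    Two-stage EasyMKL: (1) build (trace-normalized) base Grams for the subset;
    (2) solve γ on their unweighted average; (3) η from per-kernel margins;
    (4) re-solve γ on the η-weighted composite; (5) KOMD-style midpoint bias;
    (6) Platt risk calibration on the training scores.  Deterministic given
    its inputs.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    labels = np.asarray(labels)
    spec_list = [
        (specs or {}).get(kind, default_kernel_spec(kind)) for kind in subset
    ]
    if not spec_list:
        raise ValueError("kernel subset must be non-empty")
    grams, scales = _train_grams(X, spec_list, trace_normalized)
    avg = sum(grams) / len(grams)
    stage1 = solve_gamma(avg, labels, phi=phi, tol=tol, max_sweeps=max_sweeps, seed=seed)
    eta = kernel_weights(stage1.gamma, labels, grams)
    K_eta = composite_gram(grams, eta)
    stage2 = solve_gamma(K_eta, labels, phi=phi, tol=tol, max_sweeps=max_sweeps, seed=seed)
    gamma_vec = stage2.gamma
    y = labels.astype(float)
    raw = K_eta @ (y * gamma_vec)  # unbiased training scores
    pos, neg = _class_masks(labels)
    bias = 0.5 * (float(gamma_vec[pos] @ raw[pos]) + float(gamma_vec[neg] @ raw[neg]))
    scores = raw - bias
    platt_a, platt_b = _platt_fit(scores, labels)
    return MkModel(
        X_train=X,
        y_train=labels.astype(int),
        specs=spec_list,
        eta=eta,
        gamma=gamma_vec,
        bias=bias,
        kernel_scales=scales,
        platt_a=platt_a,
        platt_b=platt_b,
        operating_threshold=operating_threshold,
        phi=phi,
        solver_info={
            "stage1_sweeps": stage1.sweeps,
            "stage2_sweeps": stage2.sweeps,
            "stage2_objective": stage2.objective,
        },
    )


def decision_scores(model: MkModel, X_new: np.ndarray) -> np.ndarray:
    """Kernel-expansion decision score Σᵢ yᵢ γᵢ k_η(x, xᵢ) − b for each row."""
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    if X_new.shape[1] != model.X_train.shape[1]:
        raise ValueError(
            f"dimension mismatch: model expects {model.X_train.shape[1]} encoded columns"
        )
    K = np.zeros((X_new.shape[0], model.X_train.shape[0]))
    for w, spec, scale in zip(model.eta, model.specs, model.kernel_scales):
        if w == 0.0:
            continue
        K += w * scale * gram(spec, X_new, model.X_train)
    return K @ (model.y_train.astype(float) * model.gamma) - model.bias


def risk(model: MkModel, X_new: np.ndarray) -> np.ndarray:
    """Calibrated recurrence risk in (0, 1), strictly increasing in score."""
    if model.platt_a is None or model.platt_b is None:
        raise ValueError("model has no fitted risk calibration")
    s = decision_scores(model, X_new)
    r = 1.0 / (1.0 + np.exp(model.platt_a * s + model.platt_b))
    # keep the open interval even where the logistic saturates in floats
    return np.clip(r, 1e-15, 1.0 - 1e-15)
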