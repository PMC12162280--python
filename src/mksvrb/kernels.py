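"""Base kernels, Gram construction, trace normalization, composite kernels.

Four base kernels measure patient similarity on the encoded feature space:
linear xᵀz, polynomial (xᵀz + offset)^degree, sigmoid tanh(α·xᵀz + β) and
Gaussian exp(−σ‖x−z‖²).  A composite kernel is a convex combination
Σₘ ηₘ Kₘ over a non-empty subset of these.  Base Grams are trace-normalized
before combination (K·n/tr(K)) so no kernel dominates purely by scale.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

# canonical ordering used everywhere a "Config k" index appears
KERNEL_KINDS: tuple[str, ...] = ("linear", "polynomial", "sigmoid", "gaussian")


@dataclass(frozen=True)
class KernelSpec:
    """One base kernel and the hyperparameters of its kind.

    Only the parameters of the declared kind are meaningful: ``offset``/
    ``degree`` for polynomial, ``alpha``/``beta`` for sigmoid, ``sigma`` for
    the Gaussian width.  The linear kernel has no hyperparameters.
    """

    kind: str
    offset: float | None = None
    degree: int | None = None
    alpha: float | None = None
    beta: float | None = None
    sigma: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in KERNEL_KINDS:
            raise ValueError(f"unknown kernel kind {self.kind!r}")
        expected = {
            "linear": (),
            "polynomial": ("offset", "degree"),
            "sigmoid": ("alpha", "beta"),
            "gaussian": ("sigma",),
        }[self.kind]
        for name in ("offset", "degree", "alpha", "beta", "sigma"):
            val = getattr(self, name)
            if name in expected:
                if val is None:
                    raise ValueError(f"{self.kind} kernel requires parameter {name!r}")
            elif val is not None:
                raise ValueError(f"parameter {name!r} is not a {self.kind} kernel parameter")
        if self.kind == "polynomial":
            if self.offset < 0:
                raise ValueError("polynomial offset must be >= 0")
            if int(self.degree) != self.degree or self.degree < 1:
                raise ValueError("polynomial degree must be an integer >= 1")
        if self.kind == "sigmoid" and self.alpha <= 0:
            raise ValueError("sigmoid alpha must be > 0")
        if self.kind == "gaussian" and self.sigma <= 0:
            raise ValueError("gaussian sigma must be > 0")

    def to_dict(self) -> dict:
        d = {"kind": self.kind}
        for name in ("offset", "degree", "alpha", "beta", "sigma"):
            val = getattr(self, name)
            if val is not None:
                d[name] = val
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "KernelSpec":
        return cls(**d)


def default_kernel_spec(kind: str) -> KernelSpec:
    """Default hyperparameters, sensible on z-scored features."""
    return {
        "linear": KernelSpec("linear"),
        "polynomial": KernelSpec("polynomial", offset=1.0, degree=2),
        "sigmoid": KernelSpec("sigmoid", alpha=0.1, beta=0.0),
        "gaussian": KernelSpec("gaussian", sigma=0.1),
    }[kind]


def gram(spec: KernelSpec, X1: np.ndarray, X2: np.ndarray) -> np.ndarray:
    """Gram matrix: entry (i, j) is the kernel of row i of X1 and row j of X2."""
    X1 = np.atleast_2d(np.asarray(X1, dtype=float))
    X2 = np.atleast_2d(np.asarray(X2, dtype=float))
    if X1.shape[1] != X2.shape[1]:
        raise ValueError(f"dimension mismatch: {X1.shape[1]} vs {X2.shape[1]} columns")
    if spec.kind == "gaussian":
        return np.exp(-spec.sigma * cdist(X1, X2, "sqeuclidean"))
    dot = X1 @ X2.T
    if spec.kind == "linear":
        return dot
    if spec.kind == "polynomial":
        return (dot + spec.offset) ** int(spec.degree)
    return np.tanh(spec.alpha * dot + spec.beta)


def trace_normalize(K: np.ndarray) -> np.ndarray:
    """Rescale a square Gram so its trace equals n (K · n / tr K)."""
    K = np.asarray(K, dtype=float)
    if K.ndim != 2 or K.shape[0] != K.shape[1]:
        raise ValueError("trace normalization requires a square Gram")
    tr = float(np.trace(K))
    if tr <= 0:
        raise ValueError("trace normalization requires a strictly positive trace")
    return K * (K.shape[0] / tr)


def composite_gram(grams: list[np.ndarray], eta: np.ndarray) -> np.ndarray:
    """Entrywise convex combination Σₘ ηₘ Kₘ of same-shape Grams."""
    eta = np.asarray(eta, dtype=float)
    if len(grams) != len(eta):
        raise ValueError("one weight per Gram required")
    if abs(eta.sum() - 1.0) > 1e-8 or (eta < -1e-12).any():
        raise ValueError("kernel weights must be non-negative and sum to 1")
    shape = grams[0].shape
    out = np.zeros(shape)
    for w, K in zip(eta, grams):
        if K.shape != shape:
            raise ValueError("Gram shapes disagree")
        out += w * K
    return out


def enumerate_kernel_subsets(kinds: tuple[str, ...] = KERNEL_KINDS) -> list[tuple[str, ...]]:
    """All non-empty kernel subsets, ordered by size then lexicographically.

    With the four base kinds this yields the 15 configurations (4 single-kernel
    and 11 multi-kernel) in the canonical "Config 1..15" order.
    """
    kinds = tuple(kinds)
    if not kinds:
        raise ValueError("at least one kernel kind required")
    if len(set(kinds)) != len(kinds):
        raise ValueError("duplicate kernel kinds")
    order = {k: KERNEL_KINDS.index(k) for k in kinds}
    sorted_kinds = sorted(kinds, key=order.get)
    out: list[tuple[str, ...]] = []
    for size in range(1, len(kinds) + 1):
        for combo in itertools.combinations(sorted_kinds, size):
            out.append(combo)
    return out


def subset_label(subset: tuple[str, ...]) -> str:
    """Human-readable label like "k1+k3" in the canonical kernel order."""
    return "+".join(f"k{KERNEL_KINDS.index(k) + 1}" for k in subset)
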