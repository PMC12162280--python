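"""Particle swarm optimization for kernel hyperparameters and the trade-off φ.

Standard global-best PSO: particle h moves with velocity
v ← ψ·v + c1·r1·(pb_h − W_h) + c2·r2·(gb − W_h) and position W ← W + v,
with r1, r2 ~ U(0,1) drawn fresh (one scalar each per particle per update).
Defaults follow the study protocol: 10 particles, 10 iterations, inertia
ψ = 0.9, cognitive and social factors c1 = c2 = 2.  The tuning objective is
validation-fold AUC of a model fitted on the training fold.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .easymkl import decision_scores, fit_mkmodel
from .kernels import KernelSpec, default_kernel_spec

log = logging.getLogger(__name__)


@dataclass
class SwarmConfig:
    n_particles: int = 10
    n_iterations: int = 10
    inertia: float = 0.9
    cognitive: float = 2.0
    social: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_particles < 1 or self.n_iterations < 1:
            raise ValueError("particle and iteration counts must be >= 1")
        if min(self.inertia, self.cognitive, self.social) < 0:
            raise ValueError("inertia/cognitive/social factors must be >= 0")


@dataclass
class SearchBox:
    """Axis-aligned search region with per-dimension sampling kind.

    Kinds: "real" (uniform), "log_real" (log-uniform, positive bounds),
    "integer" (continuous position, rounded at evaluation time).
    """

    names: list[str]
    lower: np.ndarray
    upper: np.ndarray
    kinds: list[str]

    def __post_init__(self) -> None:
        self.lower = np.asarray(self.lower, dtype=float)
        self.upper = np.asarray(self.upper, dtype=float)
        if not (len(self.names) == len(self.lower) == len(self.upper) == len(self.kinds)):
            raise ValueError("box fields must share one length")
        if len(self.names) < 1:
            raise ValueError("search box needs at least one dimension")
        if not (self.lower < self.upper).all():
            raise ValueError("lower bound must be strictly below upper in every dimension")
        for k, lo in zip(self.kinds, self.lower):
            if k not in ("real", "log_real", "integer"):
                raise ValueError(f"unknown dimension kind {k!r}")
            if k == "log_real" and lo <= 0:
                raise ValueError("log_real dimensions need positive bounds")

    @property
    def dim(self) -> int:
        return len(self.names)

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        u = rng.random((n, self.dim))
        out = np.empty_like(u)
        for j, kind in enumerate(self.kinds):
            lo, hi = self.lower[j], self.upper[j]
            if kind == "log_real":
                out[:, j] = np.exp(math.log(lo) + u[:, j] * (math.log(hi) - math.log(lo)))
            else:
                out[:, j] = lo + u[:, j] * (hi - lo)
        return out

    def decode(self, position: np.ndarray) -> dict[str, float]:
        """Map a raw position to evaluated parameter values (integers rounded)."""
        vals = {}
        for j, (name, kind) in enumerate(zip(self.names, self.kinds)):
            v = float(np.clip(position[j], self.lower[j], self.upper[j]))
            vals[name] = int(round(v)) if kind == "integer" else v
        return vals


@dataclass
class PsoResult:
    best_position: np.ndarray
    best_value: float
    history: list[dict] = field(default_factory=list)  # iteration, particle, position, value


def _evaluate(objective, position: np.ndarray, box: SearchBox) -> float:
    try:
        val = float(objective(position))
    except (ValueError, ArithmeticError, np.linalg.LinAlgError) as exc:
        log.warning("objective raised %s at %s; treated as -inf", exc, box.decode(position))
        return -math.inf
    if not math.isfinite(val):
        log.warning("non-finite objective at %s; treated as -inf", box.decode(position))
        return -math.inf
    return val


def pso_optimize(
    objective,
    box: SearchBox,
    config: SwarmConfig | None = None,
    initial_positions: np.ndarray | None = None,
) -> PsoResult:
    """Maximize ``objective`` over the box; deterministic given ``config.seed``.

    Positions are initialized uniformly in the box (log-uniform on log
    dimensions); ``initial_positions`` rows, if given, overwrite the first
    particles so known-good candidates (e.g. default hyperparameters) are
    always part of the evaluated set.  Velocities start at zero, are clamped
    to ±half the box width per dimension, and positions are clipped to the box
    after every move.
    """
    config = config or SwarmConfig()
    rng = np.random.default_rng(config.seed)
    W = box.sample(rng, config.n_particles)
    if initial_positions is not None:
        seeds = np.atleast_2d(np.asarray(initial_positions, dtype=float))
        k = min(len(seeds), config.n_particles)
        W[:k] = np.clip(seeds[:k], box.lower, box.upper)
    V = np.zeros_like(W)
    vmax = 0.5 * (box.upper - box.lower)

    history: list[dict] = []
    values = np.array([_evaluate(objective, w, box) for w in W])
    for h, (w, val) in enumerate(zip(W, values)):
        history.append({"iteration": 0, "particle": h, "position": w.copy(), "value": val})
    pb = W.copy()
    pbv = values.copy()
    gi = int(np.argmax(pbv))
    gb, gbv = pb[gi].copy(), float(pbv[gi])

    for it in range(1, config.n_iterations + 1):
        for h in range(config.n_particles):
            r1 = rng.random()
            r2 = rng.random()
            V[h] = (
                config.inertia * V[h]
                + config.cognitive * r1 * (pb[h] - W[h])
                + config.social * r2 * (gb - W[h])
            )
            np.clip(V[h], -vmax, vmax, out=V[h])
            W[h] = np.clip(W[h] + V[h], box.lower, box.upper)
            val = _evaluate(objective, W[h], box)
            history.append({"iteration": it, "particle": h, "position": W[h].copy(), "value": val})
            if val > pbv[h]:
                pbv[h] = val
                pb[h] = W[h].copy()
                if val > gbv:
                    gbv = float(val)
                    gb = W[h].copy()
    return PsoResult(best_position=gb, best_value=gbv, history=history)


# search bounds per tunable hyperparameter (chosen to span the regimes where
# each kernel's behaviour changes qualitatively on z-scored features)
_PARAM_BOUNDS: dict[str, tuple[float, float, str]] = {
    "offset": (0.0, 10.0, "real"),
    "degree": (1.0, 5.0, "integer"),
    "alpha": (1e-3, 10.0, "log_real"),
    "beta": (-10.0, 0.0, "real"),
    "sigma": (1e-3, 10.0, "log_real"),
    "phi": (0.01, 0.99, "real"),
}

_KERNEL_PARAMS: dict[str, tuple[str, ...]] = {
    "linear": (),
    "polynomial": ("offset", "degree"),
    "sigmoid": ("alpha", "beta"),
    "gaussian": ("sigma",),
}


def build_search_box(subset: tuple[str, ...]) -> SearchBox:
    """Search box over the hyperparameters of the kernels present, plus φ.

    The dimension Z is the number of tunable hyperparameters: offset and
    degree (polynomial), α and β (sigmoid), σ (Gaussian) and the universal φ;
    a linear-only subset therefore has Z = 1.
    """
    names: list[str] = []
    for kind in subset:
        for p in _KERNEL_PARAMS[kind]:
            names.append(f"{kind}.{p}")
    names.append("phi")
    lower, upper, kinds = [], [], []
    for name in names:
        lo, hi, k = _PARAM_BOUNDS[name.split(".")[-1]]
        lower.append(lo)
        upper.append(hi)
        kinds.append(k)
    return SearchBox(names=names, lower=np.array(lower), upper=np.array(upper), kinds=kinds)


def decode_hyperparams(
    box: SearchBox, position: np.ndarray, subset: tuple[str, ...]
) -> tuple[dict[str, KernelSpec], float]:
    """Turn a swarm position into per-kernel specs and the φ value."""
    vals = box.decode(position)
    specs: dict[str, KernelSpec] = {}
    for kind in subset:
        params = {p: vals[f"{kind}.{p}"] for p in _KERNEL_PARAMS[kind]}
        specs[kind] = KernelSpec(kind, **params) if params else KernelSpec(kind)
    return specs, float(vals["phi"])


def _default_position(box: SearchBox, subset: tuple[str, ...]) -> np.ndarray:
    pos = np.empty(box.dim)
    for j, name in enumerate(box.names):
        if name == "phi":
            pos[j] = 0.5
            continue
        kind, param = name.split(".")
        pos[j] = getattr(default_kernel_spec(kind), param)
    return np.clip(pos, box.lower, box.upper)


@dataclass
class TuneResult:
    specs: dict[str, KernelSpec]
    phi: float
    best_value: float
    best_position: np.ndarray
    history: list[dict]

    def history_frame(self):
        import pandas as pd

        rows = []
        for rec in self.history:
            row = {"iteration": rec["iteration"], "particle": rec["particle"], "value": rec["value"]}
            row.update({f"pos_{j}": p for j, p in enumerate(rec["position"])})
            rows.append(row)
        return pd.DataFrame(rows)


def tune_kernel_hyperparams(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    subset: tuple[str, ...],
    config: SwarmConfig | None = None,
    trace_normalized: bool = True,
) -> TuneResult:
    """PSO search maximizing validation AUC for one kernel subset.

    The default-hyperparameter candidate is injected into the initial swarm,
    so the tuned result never scores below the defaults on the folds used.
    """
    from .evaluation import auc  # local import to avoid a cycle

    y_train = np.asarray(y_train)
    y_val = np.asarray(y_val)
    for y in (y_train, y_val):
        if not ((y == 1).any() and (y == -1).any()):
            raise ValueError("tuning folds must contain both classes")
    box = build_search_box(subset)

    def objective(position: np.ndarray) -> float:
        specs, phi = decode_hyperparams(box, position, subset)
        model = fit_mkmodel(
            X_train, y_train, subset, specs=specs, phi=phi, trace_normalized=trace_normalized
        )
        return auc(decision_scores(model, X_val), y_val)

    result = pso_optimize(
        objective, box, config, initial_positions=_default_position(box, subset)[None, :]
    )
    specs, phi = decode_hyperparams(box, result.best_position, subset)
    return TuneResult(
        specs=specs,
        phi=phi,
        best_value=result.best_value,
        best_position=result.best_position,
        history=result.history,
    )
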