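"""Grey Wolf Optimizer (GWO) for hyperparameter search.

GWO is a population metaheuristic modelled on the hunting hierarchy of grey
wolf packs: the three best solutions so far (alpha, beta, delta) act as
leaders, and every wolf moves toward a randomized average of the three.
The pursuit is controlled by a parameter ``a`` decaying linearly from 2 to 0
over the run: per-dimension coefficients A = 2 a r1 - a and C = 2 r2
(r1, r2 uniform on [0, 1]) blend exploration (|A| > 1 pushes wolves away
from leaders) and exploitation (|A| < 1 pulls them in).

The optimizer is generic over any scalar objective (minimized); a small
:class:`SearchSpace` abstraction handles box bounds, log-scaled axes and
integer rounding so it can tune the classifier's training knobs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .network import Hyperparams


@dataclass(frozen=True)
class Dimension:
    """One search axis: box bounds, optionally log10-scaled and/or integer."""

    name: str
    lower: float
    upper: float
    scale: str = "linear"  # "linear" | "log"
    kind: str = "real"     # "real" | "integer"

    def __post_init__(self):
        if self.lower >= self.upper:
            raise ValueError(f"{self.name}: lower bound must be below upper bound")
        if self.scale == "log" and self.lower <= 0:
            raise ValueError(f"{self.name}: log scale requires positive bounds")

    # internal (search) coordinates: log10 for log axes
    def to_internal(self, value: float) -> float:
        return float(np.log10(value)) if self.scale == "log" else float(value)

    def from_internal(self, z: float) -> float:
        v = 10.0**z if self.scale == "log" else z
        return int(round(v)) if self.kind == "integer" else float(v)

    @property
    def internal_bounds(self) -> tuple[float, float]:
        return self.to_internal(self.lower), self.to_internal(self.upper)


@dataclass(frozen=True)
class SearchSpace:
    dimensions: tuple[Dimension, ...]

    @property
    def lower(self) -> np.ndarray:
        return np.array([d.internal_bounds[0] for d in self.dimensions])

    @property
    def upper(self) -> np.ndarray:
        return np.array([d.internal_bounds[1] for d in self.dimensions])

    def decode(self, position: np.ndarray) -> dict[str, float]:
        return {d.name: d.from_internal(z) for d, z in zip(self.dimensions, position)}


def default_hyperparam_space() -> SearchSpace:
    """Box bounds for tuning the classifier: momentum, learning rate (log),
    epoch budget (integer) and L2 coefficient (log)."""
    return SearchSpace((
        Dimension("momentum", 0.5, 0.99),
        Dimension("learning_rate", 1e-4, 1e-1, scale="log"),
        Dimension("epochs", 5, 50, kind="integer"),
        Dimension("l2", 1e-5, 1e-2, scale="log"),
    ))


def coefficient_schedule(t: int, T: int) -> float:
    """Linear decay a(t) = 2 (1 - t / T): 2 at the start, 0 at the horizon."""
    if T < 1:
        raise ValueError("horizon T must be >= 1")
    if not 0 <= t <= T:
        raise ValueError(f"iteration t={t} outside [0, {T}]")
    return 2.0 * (1.0 - t / T)


def draw_coefficients(a: float, r1: float, r2: float) -> tuple[float, float]:
    """A = 2 a r1 - a (in [-a, a]) and C = 2 r2 (in [0, 2])."""
    return 2.0 * a * r1 - a, 2.0 * r2


def update_position(
    wolf: np.ndarray,
    leaders: tuple[np.ndarray, np.ndarray, np.ndarray],
    a: float,
    rng: np.random.Generator,
    lower: np.ndarray | None = None,
    upper: np.ndarray | None = None,
) -> np.ndarray:
    """Move one wolf toward the randomized mean of the three leaders.

    For each leader L (fresh r1, r2 per leader and per dimension):
    D = |C * L - X|, candidate = L - A * D; the new position is the mean of
    the three candidates, clamped to the bounds when given.
    """
    wolf = np.asarray(wolf, dtype=np.float64)
    candidates = []
    for leader in leaders:
        r1 = rng.random(wolf.shape)
        r2 = rng.random(wolf.shape)
        A = 2.0 * a * r1 - a
        C = 2.0 * r2
        D = np.abs(C * leader - wolf)
        candidates.append(leader - A * D)
    new = np.mean(candidates, axis=0)
    if lower is not None:
        new = np.clip(new, lower, upper)
    return new


@dataclass
class OptimizeResult:
    best_position: np.ndarray
    best_fitness: float
    trace: list[float] = field(default_factory=list)      # best-so-far per iteration
    evaluations: list[tuple[np.ndarray, float]] = field(default_factory=list)


class GreyWolfOptimizer:
    """Minimize a scalar objective over a box with the grey-wolf update rule.

    ``n_wolves >= 3`` is required (alpha, beta and delta must exist); with
    exactly 3 wolves every agent is a leader.  Non-finite objective values
    are recorded as +inf and the run continues.
    """

    def __init__(self, n_wolves: int = 10, n_iterations: int = 10, seed: int = 0):
        if n_wolves < 3:
            raise ValueError("need at least 3 wolves (alpha, beta, delta)")
        if n_iterations < 1:
            raise ValueError("need at least one iteration")
        self.n_wolves = n_wolves
        self.n_iterations = n_iterations
        self.seed = seed

    def optimize(self, objective, space: SearchSpace) -> OptimizeResult:
        rng = np.random.default_rng(self.seed)
        lower, upper = space.lower, space.upper
        d = len(space.dimensions)
        positions = rng.uniform(lower, upper, size=(self.n_wolves, d))

        def evaluate(x: np.ndarray) -> float:
            try:
                v = float(objective(x))
            except Exception:
                return np.inf
            return v if np.isfinite(v) else np.inf

        result = OptimizeResult(best_position=positions[0].copy(), best_fitness=np.inf)
        fitness = np.array([evaluate(x) for x in positions])
        for x, f in zip(positions, fitness):
            result.evaluations.append((x.copy(), f))

        for t in range(self.n_iterations):
            order = np.argsort(fitness, kind="stable")
            leaders = tuple(positions[order[i]].copy() for i in range(3))
            if fitness[order[0]] < result.best_fitness:
                result.best_fitness = float(fitness[order[0]])
                result.best_position = positions[order[0]].copy()
            result.trace.append(result.best_fitness)
            a = coefficient_schedule(t, self.n_iterations)
            for i in range(self.n_wolves):
                positions[i] = update_position(positions[i], leaders, a, rng, lower, upper)
                fitness[i] = evaluate(positions[i])
                result.evaluations.append((positions[i].copy(), fitness[i]))

        best_final = int(np.argmin(fitness))
        if fitness[best_final] < result.best_fitness:
            result.best_fitness = float(fitness[best_final])
            result.best_position = positions[best_final].copy()
        return result


def optimize(objective, space: SearchSpace, n_wolves: int = 10, T: int = 10, seed: int = 0):
    """Functional wrapper: returns (best position, best fitness, trace)."""
    res = GreyWolfOptimizer(n_wolves, T, seed).optimize(objective, space)
    return res.best_position, res.best_fitness, res.trace


def tune_hyperparameters(
    train_eval,
    space: SearchSpace | None = None,
    n_wolves: int = 10,
    T: int = 10,
    seed: int = 0,
) -> tuple[Hyperparams, OptimizeResult]:
    """Maximize validation accuracy over the hyperparameter box.

    ``train_eval`` maps a :class:`~lightmg.network.Hyperparams` to a
    validation accuracy in [0, 1]; internally its negation is minimized.
    Integer axes (the epoch budget) are rounded at evaluation time.  Returns
    the decoded best hyperparameters plus the full evaluation log.
    """
    space = space or default_hyperparam_space()

    def objective(position: np.ndarray) -> float:
        hp = Hyperparams(**space.decode(position))
        return -float(train_eval(hp))

    result = GreyWolfOptimizer(n_wolves, T, seed).optimize(objective, space)
    best = Hyperparams(**space.decode(result.best_position))
    return best, result
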