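"""Real-coded genetic algorithm over the surrogate model.

The fitness aggregates the four extraction responses (total phenolics,
antioxidant activity, beta-carotenoids, flavonoids) into one scalar: each
response is min-max normalised against its observed range and the
normalised terms are summed, so fitness lives in [0, n_responses] and all
responses are maximised by default.

The optimizer is a plain bounded real-coded GA: tournament selection,
blend (BLX-alpha) crossover, Gaussian mutation with boundary clipping, and
elitism — which makes the best-fitness trace non-decreasing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = ["FitnessSpec", "GAConfig", "GAResult", "fitness_eq1", "optimize", "validate_optimum"]


@dataclass
class FitnessSpec:
    """Bounds, normalisation ranges and optimisation directions.

    ``bounds`` is (k, 2) in natural units.  ``response_min``/``response_max``
    normalise each response; ``directions`` holds +1 to maximise (default)
    or -1 to minimise a response.
    """

    bounds: np.ndarray
    response_min: np.ndarray
    response_max: np.ndarray
    directions: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.bounds = np.atleast_2d(np.asarray(self.bounds, float))
        self.response_min = np.asarray(self.response_min, float).ravel()
        self.response_max = np.asarray(self.response_max, float).ravel()
        if self.bounds.shape[1] != 2 or np.any(self.bounds[:, 1] <= self.bounds[:, 0]):
            raise ValueError("bounds must be (k, 2) with low < high")
        if not np.all(np.isfinite(self.bounds)):
            raise ValueError("bounds must be finite")
        if np.any(self.response_max <= self.response_min):
            raise ValueError("degenerate response normalization range")
        if self.directions is None:
            self.directions = np.ones_like(self.response_min)
        else:
            self.directions = np.asarray(self.directions, float).ravel()

    @property
    def n_factors(self) -> int:
        return len(self.bounds)


def fitness_eq1(responses: np.ndarray, spec: FitnessSpec) -> float:
    """Sum of min-max-normalised responses; in [0, n_responses].

    A response further than three normalisation ranges outside its band is
    treated as surrogate extrapolation and triggers a warning.
    """
    y = np.asarray(responses, float).ravel()
    span = spec.response_max - spec.response_min
    z = (y - spec.response_min) / span
    if np.any(np.abs(z - 0.5) > 3.0):
        warnings.warn("response far outside its normalization range (extrapolation)", RuntimeWarning)
    z = np.where(spec.directions >= 0, z, 1.0 - z)
    return float(z.sum())


@dataclass
class GAConfig:
    population: int = 50
    generations: int = 200
    p_crossover: float = 0.8
    p_mutation: float = 0.1
    mutation_scale: float = 0.05  # sigma as fraction of each factor range
    elitism: int = 2
    tournament: int = 3
    blx_alpha: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population < 4:
            raise ValueError("population must be >= 4")
        for p in (self.p_crossover, self.p_mutation):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")


@dataclass
class GAResult:
    best_point: np.ndarray
    best_fitness: float
    best_responses: np.ndarray
    solutions: np.ndarray  # deduplicated final population, best first
    history: np.ndarray = field(default=None)  # per-generation best fitness


def _evaluate(evaluate, spec: FitnessSpec, pop: np.ndarray):
    resp = np.empty((len(pop), len(spec.response_min)))
    fit = np.empty(len(pop))
    for i, p in enumerate(pop):
        y = np.asarray(evaluate(p), float).ravel()
        if not np.all(np.isfinite(y)):
            warnings.warn("non-finite surrogate response; individual demoted", RuntimeWarning)
            resp[i] = np.nan
            fit[i] = -np.inf
        else:
            resp[i] = y
            fit[i] = fitness_eq1(y, spec)
    return resp, fit


def optimize(
    evaluate,
    spec: FitnessSpec,
    config: GAConfig | None = None,
    init_points: np.ndarray | None = None,
) -> GAResult:
    """Maximise the aggregate fitness of ``evaluate`` over the bounded box.

    ``evaluate`` maps a natural-unit point to the response vector (for the
    full pipeline this is the trained network's forward pass).
    ``init_points`` seeds part of the initial population — typically the
    design points the surrogate was trained on.  Deterministic for a fixed
    seed.
    """
    config = config or GAConfig()
    rng = np.random.default_rng(config.seed)
    lo, hi = spec.bounds[:, 0], spec.bounds[:, 1]
    span = hi - lo
    k = spec.n_factors

    pop = rng.uniform(lo, hi, (config.population, k))
    if init_points is not None:
        seed_pts = np.clip(np.atleast_2d(np.asarray(init_points, float)), lo, hi)
        m = min(len(seed_pts), config.population)
        pop[:m] = seed_pts[:m]

    resp, fit = _evaluate(evaluate, spec, pop)
    history = []
    for _ in range(config.generations):
        order = np.argsort(-fit)
        elite = pop[order[: config.elitism]].copy()
        history.append(fit[order[0]])

        # tournament selection of parent indices
        n_children = config.population - config.elitism
        parents = np.empty((2 * n_children, k))
        for j in range(2 * n_children):
            contenders = rng.integers(0, config.population, config.tournament)
            parents[j] = pop[contenders[np.argmax(fit[contenders])]]

        children = np.empty((n_children, k))
        for c in range(n_children):
            p1, p2 = parents[2 * c], parents[2 * c + 1]
            if rng.random() < config.p_crossover:
                lo_g = np.minimum(p1, p2)
                hi_g = np.maximum(p1, p2)
                d = hi_g - lo_g
                children[c] = rng.uniform(
                    lo_g - config.blx_alpha * d, hi_g + config.blx_alpha * d
                )
            else:
                children[c] = p1
            mutate = rng.random(k) < config.p_mutation
            children[c] = np.where(
                mutate,
                children[c] + rng.normal(0.0, config.mutation_scale * span),
                children[c],
            )
        children = np.clip(children, lo, hi)
        pop = np.vstack([elite, children])
        resp, fit = _evaluate(evaluate, spec, pop)

    order = np.argsort(-fit)
    history.append(fit[order[0]])
    best = pop[order[0]].copy()
    # dedupe the final population at modest precision, keep best-first order
    seen: set[tuple] = set()
    uniq = []
    for i in order:
        key = tuple(np.round(pop[i], 6))
        if key not in seen:
            seen.add(key)
            uniq.append(pop[i])
    return GAResult(
        best_point=best,
        best_fitness=float(fit[order[0]]),
        best_responses=resp[order[0]].copy(),
        solutions=np.array(uniq),
        history=np.array(history),
    )


def validate_optimum(experimental: np.ndarray, predicted: np.ndarray) -> np.ndarray:
    """Per-response relative deviation, 100*|predicted - experimental|/experimental."""
    e = np.asarray(experimental, float).ravel()
    p = np.asarray(predicted, float).ravel()
    if e.shape != p.shape:
        raise ValueError("experimental and predicted must have the same length")
    if np.any(e == 0):
        raise ValueError("zero experimental value in relative deviation")
    return 100.0 * np.abs(p - e) / np.abs(e)
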