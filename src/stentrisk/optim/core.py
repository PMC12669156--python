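"""Population metaheuristics with a shared run contract.

The sequoia optimizer mimics a redwood forest's self-regulation in three
phases per generation:

* canopy growth -- every tree moves toward the current tallest (global
  best) with a coefficient annealed linearly from 2 to 0, so early moves
  can overshoot the leader (exploration) and late moves contract onto it;
* seed dispersal -- a random half of the population takes a heavy-tailed
  Levy flight whose step scale is a fraction of the domain range, with
  greedy acceptance (a tree only moves to better ground);
* fire renewal -- the worst few individuals are burned and re-seeded
  across the whole domain each generation.

The improved variant adds chaotic (logistic-map) initialization and an
exponentially decaying Levy step scale; the base variant uses uniform
initialization and a fixed scale. Classic PSO/GA/GWO/WOA baselines share
the same seeded, clipped, best-so-far-monotone run contract.

Every algorithm accepts both scalar objectives ``f(x) -> float`` and
vectorized ones ``f(X[pop, dim]) -> array[pop]``; NaN evaluations are
discarded (the candidate is rejected) with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .levy import logistic_chaos_sequence, mantegna_sigma, step_scale

ALGORITHMS = ("ISequoiaOA", "SequoiaOA", "PSO", "GA", "GWO", "WOA")


@dataclass(frozen=True)
class SearchSpace:
    dim: int
    lower: np.ndarray
    upper: np.ndarray
    discrete: bool = False

    def __post_init__(self) -> None:
        lo = np.broadcast_to(np.asarray(self.lower, dtype=float), (self.dim,)).copy()
        hi = np.broadcast_to(np.asarray(self.upper, dtype=float), (self.dim,)).copy()
        object.__setattr__(self, "lower", lo)
        object.__setattr__(self, "upper", hi)
        if not np.all(lo < hi):
            raise ValueError("lower bounds must be strictly below upper bounds")

    @property
    def range(self) -> np.ndarray:
        return self.upper - self.lower

    def clip(self, X: np.ndarray) -> np.ndarray:
        return np.clip(X, self.lower, self.upper)


@dataclass(frozen=True)
class OptimizerConfig:
    pop_size: int = 30
    max_iters: int = 500
    seed: int = 0
    levy_beta: float = 1.5
    alpha0: float = 0.1
    renewal_fraction: float = 0.1
    chaotic_init: bool = True

    def __post_init__(self) -> None:
        if self.pop_size < 2:
            raise ValueError("pop_size must be >= 2")
        if self.max_iters < 1:
            raise ValueError("max_iters must be >= 1")
        if not 1.0 < self.levy_beta <= 2.0:
            raise ValueError("levy_beta must satisfy 1 < beta <= 2")
        if not 0.0 <= self.renewal_fraction < 1.0:
            raise ValueError("renewal_fraction must be in [0, 1)")


@dataclass
class OptResult:
    best_position: np.ndarray
    best_fitness: float
    history: list[float] = field(default_factory=list)
    evals: int = 0


def _evaluate(objective: Callable, X: np.ndarray) -> np.ndarray:
    """Evaluate a population; NaN results are replaced by +inf with a warning."""
    try:
        f = np.asarray(objective(X), dtype=float)
        if f.shape != (X.shape[0],):
            raise TypeError
    except (TypeError, ValueError, IndexError):
        f = np.array([float(objective(x)) for x in X])
    bad = ~np.isfinite(f) | np.isnan(f)
    if bad.any():
        warnings.warn(f"{int(bad.sum())} non-finite objective value(s) discarded")
        f = np.where(bad, np.inf, f)
    return f


def init_population(space: SearchSpace, config: OptimizerConfig) -> np.ndarray:
    """Seeded chaotic or uniform initial positions inside the box."""
    rng = np.random.default_rng(config.seed)
    return _init(space, config.pop_size, rng, config.chaotic_init)


def _init(space: SearchSpace, n: int, rng: np.random.Generator, chaotic: bool) -> np.ndarray:
    if chaotic:
        # Latin strata per dimension; within-stratum offsets come from the
        # logistic orbit pushed through the arcsine CDF (uniform marginals),
        # which spreads the population more evenly than iid uniform draws
        x0 = rng.uniform(0.05, 0.95)
        while x0 in (0.25, 0.5, 0.75):
            x0 = rng.uniform(0.05, 0.95)  # pragma: no cover - measure-zero redraw
        orbit = logistic_chaos_sequence(x0, n * space.dim).reshape(n, space.dim)
        jitter = (2.0 / np.pi) * np.arcsin(np.sqrt(orbit))
        u = np.empty((n, space.dim))
        for j in range(space.dim):
            u[:, j] = (rng.permutation(n) + jitter[:, j]) / n
    else:
        u = rng.uniform(size=(n, space.dim))
    return space.lower + u * space.range


def _sequoia(
    objective: Callable,
    space: SearchSpace,
    config: OptimizerConfig,
    dynamic_levy: bool,
) -> OptResult:
    rng = np.random.default_rng(config.seed)
    pop, dim, T = config.pop_size, space.dim, config.max_iters
    X = _init(space, pop, rng, config.chaotic_init)
    F = _evaluate(objective, X)
    evals = pop
    ib = int(np.argmin(F))
    best_x, best_f = X[ib].copy(), float(F[ib])
    history: list[float] = []
    sigma = mantegna_sigma(config.levy_beta)
    n_renew = int(np.floor(config.renewal_fraction * pop))

    for t in range(T):
        c = 2.0 * (1.0 - t / T)
        alpha = step_scale(t, T, config.alpha0) if dynamic_levy else config.alpha0

        # canopy growth: guided move toward the leader with possible overshoot
        cand = X + c * rng.uniform(size=(pop, dim)) * (best_x - X)

        # seed dispersal: Levy flight on a random half, scaled by domain range
        half = rng.choice(pop, size=pop // 2, replace=False)
        u = rng.normal(0.0, sigma, size=(len(half), dim))
        v = rng.normal(0.0, 1.0, size=(len(half), dim))
        levy = u / np.abs(v) ** (1.0 / config.levy_beta)
        cand[half] += alpha * levy * space.range

        cand = space.clip(cand)
        f_cand = _evaluate(objective, cand)
        evals += pop
        improved = f_cand < F
        X[improved] = cand[improved]
        F[improved] = f_cand[improved]

        # fire renewal: burn the worst individuals, re-seed across the domain
        if n_renew:
            worst = np.argsort(F)[-n_renew:]
            X[worst] = _init(space, n_renew, rng, config.chaotic_init)
            F[worst] = _evaluate(objective, X[worst])
            evals += n_renew

        ib = int(np.argmin(F))
        if F[ib] < best_f:
            best_f = float(F[ib])
            best_x = X[ib].copy()
        history.append(best_f)

    return OptResult(best_x, best_f, history, evals)


def iseq_optimize(objective: Callable, space: SearchSpace, config: OptimizerConfig) -> OptResult:
    """Improved sequoia optimizer: chaotic init + decaying Levy step scale."""
    return _sequoia(objective, space, config, dynamic_levy=True)


def _pso(objective, space, config):
    rng = np.random.default_rng(config.seed)
    pop, dim, T = config.pop_size, space.dim, config.max_iters
    X = _init(space, pop, rng, chaotic=False)
    vmax = 0.2 * space.range
    V = rng.uniform(-1, 1, size=(pop, dim)) * vmax
    F = _evaluate(objective, X)
    evals = pop
    P, Pf = X.copy(), F.copy()
    ib = int(np.argmin(Pf))
    best_x, best_f = P[ib].copy(), float(Pf[ib])
    history = []
    for t in range(T):
        w = 0.9 - 0.5 * t / T
        r1 = rng.uniform(size=(pop, dim))
        r2 = rng.uniform(size=(pop, dim))
        V = np.clip(w * V + 2.0 * r1 * (P - X) + 2.0 * r2 * (best_x - X), -vmax, vmax)
        X = space.clip(X + V)
        F = _evaluate(objective, X)
        evals += pop
        better = F < Pf
        P[better], Pf[better] = X[better], F[better]
        ib = int(np.argmin(Pf))
        if Pf[ib] < best_f:
            best_f, best_x = float(Pf[ib]), P[ib].copy()
        history.append(best_f)
    return OptResult(best_x, best_f, history, evals)


def _ga(objective, space, config):
    rng = np.random.default_rng(config.seed)
    pop, dim, T = config.pop_size, space.dim, config.max_iters
    X = _init(space, pop, rng, chaotic=False)
    F = _evaluate(objective, X)
    evals = pop
    ib = int(np.argmin(F))
    best_x, best_f = X[ib].copy(), float(F[ib])
    history = []
    pm = 1.0 / dim
    for t in range(T):
        # binary tournament selection
        a = rng.integers(pop, size=pop)
        b = rng.integers(pop, size=pop)
        parents = np.where((F[a] < F[b])[:, None], X[a], X[b])
        # uniform crossover between consecutive parent pairs
        mates = parents[rng.permutation(pop)]
        mask = rng.uniform(size=(pop, dim)) < 0.5
        children = np.where(mask, parents, mates)
        # gaussian mutation with mildly decaying scale
        sig = 0.1 * (1.0 - 0.9 * t / T) * space.range
        mut = rng.uniform(size=(pop, dim)) < pm
        children = children + mut * rng.normal(0.0, 1.0, size=(pop, dim)) * sig
        children = space.clip(children)
        Fc = _evaluate(objective, children)
        evals += pop
        # elitism: keep the best-so-far alive
        iw = int(np.argmax(Fc))
        children[iw], Fc[iw] = best_x, best_f
        X, F = children, Fc
        ib = int(np.argmin(F))
        if F[ib] < best_f:
            best_f, best_x = float(F[ib]), X[ib].copy()
        history.append(best_f)
    return OptResult(best_x, best_f, history, evals)


def _gwo(objective, space, config):
    rng = np.random.default_rng(config.seed)
    pop, dim, T = config.pop_size, space.dim, config.max_iters
    X = _init(space, pop, rng, chaotic=False)
    F = _evaluate(objective, X)
    evals = pop
    order = np.argsort(F)
    leaders = X[order[:3]].copy()
    leaders_f = F[order[:3]].copy()
    best_x, best_f = leaders[0].copy(), float(leaders_f[0])
    history = []
    for t in range(T):
        a = 2.0 * (1.0 - t / T)
        Xn = np.zeros_like(X)
        for leader in leaders:
            A = a * (2.0 * rng.uniform(size=(pop, dim)) - 1.0)
            C = 2.0 * rng.uniform(size=(pop, dim))
            D = np.abs(C * leader - X)
            Xn += leader - A * D
        X = space.clip(Xn / 3.0)
        F = _evaluate(objective, X)
        evals += pop
        pool = np.vstack([X, leaders])
        pool_f = np.concatenate([F, leaders_f])
        sel = np.argsort(pool_f)[:3]
        leaders, leaders_f = pool[sel].copy(), pool_f[sel].copy()
        if leaders_f[0] < best_f:
            best_f, best_x = float(leaders_f[0]), leaders[0].copy()
        history.append(best_f)
    return OptResult(best_x, best_f, history, evals)


def _woa(objective, space, config):
    rng = np.random.default_rng(config.seed)
    pop, dim, T = config.pop_size, space.dim, config.max_iters
    X = _init(space, pop, rng, chaotic=False)
    F = _evaluate(objective, X)
    evals = pop
    ib = int(np.argmin(F))
    best_x, best_f = X[ib].copy(), float(F[ib])
    history = []
    for t in range(T):
        a = 2.0 * (1.0 - t / T)
        Xn = X.copy()
        for i in range(pop):
            r = rng.uniform(size=dim)
            A = a * (2.0 * r - 1.0)
            C = 2.0 * rng.uniform(size=dim)
            if rng.uniform() < 0.5:
                if np.abs(A).max() < 1.0:
                    Xn[i] = best_x - A * np.abs(C * best_x - X[i])
                else:
                    j = rng.integers(pop)
                    Xn[i] = X[j] - A * np.abs(C * X[j] - X[i])
            else:
                L = rng.uniform(-1.0, 1.0, size=dim)
                D = np.abs(best_x - X[i])
                Xn[i] = D * np.exp(L) * np.cos(2.0 * np.pi * L) + best_x
        X = space.clip(Xn)
        F = _evaluate(objective, X)
        evals += pop
        ib = int(np.argmin(F))
        if F[ib] < best_f:
            best_f, best_x = float(F[ib]), X[ib].copy()
        history.append(best_f)
    return OptResult(best_x, best_f, history, evals)


def baseline_optimize(
    algorithm: str, objective: Callable, space: SearchSpace, config: OptimizerConfig
) -> OptResult:
    """Run one of the comparison optimizers under the shared contract.

    ``SequoiaOA`` is the base variant: uniform initialization and a fixed
    (non-decaying) Levy scale.
    """
    algorithm = algorithm.strip()
    if algorithm == "ISequoiaOA":
        return iseq_optimize(objective, space, config)
    if algorithm == "SequoiaOA":
        base_cfg = OptimizerConfig(
            pop_size=config.pop_size,
            max_iters=config.max_iters,
            seed=config.seed,
            levy_beta=config.levy_beta,
            alpha0=config.alpha0,
            renewal_fraction=config.renewal_fraction,
            chaotic_init=False,
        )
        return _sequoia(objective, space, base_cfg, dynamic_levy=False)
    table = {"PSO": _pso, "GA": _ga, "GWO": _gwo, "WOA": _woa}
    if algorithm not in table:
        raise ValueError(f"unknown algorithm {algorithm!r}; choose from {ALGORITHMS}")
    return table[algorithm](objective, space, config)


def random_search(objective: Callable, space: SearchSpace, evals: int, seed: int) -> OptResult:
    """Uniform random sampling at a fixed evaluation budget (null baseline)."""
    rng = np.random.default_rng(seed)
    X = space.lower + rng.uniform(size=(evals, space.dim)) * space.range
    F = _evaluate(objective, X)
    best = np.minimum.accumulate(F)
    ib = int(np.argmin(F))
    return OptResult(X[ib].copy(), float(F[ib]), best.tolist(), evals)
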