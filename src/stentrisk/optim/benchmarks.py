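"""Built-in benchmark suite and the optimizer comparison harness.

Twelve standard unconstrained test functions with known global minimum
value 0. To avoid the origin-bias that favours contraction-style
optimizers, each function's optimum is translated to a seeded random point
drawn within the central 60% of its box before a run.

The harness mirrors the common swarm-benchmark protocol: fixed dimension,
population 30, a fixed iteration budget and repeated independent seeded
runs per (function, algorithm) cell, summarized by min/median/mean/sd.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import OptimizerConfig, OptResult, SearchSpace, baseline_optimize


def _sphere(Z):
    return (Z**2).sum(axis=1)


def _ellipsoid(Z):
    d = Z.shape[1]
    w = 10.0 ** (6.0 * np.arange(d) / max(d - 1, 1))
    return (w * Z**2).sum(axis=1)


def _rosenbrock(Z):
    X = Z + 1.0  # optimum at z=0
    return (100.0 * (X[:, 1:] - X[:, :-1] ** 2) ** 2 + (X[:, :-1] - 1.0) ** 2).sum(axis=1)


def _rastrigin(Z):
    return (Z**2 - 10.0 * np.cos(2.0 * np.pi * Z) + 10.0).sum(axis=1)


def _ackley(Z):
    d = Z.shape[1]
    return (
        -20.0 * np.exp(-0.2 * np.sqrt((Z**2).sum(axis=1) / d))
        - np.exp(np.cos(2.0 * np.pi * Z).sum(axis=1) / d)
        + 20.0
        + np.e
    )


def _griewank(Z):
    d = Z.shape[1]
    j = np.sqrt(np.arange(1, d + 1))
    return (Z**2).sum(axis=1) / 4000.0 - np.prod(np.cos(Z / j), axis=1) + 1.0


def _zakharov(Z):
    d = Z.shape[1]
    s2 = (0.5 * np.arange(1, d + 1) * Z).sum(axis=1)
    return (Z**2).sum(axis=1) + s2**2 + s2**4


def _levy_fn(Z):
    W = 1.0 + Z / 4.0
    term1 = np.sin(np.pi * W[:, 0]) ** 2
    term3 = (W[:, -1] - 1.0) ** 2 * (1.0 + np.sin(2.0 * np.pi * W[:, -1]) ** 2)
    mid = W[:, :-1]
    term2 = ((mid - 1.0) ** 2 * (1.0 + 10.0 * np.sin(np.pi * mid + 1.0) ** 2)).sum(axis=1)
    return term1 + term2 + term3


def _schwefel_222(Z):
    return np.abs(Z).sum(axis=1) + np.prod(np.abs(Z), axis=1)


def _alpine(Z):
    return np.abs(Z * np.sin(Z) + 0.1 * Z).sum(axis=1)


def _sum_diff_powers(Z):
    d = Z.shape[1]
    return (np.abs(Z) ** (np.arange(2, d + 2))).sum(axis=1)


def _expanded_schaffer(Z):
    def g(x, y):
        s = x**2 + y**2
        return 0.5 + (np.sin(np.sqrt(s)) ** 2 - 0.5) / (1.0 + 0.001 * s) ** 2

    total = g(Z[:, -1], Z[:, 0])
    for j in range(Z.shape[1] - 1):
        total = total + g(Z[:, j], Z[:, j + 1])
    return total


@dataclass(frozen=True)
class BenchmarkFunction:
    name: str
    fn: callable
    lower: float
    upper: float

    def shifted(self, dim: int, seed: int):
        """Return (objective, space) with the optimum moved to a seeded point."""
        rng = np.random.default_rng(seed)
        lo, hi = self.lower, self.upper
        shift = rng.uniform(lo + 0.2 * (hi - lo), hi - 0.2 * (hi - lo), size=dim)
        fn = self.fn

        def objective(X):
            arr = np.asarray(X, dtype=float)
            out = fn(np.atleast_2d(arr) - shift)
            return float(out[0]) if arr.ndim == 1 else out

        return objective, SearchSpace(dim, np.full(dim, lo), np.full(dim, hi)), shift


BENCHMARK_SUITE: tuple[BenchmarkFunction, ...] = (
    BenchmarkFunction("sphere", _sphere, -100, 100),
    BenchmarkFunction("ellipsoid", _ellipsoid, -100, 100),
    BenchmarkFunction("rosenbrock", _rosenbrock, -30, 30),
    BenchmarkFunction("rastrigin", _rastrigin, -5.12, 5.12),
    BenchmarkFunction("ackley", _ackley, -32.768, 32.768),
    BenchmarkFunction("griewank", _griewank, -600, 600),
    BenchmarkFunction("zakharov", _zakharov, -10, 10),
    BenchmarkFunction("levy", _levy_fn, -10, 10),
    BenchmarkFunction("schwefel_222", _schwefel_222, -10, 10),
    BenchmarkFunction("alpine", _alpine, -10, 10),
    BenchmarkFunction("sum_diff_powers", _sum_diff_powers, -1, 1),
    BenchmarkFunction("expanded_schaffer", _expanded_schaffer, -100, 100),
)


@dataclass
class BenchmarkReport:
    results: pd.DataFrame  # columns: function, algorithm, run, final_fitness
    traces: pd.DataFrame  # columns: function, algorithm, run, iteration, best_fitness
    config: dict = field(default_factory=dict)

    def summary(self) -> pd.DataFrame:
        return (
            self.results.groupby(["function", "algorithm"])["final_fitness"]
            .agg(["min", "median", "mean", "std"])
            .reset_index()
        )

    def win_count(self, challenger: str, incumbent: str) -> int:
        """Number of functions where the challenger's median is <= incumbent's."""
        med = self.results.groupby(["function", "algorithm"])["final_fitness"].median()
        fns = self.results["function"].unique()
        return int(sum(med[f, challenger] <= med[f, incumbent] for f in fns))


def run_benchmark(
    functions=BENCHMARK_SUITE,
    algorithms=("ISequoiaOA", "SequoiaOA"),
    dim: int = 10,
    pop: int = 30,
    iters: int = 500,
    runs: int = 30,
    seed: int = 0,
    keep_traces: bool = False,
) -> BenchmarkReport:
    if not functions:
        raise ValueError("benchmark suite must be non-empty")
    rows, trace_rows = [], []
    ss = np.random.SeedSequence(seed)
    for bf in functions:
        # one optimum shift per function, shared across algorithms and runs
        shift_seed = int(ss.spawn(1)[0].generate_state(1)[0] % 2**31)
        for run in range(runs):
            run_seed = int(
                np.random.SeedSequence([seed, run, hash(bf.name) % 2**31]).generate_state(1)[0]
                % 2**31
            )
            objective, space, _ = bf.shifted(dim, shift_seed)
            for algo in algorithms:
                cfg = OptimizerConfig(pop_size=pop, max_iters=iters, seed=run_seed)
                res: OptResult = baseline_optimize(algo, objective, space, cfg)
                if not np.all((res.best_position >= space.lower) & (res.best_position <= space.upper)):
                    raise AssertionError("best position escaped bounds")
                rows.append((bf.name, algo, run, res.best_fitness))
                if keep_traces:
                    for it, v in enumerate(res.history):
                        trace_rows.append((bf.name, algo, run, it, v))
    results = pd.DataFrame(rows, columns=["function", "algorithm", "run", "final_fitness"])
    traces = pd.DataFrame(
        trace_rows, columns=["function", "algorithm", "run", "iteration", "best_fitness"]
    )
    return BenchmarkReport(
        results, traces, {"dim": dim, "pop": pop, "iters": iters, "runs": runs, "seed": seed}
    )
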