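"""Low-level stochastic primitives for the sequoia optimizer.

* logistic chaotic map (r = 4) for de-clustered population initialization,
* Mantegna's algorithm for Levy-stable flight steps,
* the exponential step-scale schedule that anneals exploration into
  exploitation over the run.
"""

from __future__ import annotations

import math

import numpy as np

# Orbits of the r=4 logistic map that collapse to fixed points or short cycles.
_DEGENERATE_X0 = {0.0, 0.25, 0.5, 0.75, 1.0}


def logistic_chaos_sequence(x0: float, n: int) -> np.ndarray:
    """Iterate x_{k+1} = 4 x_k (1 - x_k) for ``n`` steps from ``x0``.

    The r=4 logistic map is chaotic on (0, 1) with invariant arcsine
    (Beta(1/2, 1/2)) density; its low serial correlation spreads initial
    populations more evenly than iid uniform draws.
    """
    if not 0.0 < x0 < 1.0 or x0 in _DEGENERATE_X0:
        raise ValueError(
            f"x0={x0} lies on a degenerate orbit of the logistic map; redraw x0"
        )
    out = np.empty(n)
    x = x0
    for k in range(n):
        x = 4.0 * x * (1.0 - x)
        out[k] = x
    return out


def mantegna_sigma(beta: float) -> float:
    """Scale of the numerator Gaussian in Mantegna's Levy-step algorithm."""
    if not 1.0 < beta <= 2.0:
        raise ValueError("levy beta must satisfy 1 < beta <= 2")
    num = math.gamma(1.0 + beta) * math.sin(math.pi * beta / 2.0)
    den = math.gamma((1.0 + beta) / 2.0) * beta * 2.0 ** ((beta - 1.0) / 2.0)
    return (num / den) ** (1.0 / beta)


def mantegna_levy(beta: float, n: int, rng: np.random.Generator | int) -> np.ndarray:
    """Draw ``n`` heavy-tailed steps u / |v|^(1/beta), u ~ N(0, sigma_u^2), v ~ N(0,1)."""
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    sigma = mantegna_sigma(beta)
    u = rng.normal(0.0, sigma, size=n)
    v = rng.normal(0.0, 1.0, size=n)
    return u / np.abs(v) ** (1.0 / beta)


def step_scale(t: int, T: int, alpha0: float) -> float:
    """Exponentially decaying flight scale alpha0 * exp(-4 t / T)."""
    if not 0 <= t <= T:
        raise ValueError("iteration t must lie in [0, T]")
    return alpha0 * math.exp(-4.0 * t / T)
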