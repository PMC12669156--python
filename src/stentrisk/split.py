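"""Stratified train/test partitioning.

The overall training size is round(fraction * N); per-outcome-stratum
allocations are rounded by the largest-remainder rule with ties awarded to
the minority class, so stratum totals always sum to the overall size. For
the study cohort (826 records, 128 events, fraction 0.8) this yields the
661/165 partition with 103 training events.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .schema import CohortTable


@dataclass(frozen=True)
class SplitResult:
    train_index: frozenset[int]
    test_index: frozenset[int]
    ratio: float
    seed: int

    def train_array(self) -> np.ndarray:
        return np.array(sorted(self.train_index), dtype=int)

    def test_array(self) -> np.ndarray:
        return np.array(sorted(self.test_index), dtype=int)


def stratum_train_sizes(n_per_stratum: dict[int, int], train_fraction: float) -> dict[int, int]:
    """Largest-remainder allocation of the rounded overall train size.

    Ties in fractional remainder go to the minority (smaller) stratum.
    """
    total = sum(n_per_stratum.values())
    target = int(round(train_fraction * total))
    quotas = {k: train_fraction * n for k, n in n_per_stratum.items()}
    alloc = {k: int(np.floor(q)) for k, q in quotas.items()}
    short = target - sum(alloc.values())
    # rank by remainder desc, then by stratum size asc (minority first)
    order = sorted(
        n_per_stratum, key=lambda k: (-(quotas[k] - alloc[k]), n_per_stratum[k], k)
    )
    for k in order[: max(short, 0)]:
        alloc[k] += 1
    for k in list(alloc):
        alloc[k] = min(alloc[k], n_per_stratum[k])
    # redistribute if clipping lost any (degenerate tiny strata)
    deficit = target - sum(alloc.values())
    i = 0
    while deficit > 0 and i < len(order):
        k = order[i]
        room = n_per_stratum[k] - alloc[k]
        add = min(room, deficit)
        alloc[k] += add
        deficit -= add
        i += 1
    return alloc


def stratified_split(table: CohortTable, train_fraction: float, seed: int) -> SplitResult:
    """Seeded stratified partition by outcome class."""
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be in (0, 1)")
    y = table.outcome
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("both outcome classes must be present to stratify")
    sizes = {int(c): int((y == c).sum()) for c in classes}
    alloc = stratum_train_sizes(sizes, train_fraction)
    rng = np.random.default_rng(seed)
    train: list[int] = []
    for c in sorted(sizes):
        idx = np.flatnonzero(y == c)
        perm = rng.permutation(idx)
        train.extend(perm[: alloc[c]].tolist())
    train_set = frozenset(int(i) for i in train)
    test_set = frozenset(range(len(table))) - train_set
    return SplitResult(train_set, frozenset(test_set), train_fraction, seed)
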