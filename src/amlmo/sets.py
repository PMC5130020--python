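"""Venn decomposition and generalized Dice set similarity.

The generalized (k-set) Dice index of Diserud-Odegaard form,
``C = (k/(k-1)) * (1 - |union| / sum(|set|))``, reduces to the classic
``2|A∩B|/(|A|+|B|)`` for two sets, equals 1 for identical non-empty sets
and 0 for pairwise disjoint ones.  Confidence intervals come from a
percentile bootstrap over the element universe.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np


class EmptySetError(ValueError):
    pass


def venn_counts(sets: Mapping[str, set[str]]) -> dict[frozenset[str], int]:
    """Exact exclusive-region counts for 2 or 3 labelled sets.

    Keys are the non-empty label subsets; values are the number of
    elements belonging to exactly those sets.
    """
    labels = list(sets)
    if len(labels) != len(set(labels)):
        raise ValueError("set labels must be unique")
    if not 2 <= len(labels) <= 3:
        raise ValueError("Venn decomposition supports 2 or 3 sets")
    out: dict[frozenset[str], int] = {}
    for r in range(1, len(labels) + 1):
        for combo in combinations(labels, r):
            inside = set.intersection(*(sets[l] for l in combo))
            outside = set.union(*(sets[l] for l in labels if l not in combo), set())
            out[frozenset(combo)] = len(inside - outside)
    return out


def generalized_dice(sets: Sequence[set[str]]) -> float:
    """k-set Dice similarity in [0, 1]."""
    k = len(sets)
    if k < 2:
        raise ValueError("need at least two sets")
    if any(len(s) == 0 for s in sets):
        raise EmptySetError("Dice similarity is undefined for empty sets")
    union = len(set.union(*map(set, sets)))
    total = sum(len(s) for s in sets)
    return (k / (k - 1.0)) * (1.0 - union / total)


@dataclass
class DiceResult:
    k: int
    estimate: float
    ci_low: float
    ci_high: float
    n_bootstrap: int
    seed: int
    n_skipped: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.ci_low <= self.estimate + 1e-12 and self.estimate <= self.ci_high + 1e-12):
            raise ValueError("interval must bracket the estimate")


def dice_ci(
    universe: Sequence[str],
    membership: Mapping[str, set[str]],
    n_bootstrap: int = 1000,
    seed: int = 0,
    level: float = 0.95,
) -> DiceResult:
    """Percentile bootstrap confidence interval for the generalized Dice
    index, resampling universe elements with replacement.

    A resample in which any set comes out empty is skipped; more than 50%
    skipped replicates raises an instability error.
    """
    universe = list(universe)
    if not universe:
        raise ValueError("universe must be non-empty")
    labels = list(membership)
    if len(labels) < 2:
        raise ValueError("need at least two sets")
    for lbl in labels:
        extra = membership[lbl] - set(universe)
        if extra:
            raise ValueError(f"set {lbl!r} not contained in universe: {sorted(extra)[:5]}")

    ind = np.array(
        [[e in membership[lbl] for lbl in labels] for e in universe], dtype=bool
    )  # universe x sets
    k = len(labels)
    estimate = _dice_from_indicator(ind, k)

    rng = np.random.default_rng(seed)
    n = len(universe)
    stats_: list[float] = []
    skipped = 0
    for _ in range(n_bootstrap):
        idx = rng.integers(0, n, size=n)
        sub = ind[idx]
        if (sub.sum(axis=0) == 0).any():
            skipped += 1
            continue
        stats_.append(_dice_from_indicator(sub, k))
    if skipped > n_bootstrap / 2:
        raise RuntimeError(
            f"bootstrap unstable: {skipped}/{n_bootstrap} resamples produced an empty set"
        )
    lo, hi = np.quantile(stats_, [(1 - level) / 2, 1 - (1 - level) / 2])
    return DiceResult(
        k=k,
        estimate=float(estimate),
        ci_low=float(min(lo, estimate)),
        ci_high=float(max(hi, estimate)),
        n_bootstrap=n_bootstrap,
        seed=seed,
        n_skipped=skipped,
    )


def _dice_from_indicator(ind: np.ndarray, k: int) -> float:
    """Dice on a (possibly multiset) element x set indicator matrix."""
    union = int(ind.any(axis=1).sum())
    total = int(ind.sum())
    if total == 0:
        raise EmptySetError("all sets empty")
    return (k / (k - 1.0)) * (1.0 - union / total)
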