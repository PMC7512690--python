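"""Minimum-information-partition search: exhaustive and Queyranne's algorithm.

A partition measure Phi(S) is a symmetric set function (Phi(S) equals
Phi of the complement).  The MIP is its minimizer over nonempty proper
subsets.  Exhaustive search scans all 2^(N-1)-1 bipartitions; Queyranne's
pendant-pair algorithm needs only O(N^3) evaluations and is exact for
symmetric submodular functions (mutual information); for the
non-submodular measures it is a heuristic that is nearly always exact in
practice.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import ValidationError
from .measures import make_phi_function
from .partitions import (
    ENUMERATION_CAP,
    Bipartition,
    enumerate_bipartitions,
    n_bipartitions,
)


class CountedOracle:
    """Counts every evaluation of an underlying symmetric set function.

    The reported evaluation counts of the partition searchers follow a
    strict convention: every requested evaluation is counted and, in
    counting mode (the default), nothing is memoized.  An optional cache
    (``memoize=True``) may be used for performance, but counts produced
    with it are not comparable with the published convention.

    The empty set and the full set are boundary values of the symmetric
    function and evaluate to 0 (still counted).
    """

    def __init__(self, fn, n: int, memoize: bool = False):
        self.fn = fn
        self.n = int(n)
        self.count = 0
        self.memoize = memoize
        self._cache: dict[frozenset, float] = {}

    def __call__(self, subset) -> float:
        s = frozenset(subset)
        self.count += 1
        if self.memoize:
            key = self._canonical_key(s)
            if key not in self._cache:
                self._cache[key] = self.fn(s)
            return self._cache[key]
        return self.fn(s)

    def _canonical_key(self, s: frozenset) -> frozenset:
        if s and 0 not in s and len(s) < self.n:
            return frozenset(range(self.n)) - s
        return s

    def reset(self) -> None:
        self.count = 0
        self._cache.clear()

    @classmethod
    def for_measure(cls, joint, measure: str, memoize: bool = False, **kwargs):
        return cls(make_phi_function(joint, measure, **kwargs), joint.n, memoize=memoize)


@dataclass
class MIPSearchResult:
    """Outcome of a minimum-information-partition search.

    ``ranking`` (exhaustive search only, on request) lists every
    canonical bipartition with its Phi value, ascending.
    """

    partition: Bipartition
    phi: float
    n_evals: int
    method: str
    measure: str | None = None
    ranking: list[tuple[Bipartition, float]] | None = None
    diagnostics: dict = field(default_factory=dict)

    @property
    def phi_mean(self) -> float | None:
        """Mean Phi over all bipartitions (available with a full ranking)."""
        if self.ranking is None:
            return None
        return float(np.mean([v for _, v in self.ranking]))

    def rank_of(self, part: Bipartition, tol: float = 1e-9) -> int:
        """1-based rank of a partition's Phi value within the full ranking."""
        if self.ranking is None:
            raise ValidationError("ranking was not retained; rerun with ranking=True")
        values = dict(self.ranking)
        if part not in values:
            raise ValidationError(f"partition {part} is not in the ranking")
        v = values[part]
        return 1 + sum(1 for _, u in self.ranking if u < v - tol)


def exhaustive_mip(
    oracle, n: int, ranking: bool = False, cap: int = ENUMERATION_CAP
) -> MIPSearchResult:
    """Global MIP by scanning all canonical bipartitions.

    Ties are broken by enumeration order.  One oracle call per partition.
    """
    best_part = None
    best_val = np.inf
    pairs: list[tuple[Bipartition, float]] = []
    for part in enumerate_bipartitions(n, cap=cap):
        val = float(oracle(part.members))
        if ranking:
            pairs.append((part, val))
        if val < best_val:
            best_val = val
            best_part = part
    n_evals = getattr(oracle, "count", n_bipartitions(n))
    result = MIPSearchResult(
        partition=best_part,
        phi=best_val,
        n_evals=n_evals,
        method="exhaustive",
        measure=getattr(getattr(oracle, "fn", oracle), "measure", None),
    )
    if ranking:
        pairs.sort(key=lambda pv: pv[1])
        result.ranking = pairs
    return result


def _group_key(group: frozenset) -> int:
    return min(group)


def pendant_pair(oracle, groups: list[frozenset]) -> tuple[frozenset, frozenset]:
    """Last two groups of a maximum-adjacency ordering of ``groups``.

    The ordering starts from the first group and repeatedly appends the
    candidate u minimizing f(W ∪ {u}) - f({u}) over groups not yet in W
    (for a graph-cut f this selects the candidate most adjacent to W,
    hence "maximum adjacency").
    For a symmetric submodular f the returned pair (t, u) is pendant:
    {u} minimizes the cut among sets separating u from t.  Ties in the
    key go to the candidate with the lowest original element index.

    Every candidate's key is evaluated as two separate oracle calls,
    even when only one candidate remains.
    """
    if len(groups) < 2:
        raise ValidationError("pendant pair needs at least two groups")
    ordering = [groups[0]]
    merged = set(groups[0])
    remaining = list(groups[1:])
    while remaining:
        best_idx = None
        best_key = np.inf
        for i, u in enumerate(remaining):
            key = oracle(merged | u) - oracle(u)
            if key < best_key or (
                key == best_key and _group_key(u) < _group_key(remaining[best_idx])
            ):
                best_key = key
                best_idx = i
        u = remaining.pop(best_idx)
        ordering.append(u)
        merged |= u
    return ordering[-2], ordering[-1]


def queyranne_mip(oracle, n: int) -> MIPSearchResult:
    """Queyranne's algorithm over a counted symmetric Phi oracle.

    Runs N-1 pendant-pair phases; each phase records the cut isolating
    the last group of its maximum-adjacency ordering (one counted oracle
    call) and then merges the final pair.  The best recorded cut is
    returned, expressed in original element indices.  Under this counting
    convention the total evaluation count is (N^3 - N)/3 + N - 1,
    a function of N only.

    Exact for submodular measures; empirically near-exact otherwise.
    """
    if n < 2:
        raise ValidationError("need at least two elements")
    groups: list[frozenset] = [frozenset([i]) for i in range(n)]
    best_val = np.inf
    best_set: frozenset | None = None
    while len(groups) >= 2:
        t, u = pendant_pair(oracle, groups)
        cut_val = float(oracle(u))  # the phase's candidate cut, counted
        if cut_val < best_val:  # strict: ties keep the earliest phase
            best_val = cut_val
            best_set = u
        merged = t | u
        groups = [g for g in groups if g is not t and g is not u]
        groups.append(merged)
        groups.sort(key=_group_key)
    part = Bipartition.from_members(best_set, n)
    return MIPSearchResult(
        partition=part,
        phi=best_val,
        n_evals=getattr(oracle, "count", 0),
        method="queyranne",
        measure=getattr(getattr(oracle, "fn", oracle), "measure", None),
    )


def expected_queyranne_evals(n: int) -> int:
    """Evaluation count of :func:`queyranne_mip` as a function of N alone."""
    return (n**3 - n) // 3 + n - 1
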