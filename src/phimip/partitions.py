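"""Bipartitions of a system of N elements.

A bipartition splits the element set {1, ..., N} into a nonempty proper
subset S and its complement.  S and its complement describe the same cut,
so every partition has a canonical representative: the side containing
element 1.  Elements are 1-based in all user-facing strings (matching the
usual notation for these systems) and 0-based internally; conversion
happens only in the parser/serializer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np

from .exceptions import ValidationError

#: largest N for which exhaustive enumeration is permitted (2^(N-1)-1 cuts)
ENUMERATION_CAP = 24


@dataclass(frozen=True)
class Bipartition:
    """Canonical bipartition of ``{0, ..., n-1}`` (0-based internally).

    ``members`` is the sorted tuple of the side containing element 0, so
    two subsets that describe the same cut compare equal.  Use
    :func:`canonicalize` / :meth:`from_members` to construct from an
    arbitrary side.
    """

    members: tuple[int, ...]
    n: int = field(compare=True)

    def __post_init__(self) -> None:
        m = self.members
        if not m or len(m) >= self.n:
            raise ValidationError(
                f"bipartition side must be a nonempty proper subset, got {m!r} of n={self.n}"
            )
        if list(m) != sorted(set(m)) or m[0] != 0 or m[-1] >= self.n:
            raise ValidationError(
                f"members must be sorted, unique, within range and contain element 0: {m!r}"
            )

    @classmethod
    def from_members(cls, subset: Iterable[int], n: int) -> "Bipartition":
        """Canonical partition from either side of the cut (0-based)."""
        s = frozenset(subset)
        if not s or len(s) >= n:
            raise ValidationError("subset must be nonempty and proper")
        if not all(0 <= i < n for i in s):
            raise ValidationError(f"subset {sorted(s)!r} out of range for n={n}")
        if 0 not in s:
            s = frozenset(range(n)) - s
        return cls(tuple(sorted(s)), n)

    @property
    def complement(self) -> tuple[int, ...]:
        inside = set(self.members)
        return tuple(i for i in range(self.n) if i not in inside)

    @property
    def sign_vector(self) -> np.ndarray:
        """±1 vector, +1 on the side containing element 0."""
        sigma = -np.ones(self.n, dtype=int)
        sigma[list(self.members)] = 1
        return sigma

    def to_string(self) -> str:
        """1-based comma-separated member list, e.g. ``"1,4,7"``."""
        return ",".join(str(i + 1) for i in self.members)

    @classmethod
    def from_string(cls, text: str, n: int) -> "Bipartition":
        """Parse a 1-based comma-separated member list."""
        try:
            subset = [int(tok) - 1 for tok in text.split(",") if tok.strip()]
        except ValueError as exc:
            raise ValidationError(f"cannot parse partition {text!r}") from exc
        return cls.from_members(subset, n)

    def __str__(self) -> str:
        other = ",".join(str(i + 1) for i in self.complement)
        return f"{{{self.to_string()}}}|{{{other}}}"


def canonicalize(subset: Iterable[int], n: int) -> Bipartition:
    """Canonical representative of the cut {subset, complement} (0-based)."""
    return Bipartition.from_members(subset, n)


def enumerate_bipartitions(n: int, cap: int = ENUMERATION_CAP) -> Iterator[Bipartition]:
    """Yield all 2^(n-1)-1 canonical bipartitions in a fixed order.

    The order enumerates the subset of {1, ..., n-1} joined to element 0
    by increasing bitmask, so it is deterministic across runs.
    """
    if n < 2:
        raise ValidationError("need at least two elements to bipartition")
    if n > cap:
        raise ValidationError(
            f"n={n} exceeds the enumeration cap ({cap}); "
            "use the Queyranne or replica-exchange searchers instead"
        )
    for mask in range(2 ** (n - 1) - 1):
        members = [0] + [i for i in range(1, n) if mask >> (i - 1) & 1]
        yield Bipartition(tuple(members), n)


def n_bipartitions(n: int) -> int:
    """Number of distinct bipartitions of an n-element system."""
    return 2 ** (n - 1) - 1
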