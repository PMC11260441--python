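"""Pedigree representation and additive-relationship algebra.

A pedigree is a directed acyclic parentage structure: each individual has a
sire and a dam, either of which may be unknown.  Individuals with both
parents unknown are founders and are assumed unrelated and non-inbred (a
reasonable assumption for wild-caught parents sampled from a large
population).  An individual with exactly one known parent is allowed; the
unknown side is treated as an independent founder draw.

The additive (numerator) relationship matrix ``A`` holds, for every pair of
individuals, twice their kinship coefficient: the expected fraction of
additive genetic variance they share.  Its diagonal is ``1 + F`` where ``F``
is the inbreeding coefficient.  ``A`` is built with the tabular method,
which processes individuals in an order where parents precede offspring:

    a_jj = 1 + 0.5 * a_{s(j), d(j)}
    a_ij = 0.5 * (a_{i, s(j)} + a_{i, d(j)})    for i before j

with unknown parents contributing zero.  The recursive kinship coefficient
``f(i, j)`` is also exposed; it serves as an independent route to the same
quantities (``A = 2 f`` off-diagnoal relationships follow the textbook
coancestry recursion rather than the tabular fill order).

The study pedigrees this package targets are small (on the order of a
hundred individuals), so ``A`` is stored dense and inverted by direct
factorization; sparse-inverse machinery is deliberately out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Pedigree",
    "RelationshipMatrix",
    "PedigreeError",
    "validate_pedigree",
    "additive_relationship",
    "kinship",
]

#: canonical internal sentinel for an unknown parent
UNKNOWN = ""

#: strings accepted as "unknown parent" in files and raw records
_MISSING_TOKENS = {"", "na", "nan", "none", "0", "."}


class PedigreeError(ValueError):
    """Raised for structurally invalid pedigrees (cycles, duplicates...)."""


def _normalize_parent(value) -> str:
    if value is None:
        return UNKNOWN
    if isinstance(value, float) and np.isnan(value):
        return UNKNOWN
    s = str(value).strip()
    if s.lower() in _MISSING_TOKENS:
        return UNKNOWN
    return s


@dataclass(frozen=True)
class Pedigree:
    """Validated pedigree in topological order (parents before offspring).

    Construct via :func:`validate_pedigree` or :meth:`Pedigree.from_records`;
    the constructor itself assumes the arrays are already consistent.

    Attributes
    ----------
    ids : tuple of str
        Individual identifiers, topologically sorted, founders first among
        ties (stable with respect to input order).
    sire, dam : tuple of str
        Parent identifiers aligned with ``ids``; ``""`` marks unknown.
    """

    ids: tuple
    sire: tuple
    dam: tuple
    _index: dict = field(repr=False, hash=False, compare=False, default=None)

    def __post_init__(self):
        object.__setattr__(self, "_index", {v: k for k, v in enumerate(self.ids)})

    # -- basic queries -----------------------------------------------------
    def __len__(self) -> int:
        return len(self.ids)

    def __contains__(self, individual: str) -> bool:
        return individual in self._index

    def index(self, individual: str) -> int:
        try:
            return self._index[individual]
        except KeyError:
            raise PedigreeError(f"unknown individual {individual!r}") from None

    def parents(self, individual: str) -> tuple:
        i = self.index(individual)
        return self.sire[i], self.dam[i]

    @property
    def founders(self) -> tuple:
        return tuple(
            i for i, s, d in zip(self.ids, self.sire, self.dam)
            if s == UNKNOWN and d == UNKNOWN
        )

    def is_founder(self, individual: str) -> bool:
        s, d = self.parents(individual)
        return s == UNKNOWN and d == UNKNOWN

    # -- construction ------------------------------------------------------
    @classmethod
    def from_records(cls, records: Iterable) -> "Pedigree":
        return validate_pedigree(records)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "Pedigree":
        cols = {c.lower(): c for c in frame.columns}
        for required in ("id", "sire", "dam"):
            if required not in cols:
                raise PedigreeError(f"pedigree table lacks column {required!r}")
        records = zip(frame[cols["id"]], frame[cols["sire"]], frame[cols["dam"]])
        return validate_pedigree(records)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"id": self.ids, "sire": self.sire, "dam": self.dam})

    # -- pruning -----------------------------------------------------------
    def subset(self, keep: Sequence) -> "Pedigree":
        """Restrict to ``keep`` plus all their ancestors.

        Relationships among retained individuals are unaffected: dropping
        individuals with no retained descendants never changes the additive
        relationship between the ones that stay.
        """
        wanted = set()
        stack = [k for k in keep]
        while stack:
            ind = stack.pop()
            if ind in wanted or ind == UNKNOWN:
                continue
            wanted.add(ind)
            s, d = self.parents(ind)
            stack.extend((s, d))
        rows = [
            (i, s, d) for i, s, d in zip(self.ids, self.sire, self.dam)
            if i in wanted
        ]
        return validate_pedigree(rows)


def validate_pedigree(raw_records: Iterable) -> Pedigree:
    """Validate raw ``(individual, sire, dam)`` records into a :class:`Pedigree`.

    Parents that never appear as individuals are auto-promoted to founder
    records.  Output order is topological (parents first), stable with
    respect to the input order.

    Raises
    ------
    PedigreeError
        On duplicate ids, self-parentage, or parentage cycles.
    """
    ids: list = []
    sire: dict = {}
    dam: dict = {}
    seen = set()
    for rec in raw_records:
        ind, s, d = rec[0], rec[1], rec[2]
        ind = str(ind).strip()
        if not ind or ind.lower() in _MISSING_TOKENS:
            raise PedigreeError(f"invalid individual id {rec[0]!r}")
        s, d = _normalize_parent(s), _normalize_parent(d)
        if ind in seen:
            raise PedigreeError(f"duplicate individual id {ind!r}")
        if ind in (s, d):
            raise PedigreeError(f"self-parentage: {ind!r} listed as its own parent")
        seen.add(ind)
        ids.append(ind)
        sire[ind], dam[ind] = s, d

    # auto-promote named-but-unlisted parents to founders
    for ind in list(ids):
        for p in (sire[ind], dam[ind]):
            if p != UNKNOWN and p not in seen:
                seen.add(p)
                ids.append(p)
                sire[p], dam[p] = UNKNOWN, UNKNOWN

    # Kahn topological sort, stable in input order
    order_of = {ind: k for k, ind in enumerate(ids)}
    children: dict = {ind: [] for ind in ids}
    n_pending = {}
    for ind in ids:
        parents = [p for p in (sire[ind], dam[ind]) if p != UNKNOWN]
        n_pending[ind] = len(parents)
        for p in parents:
            children[p].append(ind)
    import heapq

    ready = [order_of[i] for i in ids if n_pending[i] == 0]
    heapq.heapify(ready)
    topo: list = []
    while ready:
        ind = ids[heapq.heappop(ready)]
        topo.append(ind)
        for ch in children[ind]:
            n_pending[ch] -= 1
            if n_pending[ch] == 0:
                heapq.heappush(ready, order_of[ch])
    if len(topo) != len(ids):
        stuck = next(i for i in ids if n_pending[i] > 0)
        raise PedigreeError(f"parentage cycle detected involving {stuck!r}")

    return Pedigree(
        ids=tuple(topo),
        sire=tuple(sire[i] for i in topo),
        dam=tuple(dam[i] for i in topo),
    )


@dataclass(frozen=True)
class RelationshipMatrix:
    """Dense additive relationship matrix indexed by pedigree order."""

    ids: tuple
    values: np.ndarray  # (n, n), symmetric PSD, entries in [0, 2]

    def __post_init__(self):
        object.__setattr__(self, "_index", {v: k for k, v in enumerate(self.ids)})

    def loc(self, i: str, j: str) -> float:
        return float(self.values[self._index[i], self._index[j]])

    def inbreeding(self, individual: str) -> float:
        k = self._index[individual]
        return float(self.values[k, k] - 1.0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)


def additive_relationship(pedigree: Pedigree) -> RelationshipMatrix:
    """Build the additive relationship matrix A by the tabular method."""
    n = len(pedigree)
    idx = {ind: k for k, ind in enumerate(pedigree.ids)}
    si = np.array([idx.get(s, -1) for s in pedigree.sire], dtype=np.int64)
    di = np.array([idx.get(d, -1) for d in pedigree.dam], dtype=np.int64)
    A = np.zeros((n, n))
    for j in range(n):
        s, d = si[j], di[j]
        # topological order guarantees s < j and d < j
        row = np.zeros(j)
        if s >= 0:
            row += 0.5 * A[s, :j]
        if d >= 0:
            row += 0.5 * A[d, :j]
        A[j, :j] = row
        A[:j, j] = row
        A[j, j] = 1.0 + (0.5 * A[s, d] if (s >= 0 and d >= 0) else 0.0)
    return RelationshipMatrix(ids=pedigree.ids, values=A)


def kinship(pedigree: Pedigree, i: str, j: str, _memo: dict | None = None) -> float:
    """Recursive kinship (coancestry) coefficient f(i, j).

    Independent of the tabular construction: follows the classical
    recursion, with the later-born individual expanded into its parents,

        f(i, i) = 0.5 * (1 + f(s(i), d(i)))
        f(i, j) = 0.5 * (f(s(i), j) + f(d(i), j))   for i later than j

    and any term involving an unknown parent equal to zero.  Memoization is
    used for speed; results are recursion-exact.
    """
    order = {ind: k for k, ind in enumerate(pedigree.ids)}
    if i not in order:
        raise PedigreeError(f"unknown individual {i!r}")
    if j not in order:
        raise PedigreeError(f"unknown individual {j!r}")
    memo: dict = {} if _memo is None else _memo

    def f(a: str, b: str) -> float:
        if a == UNKNOWN or b == UNKNOWN:
            return 0.0
        if order[a] < order[b]:
            a, b = b, a
        key = (a, b)
        if key in memo:
            return memo[key]
        s, d = pedigree.parents(a)
        if a == b:
            val = 0.5 * (1.0 + f(s, d))
        else:
            val = 0.5 * (f(s, b) + f(d, b))
        memo[key] = val
        return val

    return f(i, j)
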