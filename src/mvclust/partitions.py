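"""Combinatorics of labelings and set partitions.

A clustering of a point set is an unlabeled partition: many label vectors
(related by a permutation of the label alphabet) induce the same partition
("label switching").  This module provides the canonical partition
representation, the label/cluster mismatch errors, the partition cost
(minimum label-Hamming distance normalized by n), enumeration of partitions
into at most ``l`` blocks (optionally with fixed block sizes), and Hamming
balls in partition space.

Points are indexed 1..n in input row order.  Partitions are stored
canonically: blocks ordered by smallest member, members ascending, so a
partition has exactly one representation and equality is structural.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

__all__ = [
    "Labeling",
    "Partition",
    "canonicalize",
    "label_mismatch_error",
    "partition_cost",
    "cluster_mismatch_error",
    "partition_distance",
    "enumerate_partitions",
    "hamming_ball",
]


@dataclass(frozen=True)
class Labeling:
    """A label vector of length n with values in {1, ..., l}."""

    labels: tuple
    l: int

    def __init__(self, labels: Sequence[int], l: Optional[int] = None):
        labels = tuple(int(x) for x in labels)
        if not labels:
            raise ValueError("labeling must have at least one point")
        if l is None:
            l = max(labels)
        if min(labels) < 1 or max(labels) > l:
            raise ValueError(f"labels must lie in 1..{l}")
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "l", int(l))

    @property
    def n(self) -> int:
        return len(self.labels)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.labels, dtype=np.int64)


@dataclass(frozen=True, order=True)
class Partition:
    """A canonical set partition of {1, ..., n}.

    ``blocks`` is a tuple of tuples: blocks ordered by smallest member,
    members ascending.  The dataclass ordering (used for deterministic
    tie-breaking throughout the package) is lexicographic on this canonical
    block structure.
    """

    blocks: tuple = field()

    def __init__(self, blocks: Iterable[Iterable[int]]):
        canon = []
        seen = set()
        for b in blocks:
            b = tuple(sorted(int(x) for x in b))
            if not b:
                raise ValueError("empty block")
            if seen & set(b):
                raise ValueError("blocks must be disjoint")
            seen.update(b)
            canon.append(b)
        if not canon:
            raise ValueError("partition must have at least one block")
        n = len(seen)
        if seen != set(range(1, n + 1)):
            raise ValueError("blocks must cover 1..n exactly")
        canon.sort(key=lambda b: b[0])
        object.__setattr__(self, "blocks", tuple(canon))

    @property
    def n(self) -> int:
        return sum(len(b) for b in self.blocks)

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)

    def sizes(self) -> tuple:
        """Block-size multiset, sorted descending."""
        return tuple(sorted((len(b) for b in self.blocks), reverse=True))

    def block_of(self) -> np.ndarray:
        """0-based block index of each point, shape (n,)."""
        out = np.empty(self.n, dtype=np.int64)
        for k, b in enumerate(self.blocks):
            for x in b:
                out[x - 1] = k
        return out

    def to_labels(self) -> Labeling:
        """The canonical inducing labeling (block k gets label k+1)."""
        return Labeling((self.block_of() + 1).tolist(), l=self.n_blocks)

    def serialize(self) -> str:
        return "|".join(",".join(str(x) for x in b) for b in self.blocks)

    @classmethod
    def deserialize(cls, text: str) -> "Partition":
        return cls([[int(x) for x in b.split(",")] for b in text.split("|")])

    def __repr__(self) -> str:  # compact, e.g. {{1,2},{3,4}}
        inner = ",".join("{" + ",".join(map(str, b)) + "}" for b in self.blocks)
        return "{" + inner + "}"


def canonicalize(labeling: Labeling) -> Partition:
    """Partition induced by a labeling; invariant to label permutations."""
    groups: dict = {}
    for idx, lab in enumerate(labeling.labels, start=1):
        groups.setdefault(lab, []).append(idx)
    return Partition(groups.values())


def label_mismatch_error(truth: Labeling, predicted: Labeling) -> float:
    """Fraction of points whose labels disagree (no label-switch allowance)."""
    if truth.n != predicted.n:
        raise ValueError("labelings must have equal length")
    t = truth.as_array()
    p = predicted.as_array()
    return float(np.mean(t != p))


def _overlap_table(q: Partition, p: Partition) -> np.ndarray:
    tab = np.zeros((q.n_blocks, p.n_blocks), dtype=np.int64)
    memb_p = p.block_of()
    for i, b in enumerate(q.blocks):
        for x in b:
            tab[i, memb_p[x - 1]] += 1
    return tab


def partition_cost(q: Partition, p: Partition) -> float:
    """Minimum label-mismatch fraction over labelings inducing ``q``.

    Equals (n - best injective block matching overlap) / n, computed with
    optimal bipartite assignment on the block-overlap contingency table, and
    is symmetric in its arguments.
    """
    if q.n != p.n:
        raise ValueError("partitions must cover the same number of points")
    tab = _overlap_table(q, p)
    rows, cols = linear_sum_assignment(tab, maximize=True)
    return float(q.n - tab[rows, cols].sum()) / q.n


def cluster_mismatch_error(pred: Partition, truth: Labeling) -> float:
    """Clustering error of a predicted partition against true labels.

    The minimum fraction of misassigned points over all labelings inducing
    the prediction — the per-point-set error statistic reported by the
    benchmark (label switching is absorbed).
    """
    return partition_cost(pred, canonicalize(truth))


def partition_distance(q: Partition, p: Partition) -> int:
    """Minimum Hamming distance between label vectors inducing q and p."""
    c = partition_cost(q, p)
    return int(round(c * q.n))


def _rgs_partitions(n: int, l: int) -> Iterator[Partition]:
    """All partitions of 1..n into at most l blocks, in lexicographic
    restricted-growth-string order (deterministic)."""
    a = [0] * n  # a[i] = block of point i+1; restricted growth: a[i] <= max(a[:i])+1
    while True:
        yield Partition(
            [[i + 1 for i in range(n) if a[i] == k] for k in range(max(a) + 1)]
        )
        # next restricted growth string with values < l
        i = n - 1
        while i > 0:
            cap = min(l - 1, max(a[:i]) + 1)
            if a[i] < cap:
                a[i] += 1
                for j in range(i + 1, n):
                    a[j] = 0
                break
            i -= 1
        else:
            return


def _sized_partitions(n: int, sizes: Sequence[int]) -> Iterator[Partition]:
    """Partitions with the exact block-size multiset ``sizes`` (deterministic
    order: recursive, smallest unplaced point first, lexicographic blocks)."""
    sizes = sorted(sizes, reverse=True)

    def rec(remaining: tuple, size_pool: list):
        if not remaining:
            yield []
            return
        first, rest = remaining[0], remaining[1:]
        tried = set()
        for s in sorted(set(size_pool), reverse=True):
            if s in tried:
                continue
            tried.add(s)
            pool = list(size_pool)
            pool.remove(s)
            for others in itertools.combinations(rest, s - 1):
                block = (first,) + others
                left = tuple(x for x in rest if x not in others)
                for tail in rec(left, pool):
                    yield [block] + tail

    for blocks in rec(tuple(range(1, n + 1)), list(sizes)):
        yield Partition(blocks)


def enumerate_partitions(
    n: int, l: int, sizes: Optional[Sequence[int]] = None
) -> Iterator[Partition]:
    """Stream all partitions of n points into at most ``l`` nonempty blocks.

    With ``sizes`` given, yields exactly the partitions whose block-size
    multiset matches (these necessarily have ``len(sizes)`` blocks).  For
    l=2 without sizes the count is 2**(n-1).  Order is deterministic.
    """
    if n < 1 or l < 1:
        raise ValueError("n and l must be >= 1")
    if sizes is not None:
        sizes = [int(s) for s in sizes]
        if any(s < 1 for s in sizes):
            raise ValueError("block sizes must be positive")
        if sum(sizes) != n:
            raise ValueError("sizes must sum to n")
        if len(sizes) > l:
            raise ValueError("more blocks than labels")
        yield from _sized_partitions(n, sizes)
    else:
        yield from _rgs_partitions(n, l)


def hamming_ball(
    center: Partition, radius: int, universe: Iterable[Partition]
) -> list:
    """Members of ``universe`` within partition distance ``radius`` of
    ``center`` (order preserved)."""
    if radius < 0:
        raise ValueError("radius must be >= 0")
    return [p for p in universe if partition_distance(center, p) <= radius]
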