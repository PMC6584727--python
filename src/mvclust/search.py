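"""Partition-risk minimization: exact (Optimal) and suboptimal (Pmax, Pseed).

The Bayes clusterer minimizes the expected cluster mismatch error

    risk(C) = sum_P cost(C, P) * P(P | S)

over candidate partitions C, where the posterior runs over a reference set
of partitions.  ``optimal_cluster`` uses the full reference set (optionally
constrained to the correct cluster sizes) and all 2^(n-1) candidates (l=2).
``pmax_cluster`` restricts the reference set to a Hamming ball around the
maximum-probability size-constrained partition; ``pseed_cluster`` first
hill-climbs to a (possibly local) MAP partition from random seeds and then
constrains both reference and candidate sets to size-matching partitions
near it.  Tie-breaking everywhere is the lexicographically smallest
canonical partition, so runs are reproducible.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.special import logsumexp

from . import _fast
from .models import (
    ModelSpec,
    draw_covariances,
    log_posterior,
    partition_log_probability,
    pointwise_log_density_table,
)
from .partitions import (
    Labeling,
    Partition,
    canonicalize,
    enumerate_partitions,
    hamming_ball,
    partition_cost,
)
from .pointset import PointSet

__all__ = [
    "SearchConfig",
    "SearchResult",
    "partition_risk",
    "optimal_cluster",
    "map_partition",
    "pmax_cluster",
    "pseed_cluster",
]


@dataclass
class SearchConfig:
    strategy: str = "optimal"  # optimal | pmax | pseed
    radius: int = 1
    cluster_sizes: Optional[Sequence[int]] = None
    n_seeds: int = 5
    seed: Optional[int] = None
    tie_break: str = "lexicographic"
    seed_search_respect_sizes: bool = False
    max_enum_n: int = 25
    engine: str = "auto"  # auto | enum | fast

    def __post_init__(self):
        if self.radius < 0:
            raise ValueError("radius must be >= 0")
        if self.n_seeds < 1:
            raise ValueError("n_seeds must be >= 1")


@dataclass
class SearchResult:
    partition: Partition
    risk: float
    center: Optional[Partition] = None
    n_reference: int = 0

    def __iter__(self):  # allow (partition, risk) unpacking
        yield self.partition
        yield self.risk


def partition_risk(candidate: Partition, reference) -> float:
    """Expected partition cost of ``candidate`` under a normalized table of
    (Partition, probability) pairs."""
    pairs = list(reference)
    total_p = sum(p for _, p in pairs)
    if abs(total_p - 1.0) > 1e-6:
        raise ValueError("reference probabilities must sum to 1")
    return float(sum(p * partition_cost(candidate, q) for q, p in pairs))


# ---------------------------------------------------------------------------
# bitmask helpers (l = 2)

def _part_to_mask(p: Partition) -> int:
    """Bipartition -> n-bit mask; bit (i-1) set iff point i is not in the
    block containing point 1 (so the mask of point 1 is always 0)."""
    if p.n_blocks == 1:
        return 0
    b2 = p.blocks[1]
    m = 0
    for x in b2:
        m |= 1 << (x - 1)
    return m


def _mask_to_part(mask: int, n: int) -> Partition:
    b1 = [i + 1 for i in range(n) if not (mask >> i) & 1]
    b2 = [i + 1 for i in range(n) if (mask >> i) & 1]
    return Partition([b1, b2] if b2 else [b1])


def _popcount(a: np.ndarray) -> np.ndarray:
    return np.bitwise_count(a)


def _risk_argmin_l2(cand_masks: np.ndarray, ref_masks: np.ndarray,
                    probs: np.ndarray, n: int):
    """Argmin of risk over candidate masks; returns (mask_list_of_ties, risk)."""
    cand_masks = cand_masks.astype(np.uint64)
    ref_masks = ref_masks.astype(np.uint64)
    best = math.inf
    tie_masks: list = []
    chunk = max(1, int(2e7) // max(1, ref_masks.size))
    for s in range(0, cand_masks.size, chunk):
        cm = cand_masks[s : s + chunk]
        t = _popcount(cm[:, None] ^ ref_masks[None, :]).astype(np.float64)
        np.minimum(t, n - t, out=t)
        risks = (t / n) @ probs
        i = int(np.argmin(risks))
        lo = risks[i]
        if lo < best - 1e-12:
            best = float(lo)
            tie_masks = []
        if lo <= best + 1e-12:
            tie_masks.extend(int(m) for m in cm[risks <= best + 1e-12])
    return tie_masks, best


def _canonical_min(parts: Iterable[Partition]) -> Partition:
    return min(parts)


def _risk_argmin_generic(candidates, ref_parts, probs):
    best = math.inf
    ties: list = []
    for cand in candidates:
        r = float(sum(p * partition_cost(cand, q) for q, p in zip(ref_parts, probs)))
        if r < best - 1e-12:
            best = r
            ties = [cand]
        elif r <= best + 1e-12:
            ties.append(cand)
    return ties, best


class _Scorer:
    """Caches labeling log posteriors within one search call.

    Hill climbing, MAP search and reference normalization repeatedly visit
    the same labelings; the posterior of a labeling is deterministic given
    the (shared) covariance draws, so caching is exact.
    """

    def __init__(self, S: PointSet, model: ModelSpec, draws):
        self.S = S
        self.model = model
        self.draws = draws
        self._memo: dict = {}

    def labeling(self, labels: tuple) -> float:
        v = self._memo.get(labels)
        if v is None:
            v = log_posterior(
                self.S, Labeling(labels, l=self.model.l), self.model, self.draws
            )
            self._memo[labels] = v
        return v

    def partition(self, p: Partition) -> float:
        from .models import _inducing_labelings

        vals = [
            self.labeling(tuple(lab.labels))
            for lab in _inducing_labelings(p, self.model.l)
        ]
        return float(logsumexp(vals))

    def normalize(self, partitions):
        partitions = list(partitions)
        if not partitions:
            raise ValueError("reference set must be nonempty")
        logs = np.array([self.partition(p) for p in partitions])
        probs = np.exp(logs - logsumexp(logs))
        probs /= probs.sum()
        return partitions, probs


# ---------------------------------------------------------------------------
# fast path (known variant, l = 2, size-constrained reference)

def _fast_applicable(S: PointSet, model: ModelSpec, cfg: SearchConfig) -> bool:
    return (
        model.variant == "known"
        and model.l == 2
        and cfg.cluster_sizes is not None
        and len(cfg.cluster_sizes) == 2
        and model.label_prior == "uniform"
        and model.label_weights is None
    )


def _loglik_tables(S: PointSet, model: ModelSpec):
    L = pointwise_log_density_table(S, model)
    delta = L[:, 0] - L[:, 1]
    T1 = float(L[:, 0].sum())
    T2 = float(L[:, 1].sum())
    return L, delta, T1, T2


def _optimal_fast(S: PointSet, model: ModelSpec, cfg: SearchConfig) -> SearchResult:
    n = S.n
    sizes = sorted(int(s) for s in cfg.cluster_sizes)
    _, delta, T1, T2 = _loglik_tables(S, model)
    n1 = sizes[1]  # size of the subset used to sweep the reference set
    equal = sizes[0] == sizes[1]
    phi, ties, n_ties = _fast.optimal_scan(delta, T1, T2, n1, equal)
    parts = []
    for j in range(n_ties):
        c = int(ties[j])
        # code bit j => point n-1-j negative; convert to mask (bit i => point i+1)
        mask = 0
        for pt in range(1, n):
            if (c >> (n - 1 - pt)) & 1:
                mask |= 1 << pt
        parts.append(_mask_to_part(mask, n))
    best = _canonical_min(parts)
    risk = 0.5 - phi / (2.0 * n)
    return SearchResult(best, float(risk), None, 0)


def _map_fast(S: PointSet, model: ModelSpec, sizes) -> Partition:
    """MAP size-constrained bipartition for the factorized known model.

    The partition log probability logaddexp(T2 + D, T1 - D) is convex in
    D = sum of per-point log-likelihood ratios over the cluster-1 block, so
    the maximum over blocks of fixed size is attained at an extreme D: the
    top-n1 or bottom-n1 points ranked by delta."""
    _, delta, T1, T2 = _loglik_tables(S, model)
    sizes = sorted(int(s) for s in sizes)
    n1 = sizes[1]
    order = np.argsort(-delta, kind="stable")
    cands = []
    for pick in (order[:n1], order[-n1:]):
        block1 = sorted(int(i) + 1 for i in pick)
        block2 = sorted(set(range(1, S.n + 1)) - set(block1))
        p = Partition([block1, block2] if block2 else [block1])
        D = float(delta[pick].sum())
        score = np.logaddexp(T2 + D, T1 - D)
        cands.append((score, p))
    best_score = max(s for s, _ in cands)
    return _canonical_min(p for s, p in cands if s >= best_score - 1e-12)


# ---------------------------------------------------------------------------
# public operations

def _guard(n: int, cfg: SearchConfig):
    if n > cfg.max_enum_n:
        raise ValueError(
            f"enumeration over partitions of n={n} points exceeds the guard "
            f"(max_enum_n={cfg.max_enum_n})"
        )


def _prepare_draws(S, model, cfg, draws):
    if model.variant == "niw" and draws is None:
        draws = draw_covariances(model, cfg.seed)
    return draws


def optimal_cluster(
    S: PointSet, model: ModelSpec, cfg: SearchConfig, draws=None
) -> SearchResult:
    """Exact Bayes clusterer: argmin of partition risk.

    Reference set: all partitions matching ``cfg.cluster_sizes`` (or all
    partitions of at most l blocks when no sizes are given).  Candidate
    set: all partitions of at most l blocks.  Exact; deterministic
    tie-break by canonical order.
    """
    n = S.n
    draws = _prepare_draws(S, model, cfg, draws)
    use_fast = cfg.engine == "fast" or (
        cfg.engine == "auto" and _fast_applicable(S, model, cfg) and n > 12
    )
    if use_fast:
        if not _fast_applicable(S, model, cfg):
            raise ValueError("fast engine requires known variant, l=2, sizes")
        return _optimal_fast(S, model, cfg)
    _guard(n, cfg)
    scorer = _Scorer(S, model, draws)
    refs = list(enumerate_partitions(n, model.l, cfg.cluster_sizes))
    refs, probs = scorer.normalize(refs)
    if model.l == 2:
        ref_masks = np.array([_part_to_mask(p) for p in refs], dtype=np.uint64)
        cand_masks = np.arange(1 << (n - 1), dtype=np.uint64) << np.uint64(1)
        # candidate masks must have bit 0 (point 1) clear: shift enumerates
        # every subset of points 2..n as the non-point-1 block
        tie_masks, risk = _risk_argmin_l2(cand_masks, ref_masks, probs, n)
        best = _canonical_min(_mask_to_part(m, n) for m in tie_masks)
    else:
        cands = enumerate_partitions(n, model.l)
        ties, risk = _risk_argmin_generic(cands, refs, probs)
        best = _canonical_min(ties)
    return SearchResult(best, float(risk), None, len(refs))


def _map_with_scorer(scorer: "_Scorer", universe: Iterable[Partition]) -> Partition:
    best_score = -math.inf
    ties: list = []
    empty = True
    for p in universe:
        empty = False
        s = scorer.partition(p)
        if s > best_score + 1e-12:
            best_score = s
            ties = [p]
        elif s >= best_score - 1e-12:
            ties.append(p)
    if empty:
        raise ValueError("universe must be nonempty")
    return _canonical_min(ties)


def map_partition(
    S: PointSet,
    model: ModelSpec,
    universe: Iterable[Partition],
    draws=None,
) -> Partition:
    """Highest-probability partition in ``universe`` (deterministic ties)."""
    return _map_with_scorer(_Scorer(S, model, draws), universe)


def _ball_by_moves(
    center: Partition, radius: int, sizes, l: int
) -> list:
    """Size-matching partitions within partition distance ``radius`` of
    ``center``, found by breadth-first single-point relabel moves from every
    labeling inducing the center (each move changes the distance by at most
    one, and any partition at distance r is reachable in r moves)."""
    want = tuple(sorted((int(s) for s in sizes), reverse=True))
    from .models import _inducing_labelings

    frontier = {tuple(lab.labels) for lab in _inducing_labelings(center, l)}
    seen_lab = set(frontier)
    found = {}
    for lab in frontier:
        part = canonicalize(Labeling(lab, l=l))
        if part.sizes() == want:
            found[part] = None
    for _ in range(radius):
        nxt = set()
        for lab in frontier:
            for i in range(len(lab)):
                for newlab in range(1, l + 1):
                    if newlab == lab[i]:
                        continue
                    cand = lab[:i] + (newlab,) + lab[i + 1 :]
                    if cand in seen_lab:
                        continue
                    seen_lab.add(cand)
                    nxt.add(cand)
                    part = canonicalize(Labeling(cand, l=l))
                    if part.sizes() == want and part not in found:
                        found[part] = None
        frontier = nxt
    return sorted(found)


def _sized_ball(S, model, cfg, center, draws):
    """Reference ball: size-matching partitions within cfg.radius of center."""
    n = S.n
    if cfg.radius <= 2:
        ball = _ball_by_moves(center, cfg.radius, cfg.cluster_sizes, model.l)
    else:
        _guard(n, cfg)
        universe = enumerate_partitions(n, model.l, cfg.cluster_sizes)
        ball = hamming_ball(center, cfg.radius, universe)
    if not ball:
        raise ValueError(
            "empty reference ball: no size-matching partition within radius "
            f"{cfg.radius} of the center"
        )
    return ball


def pmax_cluster(
    S: PointSet, model: ModelSpec, cfg: SearchConfig, draws=None
) -> SearchResult:
    """Suboptimal clusterer: reference set restricted to a Hamming ball
    around the MAP size-constrained partition; candidates unrestricted."""
    if cfg.cluster_sizes is None:
        raise ValueError("pmax requires cluster_sizes")
    n = S.n
    draws = _prepare_draws(S, model, cfg, draws)
    scorer = _Scorer(S, model, draws)
    fast = cfg.engine != "enum" and _fast_applicable(S, model, cfg)
    if fast:
        center = _map_fast(S, model, cfg.cluster_sizes)
    else:
        _guard(n, cfg)
        universe = enumerate_partitions(n, model.l, cfg.cluster_sizes)
        center = _map_with_scorer(scorer, universe)
    refs = _sized_ball(S, model, cfg, center, draws)
    refs, probs = scorer.normalize(refs)
    if len(refs) == 1:
        # the sole minimizer of cost against a singleton reference is itself
        return SearchResult(refs[0], 0.0, center, 1)
    if model.l == 2:
        ref_masks = np.array([_part_to_mask(p) for p in refs], dtype=np.uint64)
        if n > cfg.max_enum_n:
            raise ValueError("candidate scan exceeds enumeration guard")
        cand_masks = np.arange(1 << (n - 1), dtype=np.uint64) << np.uint64(1)
        tie_masks, risk = _risk_argmin_l2(cand_masks, ref_masks, probs, n)
        best = _canonical_min(_mask_to_part(m, n) for m in tie_masks)
    else:
        _guard(n, cfg)
        ties, risk = _risk_argmin_generic(
            enumerate_partitions(n, model.l), refs, probs
        )
        best = _canonical_min(ties)
    return SearchResult(best, float(risk), center, len(refs))


def _random_sized_labeling(n: int, sizes, rng) -> Labeling:
    order = rng.permutation(n)
    labels = np.empty(n, dtype=np.int64)
    pos = 0
    for i, s in enumerate(sizes, start=1):
        labels[order[pos : pos + s]] = i
        pos += s
    return Labeling(labels.tolist(), l=len(sizes))


def _hill_climb(scorer: "_Scorer", labeling: Labeling, cfg):
    """Steepest-ascent local search on the partition log probability over
    single-point relabel moves (or swap moves when sizes are enforced)."""
    l = scorer.model.l
    cur = list(labeling.labels)

    def score(lab_list):
        return scorer.partition(canonicalize(Labeling(lab_list, l=l)))

    cur_score = score(cur)
    improved = True
    while improved:
        improved = False
        best_move = None
        best_score = cur_score
        if cfg.seed_search_respect_sizes:
            moves = [
                (i, j)
                for i in range(len(cur))
                for j in range(i + 1, len(cur))
                if cur[i] != cur[j]
            ]
        else:
            moves = [
                (i, lab)
                for i in range(len(cur))
                for lab in range(1, l + 1)
                if lab != cur[i]
            ]
        for mv in moves:
            cand = list(cur)
            if cfg.seed_search_respect_sizes:
                i, j = mv
                cand[i], cand[j] = cand[j], cand[i]
            else:
                i, lab = mv
                cand[i] = lab
            s = score(cand)
            if s > best_score + 1e-12:
                best_score = s
                best_move = cand
        if best_move is not None:
            cur = best_move
            cur_score = best_score
            improved = True
    return canonicalize(Labeling(cur, l=l)), cur_score


def _hill_climb_fast(S, model, labeling: Labeling, cfg):
    """O(1)-per-move hill climb for the factorized known model, l=2."""
    L, _, _, _ = _loglik_tables(S, model)
    lab = np.asarray(labeling.labels) - 1  # 0/1
    s_direct = float(L[np.arange(S.n), lab].sum())
    s_swap = float(L[np.arange(S.n), 1 - lab].sum())

    def part_score(sd, ss):
        return np.logaddexp(sd, ss)

    cur_score = part_score(s_direct, s_swap)
    if cfg.seed_search_respect_sizes:
        # fall back to the generic swap search
        return _hill_climb(_Scorer(S, model, None), labeling, cfg)
    improved = True
    while improved:
        improved = False
        best_i = -1
        best = cur_score
        best_sd = best_ss = 0.0
        for i in range(S.n):
            dd = L[i, 1 - lab[i]] - L[i, lab[i]]
            sd = s_direct + dd
            ss = s_swap - dd
            s = part_score(sd, ss)
            if s > best + 1e-12:
                best = s
                best_i = i
                best_sd, best_ss = sd, ss
        if best_i >= 0:
            lab[best_i] = 1 - lab[best_i]
            s_direct, s_swap = best_sd, best_ss
            cur_score = best
            improved = True
    return canonicalize(Labeling((lab + 1).tolist(), l=2)), float(cur_score)


def _project_center(
    center: Partition, S: PointSet, model: ModelSpec, cfg, scorer, fast: bool
) -> Partition:
    """Move the fewest points (greedily, by highest resulting partition
    probability) to bring a partition to the required block sizes.

    The unconstrained stage-1 search can end at a partition whose sizes
    differ from the target by more than the reference radius, which would
    leave the size-matching reference ball empty; anchoring the ball at the
    size-projected center keeps the procedure well defined.  Deterministic:
    ties break by point index, then target label.
    """
    want = tuple(sorted((int(s) for s in cfg.cluster_sizes), reverse=True))
    if center.sizes() == want:
        return center
    l = model.l
    labels = list(center.to_labels().labels)
    counts = [labels.count(i + 1) for i in range(l)]
    padded = list(want) + [0] * (l - len(want))
    best_perm = min(
        itertools.permutations(padded),
        key=lambda t: (sum(abs(c - ti) for c, ti in zip(counts, t)), t),
    )
    targets = list(best_perm)
    if fast:
        L, _, _, _ = _loglik_tables(S, model)

        def score(labs):
            a = np.asarray(labs) - 1
            sd = float(L[np.arange(S.n), a].sum())
            ss = float(L[np.arange(S.n), 1 - a].sum())
            return float(np.logaddexp(sd, ss))

    else:

        def score(labs):
            return scorer.partition(canonicalize(Labeling(labs, l=l)))

    while counts != targets:
        best_s, best_move = -math.inf, None
        for i, lab in enumerate(labels):
            if counts[lab - 1] <= targets[lab - 1]:
                continue
            for tl in range(1, l + 1):
                if counts[tl - 1] >= targets[tl - 1]:
                    continue
                cand = list(labels)
                cand[i] = tl
                s = score(cand)
                if s > best_s + 1e-12:
                    best_s, best_move = s, (i, tl)
        i, tl = best_move
        counts[labels[i] - 1] -= 1
        counts[tl - 1] += 1
        labels[i] = tl
    return canonicalize(Labeling(labels, l=l))


def pseed_cluster(
    S: PointSet, model: ModelSpec, cfg: SearchConfig, draws=None
) -> SearchResult:
    """Suboptimal clusterer seeded by local MAP search.

    Stage 1: from ``n_seeds`` random size-constrained initial partitions,
    steepest-ascent hill climbing on the partition log probability over
    single-point relabel moves until no improving neighbor.  Stage 2: both
    reference and candidate sets are the size-matching partitions within
    ``radius`` of the best local optimum; returns the risk argmin.
    """
    if cfg.cluster_sizes is None:
        raise ValueError("pseed requires cluster_sizes")
    draws = _prepare_draws(S, model, cfg, draws)
    rng = np.random.default_rng(cfg.seed)
    scorer = _Scorer(S, model, draws)
    fast = cfg.engine != "enum" and _fast_applicable(S, model, cfg)
    best_part, best_score = None, -math.inf
    for _ in range(cfg.n_seeds):
        init = _random_sized_labeling(S.n, list(cfg.cluster_sizes), rng)
        if fast:
            part, s = _hill_climb_fast(S, model, init, cfg)
        else:
            part, s = _hill_climb(scorer, init, cfg)
        if s > best_score + 1e-12 or (
            s >= best_score - 1e-12 and (best_part is None or part < best_part)
        ):
            best_part, best_score = part, s
    center = _project_center(best_part, S, model, cfg, scorer, fast)
    refs = _sized_ball(S, model, cfg, center, draws)
    refs, probs = scorer.normalize(refs)
    ties, risk = _risk_argmin_generic(refs, refs, probs)
    best = _canonical_min(ties)
    return SearchResult(best, float(risk), center, len(refs))
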