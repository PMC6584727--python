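"""Marginalized label-posterior models for Gaussian clusters with MCAR missingness.

Three label-conditional Gaussian variants are supported, all evaluated in
log space:

``known``
    Means and covariances of every cluster are known; the observed entries
    of a point with label i are N(M mu_i, M Sigma_i M^T) where M selects the
    observed coordinates.  Because the missingness is MCAR, the mask process
    cancels from the label posterior and the likelihood is simply the
    product of observed-margin densities.

``gaussian_mean``
    mu_i ~ N(m_i, Sigma_i / nu_i) with Sigma_i fixed.  The mean is
    marginalized in closed form by completing the square: grouping cluster
    points by missingness pattern gives per-group sufficient statistics
    (sample mean and scatter), and the Gaussian integral contributes the
    precision matrix A_i and linear term b_i assembled over pattern groups.

``niw``
    mu_i | Sigma_i ~ N(m_i, Sigma_i / nu_i) and Sigma_i ~ IW(kappa_i, Psi_i).
    The covariance integral has no closed form under general missingness,
    so it is Monte Carlo averaged over J draws Sigma_i^(j) ~ IW(kappa_i,
    Psi_i), with the ``gaussian_mean`` closed form as the integrand.  Draws
    are generated once per (cluster, point set) and reused across all
    candidate labelings (common random numbers) so that posterior rankings
    are not corrupted by independent Monte Carlo noise.

All posteriors are unnormalized: equal up to an additive constant shared
across labelings of the same point set.  Constants that depend on which
clusters are nonempty or on the pattern grouping DO differ across labelings
and are therefore kept exactly.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.linalg import cho_solve, cholesky, solve_triangular
from scipy.special import logsumexp, multigammaln
from scipy.stats import invwishart

from .partitions import Labeling, Partition
from .pointset import PointSet

__all__ = [
    "ClusterModel",
    "ModelSpec",
    "PatternGroup",
    "group_by_pattern",
    "label_prior",
    "log_posterior_known",
    "log_posterior_gaussian_mean",
    "log_posterior_niw",
    "log_posterior",
    "niw_closed_form_complete",
    "partition_log_probability",
    "normalize_over_set",
    "draw_covariances",
    "pointwise_log_density_table",
]

_LOG2PI = math.log(2.0 * math.pi)
VARIANTS = ("known", "gaussian_mean", "niw")


@dataclass(frozen=True)
class ClusterModel:
    """Per-cluster parameters/hyperparameters; unused fields may be None.

    ``known``:          mu, Sigma
    ``gaussian_mean``:  m, nu, Sigma
    ``niw``:            m, nu, kappa, Psi
    """

    mu: Optional[np.ndarray] = None
    Sigma: Optional[np.ndarray] = None
    m: Optional[np.ndarray] = None
    nu: Optional[float] = None
    kappa: Optional[float] = None
    Psi: Optional[np.ndarray] = None

    def __post_init__(self):
        for name in ("mu", "Sigma", "m", "Psi"):
            v = getattr(self, name)
            if v is not None:
                object.__setattr__(self, name, np.asarray(v, dtype=np.float64))


@dataclass
class ModelSpec:
    """Model variant tag plus per-cluster blocks and inference settings."""

    variant: str
    clusters: Sequence[ClusterModel]
    mc_draws: int = 500
    label_prior: str = "uniform"  # uniform over L^S: P(phi) = l^{-n}
    label_weights: Optional[dict] = None  # custom: {label tuple: prob}

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")
        self.clusters = list(self.clusters)
        d = self.d
        for c in self.clusters:
            if self.variant == "known":
                if c.mu is None or c.Sigma is None:
                    raise ValueError("known variant requires mu and Sigma")
            elif self.variant == "gaussian_mean":
                if c.m is None or c.Sigma is None or c.nu is None or c.nu <= 0:
                    raise ValueError("gaussian_mean requires m, Sigma, nu>0")
            else:
                if c.m is None or c.Psi is None or c.nu is None or c.kappa is None:
                    raise ValueError("niw requires m, nu, kappa, Psi")
                if c.nu <= 0 or c.kappa <= d - 1:
                    raise ValueError("niw requires nu>0 and kappa>d-1")

    @property
    def l(self) -> int:
        return len(self.clusters)

    @property
    def d(self) -> int:
        c = self.clusters[0]
        for v in (c.mu, c.m):
            if v is not None:
                return int(v.shape[0])
        raise ValueError("cluster model has no mean parameter")


@dataclass(frozen=True)
class PatternGroup:
    """Sufficient statistics of one (cluster, missingness-pattern) group."""

    label: int  # cluster label i (1-based)
    obs_idx: tuple  # J_ig, sorted 0-based observed feature indices
    rows: tuple  # member row indices (0-based)
    n_g: int
    mean: np.ndarray  # (d_g,) sample mean of observed coordinates
    scatter: np.ndarray  # (d_g, d_g) scatter matrix

    @property
    def d_g(self) -> int:
        return len(self.obs_idx)


def group_by_pattern(S: PointSet, labeling: Labeling, i: int) -> list:
    """Split cluster-``i`` points into groups sharing an observed-feature
    set, with per-group sample mean and scatter (observed entries only).

    Rows with no observed features form a d_g = 0 group (they contribute
    only the label prior downstream).  Groups are ordered by pattern for
    determinism.
    """
    if labeling.n != S.n:
        raise ValueError("labeling length must match point count")
    rows = [r for r in range(S.n) if labeling.labels[r] == i]
    by_pattern: dict = {}
    for r in rows:
        by_pattern.setdefault(S.observed_pattern(r), []).append(r)
    groups = []
    for pattern in sorted(by_pattern):
        members = by_pattern[pattern]
        idx = np.asarray(pattern, dtype=np.int64)
        X = S.values[np.asarray(members)][:, idx]
        if len(pattern) == 0:
            mean = np.zeros(0)
            scatter = np.zeros((0, 0))
        else:
            mean = X.mean(axis=0)
            D = X - mean
            scatter = D.T @ D
        groups.append(
            PatternGroup(
                label=i,
                obs_idx=pattern,
                rows=tuple(members),
                n_g=len(members),
                mean=mean,
                scatter=scatter,
            )
        )
    return groups


def _chol(M: np.ndarray) -> np.ndarray:
    """Upper Cholesky factor; tiny diagonal jitter only on failure."""
    try:
        return cholesky(M, lower=False)
    except np.linalg.LinAlgError:
        jitter = 1e-9 * float(np.mean(np.diag(M))) + 1e-300
        return cholesky(M + jitter * np.eye(M.shape[0]), lower=False)


def _logdet(U: np.ndarray) -> float:
    return 2.0 * float(np.sum(np.log(np.diag(U))))


def label_prior(labeling: Labeling, model: ModelSpec) -> float:
    """log P(phi_S); default uniform over L^S, i.e. -n log l."""
    if model.label_weights is not None:
        try:
            return math.log(model.label_weights[tuple(labeling.labels)])
        except KeyError:
            return -math.inf
    if model.label_prior == "uniform":
        return -labeling.n * math.log(model.l)
    raise ValueError(f"unknown label prior {model.label_prior!r}")


def _loglik_known_cluster(groups: list, mu: np.ndarray, Sigma: np.ndarray) -> float:
    """Sum of observed-margin Gaussian log densities for one cluster."""
    total = 0.0
    for g in groups:
        if g.d_g == 0:
            continue
        idx = np.asarray(g.obs_idx)
        Sig = Sigma[np.ix_(idx, idx)]
        U = _chol(Sig)
        dev = g.mean - mu[idx]
        w = solve_triangular(U, dev, trans="T")
        tr = float(np.sum(cho_solve((U, False), g.scatter) * np.eye(g.d_g)))
        total += (
            -0.5 * g.n_g * (g.d_g * _LOG2PI + _logdet(U))
            - 0.5 * tr
            - 0.5 * g.n_g * float(w @ w)
        )
    return total


def _log_marginal_mean_cluster(
    groups: list, Sigma: np.ndarray, m: np.ndarray, nu: float
) -> float:
    """Exact log marginal likelihood of one cluster's observed data with the
    Gaussian mean prior integrated out at fixed covariance ``Sigma``.

    Assembles the posterior precision A = sum_g n_g M^T Sigma_g^{-1} M
    + nu Sigma^{-1} and linear term b over pattern groups, then applies the
    completed-square Gaussian integral.  Includes all constants (exact up to
    nothing), so it doubles as the Monte Carlo integrand for the NIW model.
    """
    d = Sigma.shape[0]
    obs_groups = [g for g in groups if g.d_g > 0]
    if not obs_groups:
        return 0.0
    U_S = _chol(Sigma)
    Sigma_inv = cho_solve((U_S, False), np.eye(d))
    A = nu * Sigma_inv
    b = nu * (Sigma_inv @ m)
    quad = nu * float(m @ Sigma_inv @ m)
    group_terms = 0.0
    for g in obs_groups:
        idx = np.asarray(g.obs_idx)
        Sig_g = Sigma[np.ix_(idx, idx)]
        U = _chol(Sig_g)
        Sig_g_inv = cho_solve((U, False), np.eye(g.d_g))
        tr = float(np.sum(Sig_g_inv * g.scatter))
        group_terms += -0.5 * g.n_g * (g.d_g * _LOG2PI + _logdet(U)) - 0.5 * tr
        A[np.ix_(idx, idx)] += g.n_g * Sig_g_inv
        b[idx] += g.n_g * (Sig_g_inv @ g.mean)
        quad += g.n_g * float(g.mean @ Sig_g_inv @ g.mean)
    U_A = _chol(A)
    bAb = float(np.sum(solve_triangular(U_A, b, trans="T") ** 2))
    return (
        group_terms
        + 0.5 * d * math.log(nu)
        - 0.5 * _logdet(U_S)
        - 0.5 * _logdet(U_A)
        - 0.5 * (quad - bAb)
    )


def _log_marginal_mean_cluster_batch(
    groups: list, Sigmas: np.ndarray, m: np.ndarray, nu: float
) -> np.ndarray:
    """Vectorized :func:`_log_marginal_mean_cluster` over a (J, d, d) batch
    of covariance matrices (the Monte Carlo integrand for the NIW model).
    Identical algebra, batched Cholesky factorizations."""
    J, d, _ = Sigmas.shape
    obs_groups = [g for g in groups if g.d_g > 0]
    if not obs_groups:
        return np.zeros(J)

    def batch_chol(M):
        try:
            return np.linalg.cholesky(M)
        except np.linalg.LinAlgError:
            jit = 1e-9 * np.mean(np.trace(M, axis1=-2, axis2=-1)) / M.shape[-1]
            return np.linalg.cholesky(M + jit * np.eye(M.shape[-1]))

    L_S = batch_chol(Sigmas)
    logdet_S = 2.0 * np.sum(np.log(np.diagonal(L_S, axis1=-2, axis2=-1)), axis=-1)
    eye = np.broadcast_to(np.eye(d), (J, d, d))
    Sigma_inv = np.linalg.solve(Sigmas, eye)
    A = nu * Sigma_inv
    b = nu * (Sigma_inv @ m)
    quad = nu * np.einsum("i,jik,k->j", m, Sigma_inv, m)
    group_terms = np.zeros(J)
    for g in obs_groups:
        idx = np.asarray(g.obs_idx)
        Sg = Sigmas[:, idx[:, None], idx[None, :]]
        Lg = batch_chol(Sg)
        logdet_g = 2.0 * np.sum(np.log(np.diagonal(Lg, axis1=-2, axis2=-1)), axis=-1)
        Sg_inv = np.linalg.solve(Sg, np.broadcast_to(np.eye(g.d_g), Sg.shape))
        tr = np.einsum("jab,ab->j", Sg_inv, g.scatter)
        group_terms += (
            -0.5 * g.n_g * (g.d_g * _LOG2PI + logdet_g) - 0.5 * tr
        )
        A[:, idx[:, None], idx[None, :]] += g.n_g * Sg_inv
        b[:, idx] += g.n_g * (Sg_inv @ g.mean)
        quad += g.n_g * np.einsum("a,jab,b->j", g.mean, Sg_inv, g.mean)
    L_A = batch_chol(A)
    logdet_A = 2.0 * np.sum(np.log(np.diagonal(L_A, axis1=-2, axis2=-1)), axis=-1)
    bAb = np.einsum("ja,ja->j", b, np.linalg.solve(A, b[..., None])[..., 0])
    return (
        group_terms
        + 0.5 * d * math.log(nu)
        - 0.5 * logdet_S
        - 0.5 * logdet_A
        - 0.5 * (quad - bAb)
    )


def log_posterior_known(S: PointSet, labeling: Labeling, model: ModelSpec) -> float:
    """Unnormalized log posterior of a labeling, known means/covariances."""
    total = label_prior(labeling, model)
    for i in range(1, model.l + 1):
        groups = group_by_pattern(S, labeling, i)
        if groups:
            c = model.clusters[i - 1]
            total += _loglik_known_cluster(groups, c.mu, c.Sigma)
    return total


def log_posterior_gaussian_mean(
    S: PointSet, labeling: Labeling, model: ModelSpec
) -> float:
    """Unnormalized log posterior, Gaussian mean prior marginalized."""
    total = label_prior(labeling, model)
    for i in range(1, model.l + 1):
        groups = group_by_pattern(S, labeling, i)
        if groups:
            c = model.clusters[i - 1]
            total += _log_marginal_mean_cluster(groups, c.Sigma, c.m, c.nu)
    return total


def log_posterior_niw(
    S: PointSet, labeling: Labeling, model: ModelSpec, draws: Sequence[np.ndarray]
) -> float:
    """Unnormalized log posterior under the NIW model via Monte Carlo.

    ``draws`` holds, per cluster, a (J, d, d) array of covariance samples
    from IW(kappa_i, Psi_i); the cluster integral is the log-mean-exp of
    the fixed-covariance marginal over the draws.
    """
    total = label_prior(labeling, model)
    for i in range(1, model.l + 1):
        groups = group_by_pattern(S, labeling, i)
        if not groups:
            continue
        c = model.clusters[i - 1]
        D = np.asarray(draws[i - 1])
        if D.ndim != 3 or D.shape[0] == 0:
            raise ValueError("draws must be per-cluster (J, d, d) arrays with J>=1")
        vals = _log_marginal_mean_cluster_batch(groups, D, c.m, c.nu)
        total += float(logsumexp(vals) - math.log(D.shape[0]))
    return total


def log_posterior(
    S: PointSet,
    labeling: Labeling,
    model: ModelSpec,
    draws: Optional[Sequence[np.ndarray]] = None,
) -> float:
    """Dispatch on the model variant."""
    if model.variant == "known":
        return log_posterior_known(S, labeling, model)
    if model.variant == "gaussian_mean":
        return log_posterior_gaussian_mean(S, labeling, model)
    if draws is None:
        raise ValueError("niw variant requires covariance draws")
    return log_posterior_niw(S, labeling, model, draws)


def niw_closed_form_complete(
    S: PointSet, labeling: Labeling, model: ModelSpec
) -> float:
    """Exact NIW log marginal posterior, valid only for complete data.

    Standard conjugate result: per cluster with n points, sample mean xbar
    and scatter Sc,

        log f = -(n d / 2) log pi + (d/2) log(nu / (nu+n))
                + log Gamma_d((kappa+n)/2) - log Gamma_d(kappa/2)
                + (kappa/2) log|Psi| - ((kappa+n)/2) log|Psi_n|,

    with Psi_n = Psi + Sc + (nu n / (nu+n)) (xbar-m)(xbar-m)^T.  Serves as
    the convergence target for the Monte Carlo estimator.
    """
    if not S.is_complete:
        raise ValueError("closed form requires a fully observed point set")
    if model.variant != "niw":
        raise ValueError("closed form applies to the niw variant")
    d = S.d
    total = label_prior(labeling, model)
    lab = labeling.as_array()
    for i in range(1, model.l + 1):
        X = S.values[lab == i]
        n = X.shape[0]
        if n == 0:
            continue
        c = model.clusters[i - 1]
        xbar = X.mean(axis=0)
        Dev = X - xbar
        Sc = Dev.T @ Dev
        dm = xbar - c.m
        Psi_n = c.Psi + Sc + (c.nu * n / (c.nu + n)) * np.outer(dm, dm)
        total += (
            -0.5 * n * d * math.log(math.pi)
            + 0.5 * d * (math.log(c.nu) - math.log(c.nu + n))
            + multigammaln((c.kappa + n) / 2.0, d)
            - multigammaln(c.kappa / 2.0, d)
            + 0.5 * c.kappa * _logdet(_chol(c.Psi))
            - 0.5 * (c.kappa + n) * _logdet(_chol(Psi_n))
        )
    return total


def _inducing_labelings(p: Partition, l: int) -> list:
    """All labelings inducing partition ``p`` (injective block->label maps)."""
    k = p.n_blocks
    if k > l:
        raise ValueError("partition has more blocks than labels")
    block_of = p.block_of()
    out = []
    for perm in itertools.permutations(range(1, l + 1), k):
        out.append(Labeling([perm[b] for b in block_of], l=l))
    return out


def partition_log_probability(
    p: Partition,
    S: PointSet,
    model: ModelSpec,
    draws: Optional[Sequence[np.ndarray]] = None,
) -> float:
    """log of the (unnormalized) partition probability: log-sum-exp of the
    labeling posterior over all labelings inducing ``p``.  For the NIW
    variant the same covariance draws are reused across all labelings."""
    vals = [log_posterior(S, lab, model, draws) for lab in _inducing_labelings(p, model.l)]
    return float(logsumexp(vals))


def normalize_over_set(
    partitions: Sequence[Partition],
    S: PointSet,
    model: ModelSpec,
    draws: Optional[Sequence[np.ndarray]] = None,
):
    """Posterior probabilities of a reference set of partitions, normalized
    to sum to one over the set.  Returns (list_of_partitions, probs)."""
    partitions = list(partitions)
    if not partitions:
        raise ValueError("reference set must be nonempty")
    logs = np.array(
        [partition_log_probability(p, S, model, draws) for p in partitions]
    )
    probs = np.exp(logs - logsumexp(logs))
    probs /= probs.sum()
    return partitions, probs


def draw_covariances(model: ModelSpec, rng) -> list:
    """Per-cluster (J, d, d) IW(kappa_i, Psi_i) covariance samples.

    Generated once per point set and shared across every candidate labeling
    so that Monte Carlo noise cancels from posterior comparisons.
    """
    if model.variant != "niw":
        raise ValueError("covariance draws only apply to the niw variant")
    rng = np.random.default_rng(rng)
    J = int(model.mc_draws)
    if J < 1:
        raise ValueError("mc_draws must be >= 1")
    d = model.d
    out = []
    for c in model.clusters:
        D = invwishart.rvs(df=c.kappa, scale=c.Psi, size=J, random_state=rng)
        out.append(np.asarray(D).reshape(J, d, d))
    return out


def pointwise_log_density_table(S: PointSet, model: ModelSpec) -> np.ndarray:
    """(n, l) table of per-point observed-margin log densities under the
    ``known`` variant.  Because points are conditionally independent given
    known parameters, the labeling log likelihood is the sum of table
    entries along the labeling — the backbone of the fast search paths."""
    if model.variant != "known":
        raise ValueError("density table requires the known variant")
    n, l = S.n, model.l
    out = np.zeros((n, l))
    # factor per unique pattern to reuse Cholesky factors
    by_pattern: dict = {}
    for r in range(n):
        by_pattern.setdefault(S.observed_pattern(r), []).append(r)
    for pattern, rows in by_pattern.items():
        if len(pattern) == 0:
            continue
        idx = np.asarray(pattern)
        X = S.values[np.asarray(rows)][:, idx]
        for i, c in enumerate(model.clusters):
            U = _chol(c.Sigma[np.ix_(idx, idx)])
            W = solve_triangular(U, (X - c.mu[idx]).T, trans="T")
            logdens = (
                -0.5 * len(pattern) * _LOG2PI
                - 0.5 * _logdet(U)
                - 0.5 * np.sum(W * W, axis=0)
            )
            out[np.asarray(rows), i] = logdens
    return out
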