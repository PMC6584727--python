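"""Comparison clusterers.

Missing-data-native methods (k-POD, fuzzy c-means with the optimal
completion strategy), impute-then-cluster pipelines (a multivariate-normal
Gibbs sampler feeding k-means, fuzzy c-means and hierarchical clustering),
and the completely random clusterer.  Every method consumes the same masked
:class:`~mvclust.pointset.PointSet` the optimal clusterers see — nothing
here reads a hidden value.

k-POD and FCM-OCS internals follow the standard formulations
(majorize-minimize alternating k-means with centroid refills; missing
cells as optimization variables updated as membership-weighted centroid
averages).  The Gibbs imputer alternates conditional draws of the missing
entries and conjugate Normal-inverse-Wishart draws of the mean and
covariance, and imputes with the posterior mean over post-burn-in draws.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.stats import invwishart
from sklearn.cluster import KMeans

from .partitions import Labeling, Partition, canonicalize
from .pointset import PointSet

__all__ = [
    "BaselineConfig",
    "kpod_cluster",
    "fcm_ocs_cluster",
    "gibbs_impute",
    "classic_cluster",
    "random_cluster",
]


@dataclass
class BaselineConfig:
    k: int = 2
    fuzzifier: float = 2.0  # FCM family exponent, > 1
    max_iter: int = 100
    tol: float = 1e-6
    seed: Optional[object] = None
    gibbs_burnin: int = 50
    gibbs_draws: int = 100
    fcm_init_threshold: float = 0.2  # missing-rate switch for FCM-OCS init

    def __post_init__(self):
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.fuzzifier <= 1:
            raise ValueError("fuzzifier must be > 1")


def _labels_to_partition(labels) -> Partition:
    return canonicalize(Labeling(np.asarray(labels, dtype=int) + 1))


def _mean_fill(S: PointSet) -> np.ndarray:
    X = S.values.copy()
    col_means = np.where(
        S.observed.any(axis=0),
        np.nanmean(np.where(S.observed, S.values, np.nan), axis=0),
        0.0,
    )
    miss = ~S.observed
    X[miss] = np.broadcast_to(col_means, X.shape)[miss]
    return X


def kpod_cluster(S: PointSet, cfg: BaselineConfig) -> Partition:
    """k-POD: alternate k-means on the completed table with refills of the
    missing cells from the assigned centroids (majorize-minimize; the
    observed-cell squared-residual objective is non-increasing)."""
    if cfg.k > S.n:
        raise ValueError("k must not exceed the number of points")
    rng = np.random.default_rng(cfg.seed)
    X = _mean_fill(S)
    miss = ~S.observed
    labels_prev = None
    centers = None
    for _ in range(cfg.max_iter):
        if centers is None:
            km = KMeans(
                n_clusters=cfg.k,
                n_init=10,
                random_state=int(rng.integers(2**31 - 1)),
            ).fit(X)
        else:
            km = KMeans(n_clusters=cfg.k, init=centers, n_init=1).fit(X)
        labels = km.labels_
        centers = km.cluster_centers_
        X[miss] = centers[labels][miss]
        if labels_prev is not None and np.array_equal(labels, labels_prev):
            break
        labels_prev = labels
    return _labels_to_partition(labels)


def _fcm(X, k, m, max_iter, tol, rng, init_centers=None):
    """Plain fuzzy c-means (alternating memberships/centers)."""
    n = X.shape[0]
    if init_centers is None:
        idx = rng.choice(n, size=k, replace=False)
        centers = X[idx].copy()
    else:
        centers = np.array(init_centers, dtype=float, copy=True)
    U = None
    for _ in range(max_iter):
        d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        d2 = np.maximum(d2, 1e-12)
        inv = d2 ** (-1.0 / (m - 1.0))
        U = inv / inv.sum(axis=1, keepdims=True)
        Um = U**m
        new_centers = (Um.T @ X) / Um.sum(axis=0)[:, None]
        shift = np.abs(new_centers - centers).max()
        centers = new_centers
        if shift < tol:
            break
    return centers, U


def fcm_ocs_cluster(
    S: PointSet, cfg: BaselineConfig, missing_rate_hint: Optional[float] = None
) -> Partition:
    """Fuzzy c-means with the optimal completion strategy.

    Missing cells are treated as additional optimization variables, updated
    each iteration as the membership-weighted average of the cluster
    centers.  Initial centers come from plain FCM on the fully observed
    points when the missing rate is low; at higher rates (or when too few
    complete rows exist) the data are mean-imputed first and FCM is run on
    all points.  The hard partition assigns each point to its maximal
    membership.
    """
    rng = np.random.default_rng(cfg.seed)
    rate = S.missing_fraction() if missing_rate_hint is None else missing_rate_hint
    complete_rows = S.observed.all(axis=1)
    X0 = _mean_fill(S)
    if rate < cfg.fcm_init_threshold and complete_rows.sum() >= cfg.k:
        centers, _ = _fcm(
            S.values[complete_rows], cfg.k, cfg.fuzzifier, cfg.max_iter, cfg.tol, rng
        )
    else:
        centers, _ = _fcm(X0, cfg.k, cfg.fuzzifier, cfg.max_iter, cfg.tol, rng)
    X = X0
    miss = ~S.observed
    U = None
    for _ in range(cfg.max_iter):
        d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        d2 = np.maximum(d2, 1e-12)
        inv = d2 ** (-1.0 / (cfg.fuzzifier - 1.0))
        U = inv / inv.sum(axis=1, keepdims=True)
        Um = U**cfg.fuzzifier
        new_centers = (Um.T @ X) / Um.sum(axis=0)[:, None]
        # optimal completion: refill missing cells from weighted centers
        fill = (Um @ new_centers) / Um.sum(axis=1, keepdims=True)
        X[miss] = fill[miss]
        shift = np.abs(new_centers - centers).max()
        centers = new_centers
        if shift < cfg.tol:
            break
    return _labels_to_partition(np.argmax(U, axis=1))


def gibbs_impute(S: PointSet, cfg: BaselineConfig) -> np.ndarray:
    """Impute missing entries with a multivariate-normal Gibbs sampler.

    A single Gaussian is fit to all points: the sampler alternates (i)
    drawing each row's missing entries from their normal conditional given
    the observed entries and the current (mean, covariance), and (ii)
    drawing (mean, covariance) from a weakly-informative conjugate
    Normal-inverse-Wishart posterior given the completed table.  The
    returned table has observed cells untouched and missing cells set to
    their posterior mean across post-burn-in sweeps.
    """
    rng = np.random.default_rng(cfg.seed)
    n, d = S.n, S.d
    if not (~S.observed).any():
        return S.values.copy()
    X = _mean_fill(S)
    miss_rows = [r for r in range(n) if not S.observed[r].all()]
    # weak NIW prior centered on the observed-data moments; ridge keeps the
    # scale matrix PD when n is close to d
    m0 = X.mean(axis=0)
    obs_var = np.nanvar(np.where(S.observed, S.values, np.nan), axis=0)
    obs_var = np.where(np.isfinite(obs_var) & (obs_var > 0), obs_var, 1.0)
    Psi0 = np.diag(obs_var) + 1e-6 * np.eye(d)
    nu0, kappa0 = 1.0, d + 2.0
    acc = np.zeros_like(X)
    n_acc = 0
    for it in range(cfg.gibbs_burnin + cfg.gibbs_draws):
        xbar = X.mean(axis=0)
        Dev = X - xbar
        Sc = Dev.T @ Dev
        nu_n = nu0 + n
        m_n = (nu0 * m0 + n * xbar) / nu_n
        dm = xbar - m0
        Psi_n = Psi0 + Sc + (nu0 * n / nu_n) * np.outer(dm, dm)
        Psi_n = 0.5 * (Psi_n + Psi_n.T)
        Sigma = np.atleast_2d(
            invwishart.rvs(df=kappa0 + n, scale=Psi_n, random_state=rng)
        )
        mu = rng.multivariate_normal(m_n, Sigma / nu_n)
        for r in miss_rows:
            o = S.observed[r]
            mi = ~o
            if o.any():
                Soo = Sigma[np.ix_(o, o)]
                Smo = Sigma[np.ix_(mi, o)]
                sol = np.linalg.solve(Soo, (X[r, o] - mu[o]))
                cond_mean = mu[mi] + Smo @ sol
                cond_cov = Sigma[np.ix_(mi, mi)] - Smo @ np.linalg.solve(
                    Soo, Smo.T
                )
                cond_cov = 0.5 * (cond_cov + cond_cov.T)
            else:
                cond_mean = mu[mi]
                cond_cov = Sigma[np.ix_(mi, mi)]
            X[r, mi] = rng.multivariate_normal(cond_mean, cond_cov)
        if it >= cfg.gibbs_burnin:
            acc += X
            n_acc += 1
    out = S.values.copy()
    miss = ~S.observed
    out[miss] = (acc / n_acc)[miss]
    return out


def classic_cluster(X: np.ndarray, method: str, cfg: BaselineConfig) -> Partition:
    """Standard clusterers on a complete table: seeded k-means++ Lloyd
    iterations, fuzzy c-means, or agglomerative hierarchical clustering
    with single/complete linkage cut at k clusters (Euclidean metric)."""
    X = np.asarray(X, dtype=float)
    if np.isnan(X).any():
        raise ValueError("classic clusterers require a complete table")
    rng = np.random.default_rng(cfg.seed)
    if method == "km":
        km = KMeans(
            n_clusters=cfg.k, n_init=10, random_state=int(rng.integers(2**31 - 1))
        ).fit(X)
        return _labels_to_partition(km.labels_)
    if method == "fcm":
        _, U = _fcm(X, cfg.k, cfg.fuzzifier, cfg.max_iter, cfg.tol, rng)
        return _labels_to_partition(np.argmax(U, axis=1))
    if method in ("hier_si", "hier_co"):
        link = linkage(X, method="single" if method == "hier_si" else "complete")
        labels = fcluster(link, t=cfg.k, criterion="maxclust")
        return _labels_to_partition(labels - 1)
    raise ValueError(f"unknown method {method!r}")


def random_cluster(n: int, sizes, rng) -> Partition:
    """Uniform draw among partitions with the given block sizes."""
    sizes = [int(s) for s in sizes]
    if sum(sizes) != n:
        raise ValueError("sizes must sum to n")
    rng = np.random.default_rng(rng)
    order = rng.permutation(n)
    labels = np.empty(n, dtype=int)
    pos = 0
    for i, s in enumerate(sizes):
        labels[order[pos : pos + s]] = i
        pos += s
    return _labels_to_partition(labels)
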