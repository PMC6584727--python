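"""Synthetic random-labeled-point-process generation and the benchmark protocol.

The generators emulate two-cluster Gaussian mixtures in d = 5 dimensions
under three parameter regimes (the study conditions; chosen for an
approximate two-class Bayes error of 0.15):

==================  ========================================================
variant             generating distributions
==================  ========================================================
``known``           mu_1 = 0, mu_2 = 0.445 * 1_d, Sigma = 0.23 * I_d
``gaussian_mean``   mu_i ~ N(m_i, Sigma/nu_i); m_1 = 0, m_2 = 0.45 * 1_d,
                    nu_1 = 30, nu_2 = 5, Sigma = 0.28 * I_d
``niw``             Sigma_i ~ IW(75, 20.7 * I_d), mu_i | Sigma_i as above
==================  ========================================================

Cluster sample sizes are fixed a priori; distribution parameters are drawn
first, then points.  Missingness is entry-wise i.i.d. Bernoulli(p), applied
independently of values and labels (MCAR).  ``run_benchmark`` applies every
requested clustering method to the same masked instance and scores the
cluster mismatch error against the true labels.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import invwishart, norm

from .models import ClusterModel, ModelSpec, draw_covariances
from .partitions import Labeling, cluster_mismatch_error
from .pointset import PointSet

__all__ = [
    "SimScenario",
    "table1_model",
    "draw_instance",
    "apply_mcar",
    "analytic_bayes_error",
    "expected_bayes_error_gaussian_mean",
    "expected_bayes_error_niw",
    "run_benchmark",
    "summarize_benchmark",
]

DEFAULT_REPS = {"known": 100, "gaussian_mean": 80, "niw": 40}


def table1_model(variant: str, d: int = 5, mc_draws: int = 500) -> ModelSpec:
    """The study's generating model (which is also the matched clustering
    prior) for a given variant."""
    ones = np.ones(d)
    eye = np.eye(d)
    if variant == "known":
        clusters = [
            ClusterModel(mu=0.0 * ones, Sigma=0.23 * eye),
            ClusterModel(mu=0.445 * ones, Sigma=0.23 * eye),
        ]
    elif variant == "gaussian_mean":
        clusters = [
            ClusterModel(m=0.0 * ones, nu=30.0, Sigma=0.28 * eye),
            ClusterModel(m=0.45 * ones, nu=5.0, Sigma=0.28 * eye),
        ]
    elif variant == "niw":
        clusters = [
            ClusterModel(m=0.0 * ones, nu=30.0, kappa=75.0, Psi=20.7 * eye),
            ClusterModel(m=0.45 * ones, nu=5.0, kappa=75.0, Psi=20.7 * eye),
        ]
    else:
        raise ValueError(f"unknown variant {variant!r}")
    return ModelSpec(variant=variant, clusters=clusters, mc_draws=mc_draws)


@dataclass
class SimScenario:
    """One simulation condition: model variant, sizes, missingness, reps."""

    model: ModelSpec
    n1: int = 10
    n2: int = 10
    missing_prob: float = 0.0
    n_reps: int = 100
    base_seed: int = 0
    unbalanced_swap: bool = True  # alternate size<->cluster assignment per rep

    def __post_init__(self):
        if self.n1 < 1 or self.n2 < 1:
            raise ValueError("cluster sizes must be >= 1")
        if not (0.0 <= self.missing_prob < 1.0):
            raise ValueError("missing probability must be in [0, 1)")

    @property
    def sizes(self):
        return (self.n1, self.n2)


def _realize_cluster(c: ClusterModel, variant: str, rng):
    """Draw (mu, Sigma) for one cluster according to the variant."""
    if variant == "known":
        return c.mu, c.Sigma
    if variant == "gaussian_mean":
        mu = rng.multivariate_normal(c.m, c.Sigma / c.nu)
        return mu, c.Sigma
    Sigma = np.atleast_2d(invwishart.rvs(df=c.kappa, scale=c.Psi, random_state=rng))
    mu = rng.multivariate_normal(c.m, Sigma / c.nu)
    return mu, Sigma


def draw_instance(scenario: SimScenario, rep_index: int):
    """One replicate: (complete PointSet, truth Labeling, realized params).

    Distributions are drawn first, then points.  With unequal sizes and
    ``unbalanced_swap``, the size-to-cluster assignment alternates across
    repetitions (n1 points from cluster 1 in even reps, from cluster 2 in
    odd reps).
    """
    rng = np.random.default_rng(
        np.random.SeedSequence([int(scenario.base_seed), int(rep_index), 0])
    )
    variant = scenario.model.variant
    params = [
        _realize_cluster(c, variant, rng) for c in scenario.model.clusters
    ]
    sizes = [scenario.n1, scenario.n2]
    if scenario.unbalanced_swap and scenario.n1 != scenario.n2 and rep_index % 2 == 1:
        sizes = sizes[::-1]
    X_parts, labels = [], []
    for i, ((mu, Sigma), n_i) in enumerate(zip(params, sizes), start=1):
        X_parts.append(rng.multivariate_normal(mu, Sigma, size=n_i))
        labels.extend([i] * n_i)
    X = np.vstack(X_parts)
    return PointSet(X), Labeling(labels, l=len(params)), params


def apply_mcar(points: PointSet, p: float, rng) -> PointSet:
    """Hide each entry independently with probability ``p`` (MCAR)."""
    if not (0.0 <= p < 1.0):
        raise ValueError("missing probability must be in [0, 1)")
    rng = np.random.default_rng(rng)
    mask = rng.random(points.values.shape) >= p  # True = observed
    return PointSet(points.values, points.observed & mask)


def analytic_bayes_error(mu1, mu2, Sigma) -> float:
    """Two-class equal-prior Bayes error for shared covariance:
    Phi(-Delta/2) with Delta^2 = (mu1-mu2)^T Sigma^{-1} (mu1-mu2)."""
    mu1 = np.asarray(mu1, dtype=float)
    mu2 = np.asarray(mu2, dtype=float)
    Sigma = np.asarray(Sigma, dtype=float)
    diff = mu1 - mu2
    delta2 = float(diff @ np.linalg.solve(Sigma, diff))
    if delta2 < 0:
        raise ValueError("covariance must be positive definite")
    return float(norm.cdf(-0.5 * np.sqrt(delta2)))


def expected_bayes_error_gaussian_mean(
    model: ModelSpec, n_draws: int = 100_000, rng=None
) -> float:
    """Monte Carlo expectation of the Bayes error under the random-means
    model: draw both cluster means, evaluate Phi(-Delta/2) per draw (shared
    fixed covariance), average."""
    if model.variant != "gaussian_mean":
        raise ValueError("requires the gaussian_mean variant")
    rng = np.random.default_rng(rng)
    c1, c2 = model.clusters
    d = model.d
    L1 = np.linalg.cholesky(c1.Sigma / c1.nu)
    L2 = np.linalg.cholesky(c2.Sigma / c2.nu)
    mu1 = c1.m + rng.standard_normal((n_draws, d)) @ L1.T
    mu2 = c2.m + rng.standard_normal((n_draws, d)) @ L2.T
    diff = mu1 - mu2
    delta2 = np.einsum("ij,ij->i", diff, np.linalg.solve(c1.Sigma, diff.T).T)
    return float(norm.cdf(-0.5 * np.sqrt(delta2)).mean())


def expected_bayes_error_niw(
    model: ModelSpec,
    n_reps: int = 200,
    n_points: int = 10_000,
    rng=None,
) -> float:
    """Monte Carlo expectation of the realized Bayes error under the NIW
    model: per replicate draw (mu_i, Sigma_i) for both classes, classify a
    balanced sample with the true log-density-ratio (quadratic) rule, and
    average the misclassification rate."""
    if model.variant != "niw":
        raise ValueError("requires the niw variant")
    rng = np.random.default_rng(rng)
    d = model.d
    errs = np.empty(n_reps)
    half = n_points // 2
    for r in range(n_reps):
        params = [_realize_cluster(c, "niw", rng) for c in model.clusters]
        X = np.vstack(
            [rng.multivariate_normal(mu, Sig, size=half) for mu, Sig in params]
        )
        y = np.repeat([0, 1], half)
        scores = np.empty((X.shape[0], 2))
        for i, (mu, Sig) in enumerate(params):
            L = np.linalg.cholesky(Sig)
            W = np.linalg.solve(L, (X - mu).T)
            scores[:, i] = -0.5 * np.sum(W * W, axis=0) - np.log(
                np.diag(L)
            ).sum() - 0.5 * d * np.log(2 * np.pi)
        errs[r] = np.mean(np.argmax(scores, axis=1) != y)
    return float(errs.mean())


# ---------------------------------------------------------------------------
# benchmark protocol

PROPOSED = ("optimal", "pmax", "pseed")
BASELINES = ("kpod", "fcm_ocs", "km", "fcm", "hier_si", "hier_co", "random")
ALL_METHODS = PROPOSED + BASELINES
_IMPUTED = ("km", "fcm", "hier_si", "hier_co")


def run_benchmark(
    scenario: SimScenario,
    methods: Sequence[str] = ALL_METHODS,
    radius: int = 1,
    n_seeds: int = 5,
    search_engine: str = "auto",
    baseline_config=None,
) -> pd.DataFrame:
    """Run every method on every replicate of a scenario.

    Each repetition draws one instance, masks it, and hands the *same*
    masked point set to every method; the per-instance score is the cluster
    mismatch error against the true labels.  Fully seeded: one RNG stream
    per (repetition, purpose), derived from the scenario base seed.
    Returns a long DataFrame with columns rep, method, error.
    """
    from . import baselines as bl
    from .search import SearchConfig, optimal_cluster, pmax_cluster, pseed_cluster

    for m in methods:
        if m not in ALL_METHODS:
            raise ValueError(f"unknown method {m!r}")
    cfg_b = baseline_config or bl.BaselineConfig()
    records = []
    sizes = tuple(sorted((scenario.n1, scenario.n2), reverse=True))
    for rep in range(scenario.n_reps):
        complete, truth, _ = draw_instance(scenario, rep)
        mask_rng = np.random.SeedSequence([scenario.base_seed, rep, 1])
        S = apply_mcar(complete, scenario.missing_prob, mask_rng)
        draws = None
        if scenario.model.variant == "niw" and any(m in PROPOSED for m in methods):
            draws = draw_covariances(
                scenario.model, np.random.SeedSequence([scenario.base_seed, rep, 2])
            )
        imputed = None
        if any(m in _IMPUTED for m in methods):
            gibbs_cfg = replace(
                cfg_b, seed=np.random.SeedSequence([scenario.base_seed, rep, 3])
            )
            imputed = bl.gibbs_impute(S, gibbs_cfg)
        for m in methods:
            m_rng = np.random.SeedSequence(
                [scenario.base_seed, rep, 10 + ALL_METHODS.index(m)]
            )
            if m in PROPOSED:
                scfg = SearchConfig(
                    strategy=m,
                    radius=radius,
                    cluster_sizes=sizes,
                    n_seeds=n_seeds,
                    seed=m_rng,
                    engine=search_engine,
                )
                fn = {"optimal": optimal_cluster, "pmax": pmax_cluster,
                      "pseed": pseed_cluster}[m]
                part = fn(S, scenario.model, scfg, draws=draws).partition
            elif m == "kpod":
                part = bl.kpod_cluster(S, replace(cfg_b, seed=m_rng))
            elif m == "fcm_ocs":
                part = bl.fcm_ocs_cluster(S, replace(cfg_b, seed=m_rng))
            elif m == "random":
                part = bl.random_cluster(S.n, sizes, np.random.default_rng(m_rng))
            else:
                part = bl.classic_cluster(imputed, m, replace(cfg_b, seed=m_rng))
            records.append(
                {
                    "rep": rep,
                    "method": m,
                    "error": cluster_mismatch_error(part, truth),
                }
            )
    return pd.DataFrame.from_records(records)


def summarize_benchmark(df: pd.DataFrame) -> pd.DataFrame:
    """Per-method mean error and Monte Carlo standard error of the mean."""
    g = df.groupby("method")["error"]
    out = g.agg(mean_error="mean", sd="std", n_reps="count")
    out["se"] = out["sd"] / np.sqrt(out["n_reps"])
    return out.drop(columns="sd")
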