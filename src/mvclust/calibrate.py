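"""Unsupervised feature selection and method-of-moments prior calibration.

For expression matrices (rows = samples, columns = genes, variance-
stabilized log scale), clustering features are the top genes by
variance-to-mean ratio; the next block of genes — disjoint from the
clustering features — calibrates a single set of Normal-inverse-Wishart
hyperparameters shared by both clusters, under the equicorrelated
structure

    Psi = sigma^2 * [(1 - rho) I + rho 1 1^T],   m_i = m * 1_d,
    nu_i = nu,  kappa_i = kappa,

so only five scalars (m, sigma^2, rho, kappa, nu) are estimated.

Moment equations (derived here; each calibration gene g has sample mean
xbar_g and unbiased sample variance v_g over n samples, and under the
model its per-gene variance s_g is marginally inverse-gamma with
a = (kappa - d + 1)/2, b = psi_jj/2):

    m        = mean_g xbar_g
    E[s]     = mean_g v_g                       (=: sbar)
    a        : Var_g(log v_g) = trigamma(a) + trigamma((n-1)/2)
               [v = s w with w ~ chi^2_{n-1}/(n-1) independent of s, so the
               log-variance dispersion splits into the prior part
               trigamma(a) and the sampling part trigamma((n-1)/2);
               matching on the log scale is far more stable than matching
               raw fourth moments]
    kappa    = 2 a + d - 1
    sigma^2  = sbar (kappa - d - 1)             [E[Sigma] = Psi/(kappa-d-1)]
    nu       = sbar / (Var_g(xbar_g) - sbar/n)  [Var(mu) = E[Sigma]/nu]
    rho      = mean off-diagonal sample correlation between genes
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.special import polygamma

from .models import ClusterModel, ModelSpec


def _trigamma_inverse(y: float, iters: int = 50) -> float:
    """Solve trigamma(a) = y for a > 0 by Newton iteration."""
    a = 0.5 + 1.0 / y
    for _ in range(iters):
        step = -(float(polygamma(1, a)) - y) / float(polygamma(2, a))
        a = max(a + step, 1e-8)
        if abs(step) < 1e-10 * a:
            break
    return float(a)

__all__ = ["CalibrationResult", "select_features", "calibrate"]

log = logging.getLogger(__name__)


@dataclass
class CalibrationResult:
    m: float
    sigma2: float  # diagonal of the assembled Psi
    rho: float
    kappa: float
    nu: float
    d: int

    def psi(self) -> np.ndarray:
        """Equicorrelated scale matrix (positive definite by construction)."""
        P = np.full((self.d, self.d), self.rho * self.sigma2)
        np.fill_diagonal(P, self.sigma2)
        return P

    def to_model_spec(self, mc_draws: int = 500) -> ModelSpec:
        """Ready NIW model with identical hyperparameters for both clusters."""
        block = ClusterModel(
            m=self.m * np.ones(self.d),
            nu=self.nu,
            kappa=self.kappa,
            Psi=self.psi(),
        )
        return ModelSpec(variant="niw", clusters=[block, block], mc_draws=mc_draws)


def select_features(table, k: int) -> list:
    """Top-``k`` column indices by variance-to-mean ratio (descending).

    Zero-mean columns rank as +inf when their variance is positive and as 0
    otherwise; ties break by column index (ascending).
    """
    X = np.asarray(table, dtype=float)
    if X.ndim != 2:
        raise ValueError("expression table must be 2-D (samples x genes)")
    if k > X.shape[1]:
        raise ValueError("k exceeds the number of columns")
    means = X.mean(axis=0)
    if X.shape[0] > 1:
        variances = X.var(axis=0, ddof=1)
    else:
        variances = np.zeros(X.shape[1])
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(
            means != 0,
            variances / means,
            np.where(variances > 0, np.inf, 0.0),
        )
    order = np.lexsort((np.arange(X.shape[1]), -ratio))
    return [int(i) for i in order[:k]]


def calibrate(table, d: int) -> CalibrationResult:
    """Estimate (m, sigma^2, rho, kappa, nu) from held-out calibration genes.

    ``table`` is samples x genes (the calibration genes, disjoint from the
    clustering features); ``d`` is the dimension of the clustering feature
    space for which the hyperparameters are assembled.  Out-of-range
    estimates are clipped to the valid region and logged.
    """
    X = np.asarray(table, dtype=float)
    if X.ndim != 2 or X.shape[0] < 3 or X.shape[1] < 3:
        raise ValueError("need at least 3 samples and 3 calibration genes")
    n, G = X.shape
    gene_means = X.mean(axis=0)
    gene_vars = X.var(axis=0, ddof=1)
    m = float(gene_means.mean())
    sbar = float(gene_vars.mean())
    if sbar <= 1e-12:
        raise ValueError("calibration genes are (near-)constant; variance floor hit")

    # kappa from the dispersion of per-gene log variances: subtract the
    # chi-square sampling part, invert the trigamma function for the prior
    # part (Newton iteration)
    var_logv = float(np.log(gene_vars).var(ddof=1))
    excess = var_logv - float(polygamma(1, (n - 1) / 2.0))
    if excess <= 1e-8:
        kappa = float(d + 2)
        log.warning("log-variance dispersion at sampling noise; kappa clipped")
    else:
        a = _trigamma_inverse(excess)
        kappa = 2.0 * a + d - 1.0
        if kappa <= d + 1:
            kappa = float(d + 2)
            log.warning("kappa estimate <= d+1; clipped to d+2")

    sigma2 = sbar * (kappa - d - 1.0)

    # nu from the dispersion of per-gene means
    var_m = float(gene_means.var(ddof=1))
    denom = var_m - sbar / n
    if denom <= 1e-12:
        nu = 1e6
        log.warning("mean dispersion at or below sampling noise; nu clipped high")
    else:
        nu = sbar / denom

    # rho from the average between-gene correlation
    C = np.corrcoef(X, rowvar=False)
    off = C[~np.eye(G, dtype=bool)]
    rho = float(np.nanmean(off))
    lo = -1.0 / (d - 1) + 1e-6 if d > 1 else -1.0 + 1e-6
    hi = 1.0 - 1e-6
    if not (lo < rho < hi):
        clipped = min(max(rho, lo), hi)
        log.warning("rho=%.4f outside PD range; clipped to %.4f", rho, clipped)
        rho = clipped

    return CalibrationResult(
        m=m, sigma2=float(sigma2), rho=rho, kappa=float(kappa), nu=float(nu), d=int(d)
    )
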