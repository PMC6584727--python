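"""Independent brute-force oracles used to validate the package.

Everything here is deliberately written from first principles with a
different algebraic route than the package: posteriors come from explicit
joint Gaussian densities over the stacked observed coordinates (via
scipy.stats.multivariate_normal), partition costs from exhaustive
minimization over label permutations, and the Bayes clusterer from full
enumeration of all labelings.  Slow but simple; only usable at small n.
"""

import itertools
import math

import numpy as np
from scipy.special import logsumexp
from scipy.stats import multivariate_normal as mvn


def brute_cost(q_blocks, p_blocks, n, l):
    """Partition cost by exhaustive search over injective label maps."""
    memb_p = {}
    for lab, block in enumerate(p_blocks, start=1):
        for x in block:
            memb_p[x] = lab
    best = n + 1
    for perm in itertools.permutations(range(1, l + 1), len(q_blocks)):
        mism = 0
        for lab, block in zip(perm, q_blocks):
            for x in block:
                if memb_p[x] != lab:
                    mism += 1
        best = min(best, mism)
    return best / n


def _cluster_joint_logpdf_known(S, rows, mu, Sigma):
    total = 0.0
    for r in rows:
        o = S.observed[r]
        if o.any():
            total += mvn.logpdf(S.values[r, o], mu[o], Sigma[np.ix_(o, o)])
    return total


def _cluster_joint_logpdf_mean(S, rows, m, nu, Sigma):
    """Joint density of the stacked observed entries after integrating the
    mean: blockwise covariance Sigma_obs + (1/nu) * cross terms."""
    obs = [np.flatnonzero(S.observed[r]) for r in rows]
    if sum(len(o) for o in obs) == 0:
        return 0.0
    y = np.concatenate([S.values[r][o] for r, o in zip(rows, obs)])
    mean = np.concatenate([m[o] for o in obs])
    blocks = []
    for a, oa in enumerate(obs):
        row = []
        for b, ob in enumerate(obs):
            C = (1.0 / nu) * Sigma[np.ix_(oa, ob)]
            if a == b:
                C = C + Sigma[np.ix_(oa, ob)]
            row.append(C)
        blocks.append(row)
    return mvn.logpdf(y, mean, np.block(blocks), allow_singular=False)


def _cluster_joint_logpdf_mean_draws(S, rows, m, nu, Sigmas):
    """Per-draw joint log density over the stacked observed entries.

    Same stacked-covariance construction as :func:`_cluster_joint_logpdf_mean`
    but assembled for a (J, d, d) batch of covariances at once: the joint
    covariance entry for stacked coordinates a, b (features F_a, F_b of
    point rows I_a, I_b) is Sigma[F_a, F_b] * (1/nu + [I_a == I_b]).
    """
    obs = [np.flatnonzero(S.observed[r]) for r in rows]
    k = sum(len(o) for o in obs)
    J = Sigmas.shape[0]
    if k == 0:
        return np.zeros(J)
    y = np.concatenate([S.values[r][o] for r, o in zip(rows, obs)])
    mean = np.concatenate([m[o] for o in obs])
    F = np.concatenate(obs)
    I = np.concatenate([np.full(len(o), r) for r, o in zip(rows, obs)])
    w = 1.0 / nu + (I[:, None] == I[None, :]).astype(float)
    cov = Sigmas[:, F[:, None], F[None, :]] * w[None, :, :]
    L = np.linalg.cholesky(cov)
    logdet = 2.0 * np.sum(np.log(np.diagonal(L, axis1=-2, axis2=-1)), axis=-1)
    dev = np.broadcast_to(y - mean, (J, k))[..., None]
    sol = np.linalg.solve(cov, dev)[..., 0]
    quad = np.einsum("ja,a->j", sol, y - mean)
    return -0.5 * (k * math.log(2 * math.pi) + logdet + quad)


def _cluster_term(S, rows, i, model, draws, memo=None):
    key = (tuple(rows), i)
    if memo is not None and key in memo:
        return memo[key]
    c = model.clusters[i - 1]
    if model.variant == "known":
        val = _cluster_joint_logpdf_known(S, rows, c.mu, c.Sigma)
    elif model.variant == "gaussian_mean":
        val = _cluster_joint_logpdf_mean(S, rows, c.m, c.nu, c.Sigma)
    else:
        D = np.asarray(draws[i - 1])
        vals = _cluster_joint_logpdf_mean_draws(S, rows, c.m, c.nu, D)
        val = logsumexp(vals) - math.log(D.shape[0])
    if memo is not None:
        memo[key] = val
    return val


def brute_log_posterior(S, labels, model, draws=None, memo=None):
    """Unnormalized log posterior of a label tuple, any variant."""
    n = len(labels)
    l = model.l
    total = -n * math.log(l)
    for i in range(1, l + 1):
        rows = [r for r in range(n) if labels[r] == i]
        if rows:
            total += _cluster_term(S, rows, i, model, draws, memo)
    return total


def _partition_key(labels):
    """Canonical blocks (tuple of tuples) induced by a label tuple."""
    groups = {}
    for idx, lab in enumerate(labels, start=1):
        groups.setdefault(lab, []).append(idx)
    return tuple(sorted((tuple(b) for b in groups.values()), key=lambda b: b[0]))


def brute_optimal(S, model, sizes, draws=None):
    """Exact Bayes clusterer by full labeling enumeration.

    Reference probabilities over partitions whose block-size multiset
    matches ``sizes``; candidates are all partitions of at most l blocks.
    Returns (canonical_blocks, risk); tie-break by lexicographic canonical
    block structure.
    """
    n, l = S.n, model.l
    want = tuple(sorted((int(s) for s in sizes), reverse=True))
    ref_logs = {}
    all_parts = set()
    memo = {}
    for labels in itertools.product(range(1, l + 1), repeat=n):
        key = _partition_key(labels)
        all_parts.add(key)
        szs = tuple(sorted((len(b) for b in key), reverse=True))
        if szs == want:
            lp = brute_log_posterior(S, labels, model, draws, memo)
            ref_logs.setdefault(key, []).append(lp)
    refs = sorted(ref_logs)
    logs = np.array([logsumexp(ref_logs[k]) for k in refs])
    probs = np.exp(logs - logsumexp(logs))
    probs /= probs.sum()
    best_risk, ties = math.inf, []
    for cand in sorted(all_parts):
        r = sum(
            p * brute_cost(cand, ref, n, l) for ref, p in zip(refs, probs)
        )
        if r < best_risk - 1e-12:
            best_risk, ties = r, [cand]
        elif r <= best_risk + 1e-12:
            ties.append(cand)
    return min(ties), best_risk
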