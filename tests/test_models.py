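"""Posterior models: pattern groups, marginalized posteriors, oracles."""

import math

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.special import logsumexp
from scipy.stats import invgamma, invwishart
from scipy.stats import multivariate_normal as mvn

from mvclust import (
    ClusterModel,
    Labeling,
    ModelSpec,
    Partition,
    PointSet,
    draw_covariances,
    group_by_pattern,
    label_prior,
    log_posterior_gaussian_mean,
    log_posterior_known,
    log_posterior_niw,
    niw_closed_form_complete,
    normalize_over_set,
    partition_log_probability,
)
from mvclust.models import _log_marginal_mean_cluster

from _oracles import brute_log_posterior


def random_masked_pointset(rng, n, d, p_missing=0.3):
    X = rng.normal(size=(n, d))
    mask = rng.random((n, d)) > p_missing
    return PointSet(np.where(mask, X, np.nan))


def known_model(d, rng=None, shared=False):
    rng = rng or np.random.default_rng(0)
    def cov():
        A = rng.normal(size=(d, d))
        return A @ A.T + d * np.eye(d)
    S1 = cov()
    return ModelSpec(
        "known",
        [
            ClusterModel(mu=rng.normal(size=d), Sigma=S1),
            ClusterModel(mu=rng.normal(size=d), Sigma=S1 if shared else cov()),
        ],
    )


class TestPatternGroups:
    def test_fully_observed_single_group(self):
        rng = np.random.default_rng(1)
        S = PointSet(rng.normal(size=(5, 3)))
        groups = group_by_pattern(S, Labeling([1] * 5, l=2), 1)
        assert len(groups) == 1
        g = groups[0]
        assert g.n_g == 5 and g.obs_idx == (0, 1, 2)
        np.testing.assert_allclose(g.mean, S.values.mean(axis=0))

    def test_hand_computed_stats(self):
        S = PointSet(np.array([[1.0, np.nan], [3.0, np.nan]]))
        (g,) = group_by_pattern(S, Labeling([1, 1], l=1), 1)
        assert g.obs_idx == (0,)
        assert g.mean == pytest.approx(2.0)
        assert g.scatter[0, 0] == pytest.approx(2.0)

    def test_disjoint_patterns_two_singleton_groups(self):
        S = PointSet(np.array([[1.0, np.nan], [np.nan, 5.0]]))
        groups = group_by_pattern(S, Labeling([1, 1], l=1), 1)
        assert len(groups) == 2
        assert all(g.n_g == 1 and np.all(g.scatter == 0) for g in groups)

    def test_all_missing_row_forms_empty_group(self):
        S = PointSet(np.array([[np.nan, np.nan], [1.0, 2.0]]))
        groups = group_by_pattern(S, Labeling([1, 1], l=1), 1)
        assert sorted(g.d_g for g in groups) == [0, 2]


class TestKnownPosterior:
    def test_single_point_is_log_density_plus_prior(self):
        model = known_model(3)
        x = np.array([[0.3, -0.2, 1.1]])
        S = PointSet(x)
        lp = log_posterior_known(S, Labeling([1], l=2), model)
        c = model.clusters[0]
        assert lp == pytest.approx(mvn.logpdf(x[0], c.mu, c.Sigma) - math.log(2))

    def test_grouped_form_equals_per_point_product(self):
        # the sufficient-statistic factorization must agree with the direct
        # product of observed-margin densities to high precision
        rng = np.random.default_rng(7)
        for trial in range(10):
            S = random_masked_pointset(rng, 7, 3)
            labels = tuple(rng.integers(1, 3, size=7).tolist())
            model = known_model(3, rng)
            lp = log_posterior_known(S, Labeling(labels, l=2), model)
            oracle = brute_log_posterior(S, labels, model)
            assert lp == pytest.approx(oracle, abs=1e-10)

    def test_all_features_missing_gives_prior_only(self):
        S = PointSet(np.full((3, 2), np.nan), observed=np.zeros((3, 2), bool))
        model = known_model(2)
        lab = Labeling([1, 2, 1], l=2)
        assert log_posterior_known(S, lab, model) == pytest.approx(-3 * math.log(2))


class TestGaussianMeanPosterior:
    def test_single_point_closed_form_convolution(self):
        # d=1: marginal of x is N(m, Sigma + Sigma/nu)
        model = ModelSpec(
            "gaussian_mean",
            [
                ClusterModel(m=[0.5], nu=2.0, Sigma=[[0.7]]),
                ClusterModel(m=[0.0], nu=1.0, Sigma=[[1.0]]),
            ],
        )
        S = PointSet(np.array([[1.3]]))
        lp = log_posterior_gaussian_mean(S, Labeling([1], l=2), model)
        expected = mvn.logpdf(1.3, 0.5, 0.7 + 0.35) - math.log(2)
        assert lp == pytest.approx(expected)

    def test_empty_cluster_contributes_nothing(self):
        model = ModelSpec(
            "gaussian_mean",
            [
                ClusterModel(m=[0.0], nu=2.0, Sigma=[[1.0]]),
                ClusterModel(m=[5.0], nu=3.0, Sigma=[[2.0]]),
            ],
        )
        S = PointSet(np.array([[0.1], [0.4]]))
        lp_all1 = log_posterior_gaussian_mean(S, Labeling([1, 1], l=2), model)
        # manually: prior + cluster-1 marginal only
        oracle = brute_log_posterior(S, (1, 1), model)
        assert lp_all1 == pytest.approx(oracle, abs=1e-10)

    def test_point_mass_limit_recovers_known(self):
        rng = np.random.default_rng(3)
        S = random_masked_pointset(rng, 6, 2)
        lab = Labeling([1, 2, 1, 2, 1, 2], l=2)
        mu1, mu2 = rng.normal(size=2), rng.normal(size=2)
        Sig = np.eye(2) * 0.9
        known = ModelSpec(
            "known",
            [ClusterModel(mu=mu1, Sigma=Sig), ClusterModel(mu=mu2, Sigma=Sig)],
        )
        prev_gap = None
        for nu in (1e2, 1e4, 1e6):
            gm = ModelSpec(
                "gaussian_mean",
                [
                    ClusterModel(m=mu1, nu=nu, Sigma=Sig),
                    ClusterModel(m=mu2, nu=nu, Sigma=Sig),
                ],
            )
            gap = abs(
                log_posterior_gaussian_mean(S, lab, gm)
                - log_posterior_known(S, lab, known)
            )
            if prev_gap is not None:
                assert gap < prev_gap
            prev_gap = gap
        assert prev_gap < 1e-4

    def test_matches_joint_gaussian_oracle_with_missingness(self):
        rng = np.random.default_rng(11)
        for trial in range(8):
            S = random_masked_pointset(rng, 6, 3)
            labels = tuple(rng.integers(1, 3, size=6).tolist())
            model = ModelSpec(
                "gaussian_mean",
                [
                    ClusterModel(m=rng.normal(size=3), nu=2.5, Sigma=np.eye(3) * 0.8),
                    ClusterModel(m=rng.normal(size=3), nu=4.0, Sigma=np.eye(3) * 1.3),
                ],
            )
            lp = log_posterior_gaussian_mean(S, Labeling(labels, l=2), model)
            assert lp == pytest.approx(
                brute_log_posterior(S, labels, model), abs=1e-9
            )


def niw_model(d, mc_draws=100, kappa=8.0):
    return ModelSpec(
        "niw",
        [
            ClusterModel(m=np.zeros(d), nu=3.0, kappa=kappa, Psi=np.eye(d) * 2.0),
            ClusterModel(m=np.full(d, 0.5), nu=2.0, kappa=kappa, Psi=np.eye(d)),
        ],
        mc_draws=mc_draws,
    )


class TestNiwPosterior:
    def test_single_draw_reduces_to_gaussian_mean(self):
        rng = np.random.default_rng(5)
        S = random_masked_pointset(rng, 5, 2)
        lab = Labeling([1, 2, 1, 2, 1], l=2)
        model = niw_model(2, mc_draws=1)
        draws = draw_covariances(model, 0)
        gm = ModelSpec(
            "gaussian_mean",
            [
                ClusterModel(m=model.clusters[0].m, nu=3.0, Sigma=draws[0][0]),
                ClusterModel(m=model.clusters[1].m, nu=2.0, Sigma=draws[1][0]),
            ],
        )
        assert log_posterior_niw(S, lab, model, draws) == pytest.approx(
            log_posterior_gaussian_mean(S, lab, gm), abs=1e-10
        )

    def test_duplicated_draws_leave_value_unchanged(self):
        rng = np.random.default_rng(6)
        S = random_masked_pointset(rng, 5, 2)
        lab = Labeling([1, 1, 2, 2, 1], l=2)
        model = niw_model(2, mc_draws=20)
        draws = draw_covariances(model, 1)
        doubled = [np.concatenate([D, D], axis=0) for D in draws]
        a = log_posterior_niw(S, lab, model, draws)
        b = log_posterior_niw(S, lab, model, doubled)
        assert a == pytest.approx(b, abs=1e-10)

    def test_complete_data_converges_to_conjugate_closed_form(self):
        from mvclust.models import _log_marginal_mean_cluster_batch

        rng = np.random.default_rng(9)
        S = PointSet(rng.normal(size=(6, 2)))
        lab = Labeling([1, 2, 1, 2, 1, 2], l=2)
        model = niw_model(2, mc_draws=40000)
        draws = draw_covariances(model, 123)
        mc = log_posterior_niw(S, lab, model, draws)
        cf = niw_closed_form_complete(S, lab, model)
        # delta-method standard error of the per-cluster log-mean-exp
        var = 0.0
        for i, c in enumerate(model.clusters):
            groups = group_by_pattern(S, lab, i + 1)
            vals = _log_marginal_mean_cluster_batch(groups, draws[i], c.m, c.nu)
            w = np.exp(vals - vals.max())
            var += (w.std() / w.mean()) ** 2 / len(vals)
        assert abs(mc - cf) < 3.0 * math.sqrt(var) + 1e-6

    def test_closed_form_d1_matches_quadrature(self):
        # d=1: IW(kappa, psi) is inverse-gamma(kappa/2, psi/2); integrate the
        # fixed-variance marginal numerically
        S = PointSet(np.array([[0.4], [1.1], [-0.3]]))
        lab = Labeling([1, 1, 1], l=2)
        model = ModelSpec(
            "niw",
            [
                ClusterModel(m=[0.2], nu=2.0, kappa=5.0, Psi=[[1.5]]),
                ClusterModel(m=[0.0], nu=1.0, kappa=5.0, Psi=[[1.0]]),
            ],
        )
        cf = niw_closed_form_complete(S, lab, model)
        groups = group_by_pattern(S, lab, 1)

        def integrand(s2):
            g = _log_marginal_mean_cluster(groups, np.array([[s2]]), np.array([0.2]), 2.0)
            return math.exp(g) * invgamma.pdf(s2, 5.0 / 2, scale=1.5 / 2)

        val, _ = quad(integrand, 0, np.inf)
        assert cf == pytest.approx(math.log(val) - 3 * math.log(2), abs=1e-7)

    def test_missing_data_d1_matches_quadrature(self):
        # with missingness the d=1 integrand just drops the hidden rows
        S = PointSet(np.array([[0.4], [np.nan], [-0.3], [0.9]]))
        lab = Labeling([1, 1, 1, 1], l=2)
        model = ModelSpec(
            "niw",
            [
                ClusterModel(m=[0.1], nu=2.0, kappa=6.0, Psi=[[1.2]]),
                ClusterModel(m=[0.0], nu=1.0, kappa=6.0, Psi=[[1.0]]),
            ],
            mc_draws=200_000,
        )
        draws = draw_covariances(model, 21)
        mc = log_posterior_niw(S, lab, model, draws)
        groups = group_by_pattern(S, lab, 1)

        def integrand(s2):
            g = _log_marginal_mean_cluster(groups, np.array([[s2]]), np.array([0.1]), 2.0)
            return math.exp(g) * invgamma.pdf(s2, 3.0, scale=0.6)

        val, _ = quad(integrand, 0, np.inf)
        expected = math.log(val) - 4 * math.log(2)
        assert mc == pytest.approx(expected, abs=0.02)

    def test_iw_sampler_matches_stated_density_moments(self):
        # the d=1 inverse-Wishart density in use must have mean
        # psi/(kappa-d-1) and mode psi/(kappa+d+1); check the sampler via
        # quadrature of the matching inverse-gamma density
        kappa, psi = 9.0, 2.0
        mean_quad, _ = quad(
            lambda s: s * invgamma.pdf(s, kappa / 2, scale=psi / 2), 0, np.inf
        )
        assert mean_quad == pytest.approx(psi / (kappa - 2), rel=1e-8)
        draws = invwishart.rvs(df=kappa, scale=psi, size=200_000, random_state=1)
        assert np.mean(draws) == pytest.approx(psi / (kappa - 2), rel=0.02)


class TestPriorsAndPartitionProbability:
    def test_uniform_prior_value(self):
        model = known_model(2)
        lab = Labeling([1, 2, 2, 1], l=2)
        assert label_prior(lab, model) == pytest.approx(-4 * math.log(2))

    def test_custom_weights(self):
        model = known_model(2)
        model.label_weights = {(1, 2): 0.75, (2, 1): 0.25}
        assert label_prior(Labeling([1, 2], l=2), model) == pytest.approx(
            math.log(0.75)
        )

    def test_partition_probability_sums_two_labelings(self):
        rng = np.random.default_rng(2)
        S = random_masked_pointset(rng, 4, 2)
        model = known_model(2, rng)
        p = Partition([[1, 2], [3, 4]])
        direct = logsumexp(
            [
                brute_log_posterior(S, (1, 1, 2, 2), model),
                brute_log_posterior(S, (2, 2, 1, 1), model),
            ]
        )
        assert partition_log_probability(p, S, model) == pytest.approx(direct)

    def test_symmetric_model_adds_log2(self):
        rng = np.random.default_rng(4)
        S = random_masked_pointset(rng, 4, 2)
        model = known_model(2, rng, shared=True)
        model.clusters[1] = model.clusters[0]  # identical hyperparameters
        p = Partition([[1, 3], [2, 4]])
        single = brute_log_posterior(S, (1, 2, 1, 2), model)
        assert partition_log_probability(p, S, model) == pytest.approx(
            single + math.log(2)
        )

    def test_single_block_sums_constant_labelings(self):
        rng = np.random.default_rng(8)
        S = random_masked_pointset(rng, 3, 2)
        model = known_model(2, rng)
        p = Partition([[1, 2, 3]])
        direct = logsumexp(
            [
                brute_log_posterior(S, (1, 1, 1), model),
                brute_log_posterior(S, (2, 2, 2), model),
            ]
        )
        assert partition_log_probability(p, S, model) == pytest.approx(direct)

    def test_normalize_matches_labeling_level_enumeration(self):
        import itertools

        rng = np.random.default_rng(10)
        S = random_masked_pointset(rng, 4, 2)
        model = known_model(2, rng)
        from mvclust.partitions import enumerate_partitions

        parts = list(enumerate_partitions(4, 2))
        parts, probs = normalize_over_set(parts, S, model)
        assert probs.sum() == pytest.approx(1.0)
        # labeling-level oracle
        logs = {
            labels: brute_log_posterior(S, labels, model)
            for labels in itertools.product((1, 2), repeat=4)
        }
        Z = logsumexp(list(logs.values()))
        from mvclust.partitions import canonicalize as canon

        for p, prob in zip(parts, probs):
            member = [
                lp
                for labels, lp in logs.items()
                if canon(Labeling(labels, l=2)) == p
            ]
            assert prob == pytest.approx(math.exp(logsumexp(member) - Z), abs=1e-10)

    def test_row_order_invariance(self):
        rng = np.random.default_rng(12)
        S = random_masked_pointset(rng, 5, 3)
        model = known_model(3, rng)
        lab = (1, 2, 1, 2, 2)
        perm = [3, 0, 4, 1, 2]
        S2 = PointSet(S.values[perm], S.observed[perm])
        lab2 = tuple(lab[i] for i in perm)
        a = log_posterior_known(S, Labeling(lab, l=2), model)
        b = log_posterior_known(S2, Labeling(lab2, l=2), model)
        assert a == pytest.approx(b, abs=1e-10)

    def test_feature_permutation_invariance(self):
        rng = np.random.default_rng(13)
        S = random_masked_pointset(rng, 5, 3)
        model = known_model(3, rng)
        perm = [2, 0, 1]
        S2 = PointSet(S.values[:, perm], S.observed[:, perm])
        model2 = ModelSpec(
            "known",
            [
                ClusterModel(mu=c.mu[perm], Sigma=c.Sigma[np.ix_(perm, perm)])
                for c in model.clusters
            ],
        )
        lab = Labeling((1, 2, 1, 1, 2), l=2)
        assert log_posterior_known(S, lab, model) == pytest.approx(
            log_posterior_known(S2, lab, model2), abs=1e-10
        )

    def test_mcar_marginalization_by_numeric_integration(self):
        # d=2, one hidden coordinate: the marginalized posterior equals the
        # integral of the complete-data posterior over the hidden value
        rng = np.random.default_rng(14)
        X = rng.normal(size=(4, 2))
        model = known_model(2, rng)
        lab = (1, 2, 2, 1)
        miss = np.ones((4, 2), bool)
        miss[2, 1] = False
        S = PointSet(np.where(miss, X, np.nan))
        lp = log_posterior_known(S, Labeling(lab, l=2), model)

        def integrand(z):
            Xz = X.copy()
            Xz[2, 1] = z
            return math.exp(
                brute_log_posterior(PointSet(Xz), lab, model)
            )

        val, _ = quad(integrand, -30, 30)
        assert lp == pytest.approx(math.log(val), abs=1e-7)
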