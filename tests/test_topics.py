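"""Poisson-NMF topic model: likelihood ascent, recovery, posteriors, fold changes."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import gammaln

import tricontinuum as tc
from tricontinuum.topics import PosteriorTable
from tricontinuum.utils import align_by_correlation


def _em(values: np.ndarray) -> tc.ExpressionMatrix:
    g, n = values.shape
    return tc.ExpressionMatrix(
        pd.DataFrame(values, index=[f"g{i}" for i in range(g)],
                     columns=[f"s{j}" for j in range(n)]))


@pytest.fixture(scope="module")
def planted_counts():
    """Small planted cohort with a sharp likelihood optimum."""
    truth = tc.make_mixture_truth(n_samples=50, n_genes=150, k=3,
                                  marker_block_size=15, noise_model="poisson",
                                  depth=5e3, seed=41)
    m, _ = tc.simulate_bulk_cohort(truth)
    return m.values


class TestFitTopics:
    def test_k1_reaches_saturated_rank_one_likelihood(self):
        """For k=1 the Poisson ML fit is outer(row sums, col sums)/total."""
        rng = np.random.default_rng(21)
        X = rng.poisson(rng.gamma(2.0, 20.0, size=(30, 1)) * rng.uniform(0.5, 2.0, 10))
        fit = tc.fit_topics(_em(X.astype(float)), k=1, em_iters=200, cd_iters=50,
                            seed=0, n_restarts=1)
        P_star = np.outer(X.sum(axis=1), X.sum(axis=0)) / X.sum()
        ll_star = (X * np.log(P_star) - P_star - gammaln(X + 1.0)).sum()
        assert fit.loglik_trace[-1] == pytest.approx(ll_star, abs=1e-6 * abs(ll_star))
        np.testing.assert_allclose(fit.L, 1.0)

    def test_likelihood_trace_never_decreases(self, poisson_cohort):
        m, _ = poisson_cohort
        with pytest.warns(UserWarning):
            fit = tc.fit_topics(m, k=3, em_iters=30, cd_iters=20, seed=3, n_restarts=1)
        assert np.all(np.diff(fit.loglik_trace) >= -1e-6)

    def test_parameter_recovery_on_known_mixture(self, poisson_cohort):
        """Loadings/factors recovered from Poisson counts after topic alignment."""
        m, truth = poisson_cohort
        with pytest.warns(UserWarning):
            fit = tc.fit_topics(m, k=3, em_iters=60, cd_iters=40, seed=4, n_restarts=2)
        F_true = (truth.archetype_profiles /
                  truth.archetype_profiles.sum(axis=1, keepdims=True)).T
        perm = align_by_correlation(fit.F, F_true)
        assert np.abs(fit.L[:, perm] - truth.weights).mean() < 0.05
        for t in range(3):
            assert np.corrcoef(fit.F[:, perm[t]], F_true[:, t])[0, 1] > 0.95

    def test_sample_depth_does_not_change_loadings(self, planted_counts):
        """Topic proportions are depth-independent (Poisson/multinomial equivalence)."""
        X = planted_counts
        X2 = X.copy()
        X2[:, 0] *= 7  # integer scaling keeps counts integral
        with pytest.warns(UserWarning):
            f1 = tc.fit_topics(_em(X), k=3, seed=5, n_restarts=2)
        with pytest.warns(UserWarning):
            f2 = tc.fit_topics(_em(X2), k=3, seed=5, n_restarts=2)
        perm = align_by_correlation(f2.F, f1.F)
        assert np.abs(f2.L[0, perm] - f1.L[0]).max() < 0.05

    def test_gene_and_sample_permutation_equivariance(self, planted_counts):
        X = planted_counts
        rng = np.random.default_rng(23)
        gp = rng.permutation(X.shape[0])
        sp = rng.permutation(X.shape[1])
        with pytest.warns(UserWarning):
            fit = tc.fit_topics(_em(X), k=3, seed=6, n_restarts=2)
        with pytest.warns(UserWarning):
            fit_p = tc.fit_topics(_em(X[np.ix_(gp, sp)]), k=3, seed=6, n_restarts=2)
        perm = align_by_correlation(fit_p.F, fit.F[gp])
        np.testing.assert_allclose(fit_p.F[:, perm], fit.F[gp], atol=5e-3)
        np.testing.assert_allclose(fit_p.L[:, perm], fit.L[sp], atol=5e-2)

    def test_dominant_generation_yields_dominant_loading(self, poisson_cohort):
        """Samples generated >=90% from one component load >0.8 on the matched topic."""
        m, truth = poisson_cohort
        with pytest.warns(UserWarning):
            fit = tc.fit_topics(m, k=3, em_iters=60, cd_iters=40, seed=7, n_restarts=1)
        F_true = (truth.archetype_profiles /
                  truth.archetype_profiles.sum(axis=1, keepdims=True)).T
        perm = align_by_correlation(fit.F, F_true)
        L = fit.L[:, perm]
        dominant = truth.weights.max(axis=1) >= 0.9
        assert dominant.sum() > 5
        idx = truth.weights[dominant].argmax(axis=1)
        assert np.all(L[dominant, idx] > 0.8)

    def test_k_too_large_rejected(self):
        X = np.ones((5, 4))
        with pytest.raises(ValueError, match="k="):
            tc.fit_topics(_em(X), k=4)


class TestPosteriors:
    def test_uniform_likelihood_row_returns_prior(self):
        F = np.array([[0.001, 0.001, 0.001], [0.999, 0.999, 0.999]])
        fit = tc.TopicFit(L=np.full((1, 3), 1 / 3), F=F, k=3,
                          loglik_trace=np.zeros(1), seed=0)
        post = tc.topic_posteriors(fit)
        np.testing.assert_allclose(post.posterior[0], [1 / 3] * 3, atol=1e-12)

    def test_prior_cancels_for_uniform_prior(self):
        """A likelihood row proportional to (0.6, 0.3, 0.1) posterior-normalizes to it."""
        F = np.array([[0.06, 0.03, 0.01], [0.94, 0.97, 0.99]])
        fit = tc.TopicFit(L=np.full((1, 3), 1 / 3), F=F, k=3,
                          loglik_trace=np.zeros(1), seed=0)
        post = tc.topic_posteriors(fit)
        np.testing.assert_allclose(post.posterior[0], [0.6, 0.3, 0.1], atol=1e-12)

    def test_hand_computed_nonuniform_prior(self):
        F = np.array([[0.5, 0.5, 0.0], [0.5, 0.5, 1.0]])
        fit = tc.TopicFit(L=np.full((1, 3), 1 / 3), F=F, k=3,
                          loglik_trace=np.zeros(1), seed=0)
        post = tc.topic_posteriors(fit, prior=np.array([0.8, 0.1, 0.1]))
        np.testing.assert_allclose(post.posterior[0], [0.8 / 0.9, 0.1 / 0.9, 0.0],
                                   atol=1e-12)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_matches_direct_bayes_evaluation(self, seed):
        rng = np.random.default_rng(seed)
        G, k = 20, rng.integers(2, 5)
        F = rng.dirichlet(np.ones(G), size=k).T  # columns sum to 1
        prior = rng.dirichlet(np.ones(k))
        fit = tc.TopicFit(L=np.full((1, k), 1 / k), F=F, k=int(k),
                          loglik_trace=np.zeros(1), seed=0)
        post = tc.topic_posteriors(fit, prior=prior)
        direct = np.array([
            [F[g, t] * prior[t] / sum(F[g, s] * prior[s] for s in range(k))
             for t in range(k)] for g in range(G)
        ])
        np.testing.assert_allclose(post.posterior, direct, atol=1e-12)
        assert np.allclose(post.posterior.sum(axis=1), 1.0, atol=1e-10)

    def test_negative_prior_rejected(self):
        fit = tc.TopicFit(L=np.full((1, 2), 0.5), F=np.array([[1.0, 1.0], [0.0, 0.0]]),
                          k=2, loglik_trace=np.zeros(1), seed=0)
        with pytest.raises(ValueError, match="non-negative"):
            tc.topic_posteriors(fit, prior=np.array([1.5, -0.5]))


class TestGeneLists:
    def test_threshold_rule_rows(self):
        post = PosteriorTable(
            posterior=np.array([[0.6, 0.3, 0.1], [0.45, 0.45, 0.10]]),
            prior=np.full(3, 1 / 3), gene_ids=["g1", "g2"])
        lists = tc.topic_gene_lists(post, cutoff=0.5)
        assert lists == {"topic1": ["g1"], "topic2": [], "topic3": []}

    def test_lists_are_disjoint_above_half(self):
        rng = np.random.default_rng(31)
        P = rng.dirichlet(np.ones(3), size=200)
        post = PosteriorTable(posterior=P, prior=np.full(3, 1 / 3),
                              gene_ids=[f"g{i}" for i in range(200)])
        lists = tc.topic_gene_lists(post, cutoff=0.5)
        all_genes = [g for v in lists.values() for g in v]
        assert len(all_genes) == len(set(all_genes))


class TestTopicDE:
    def test_equal_factors_give_zero_lfc(self):
        F = np.tile(np.array([[0.2], [0.8]]), (1, 3))
        fit = tc.TopicFit(L=np.full((1, 3), 1 / 3), F=F, k=3,
                          loglik_trace=np.zeros(1), seed=0)
        np.testing.assert_allclose(tc.topic_de(fit), 0.0, atol=1e-12)

    def test_fourfold_ratio_gives_lfc_two(self):
        e = 1e-4
        F = np.array([[4 * e, e], [1 - 4 * e, 1 - e]])
        fit = tc.TopicFit(L=np.full((1, 2), 0.5), F=F, k=2,
                          loglik_trace=np.zeros(1), seed=0)
        lfc = tc.topic_de(fit, pseudocount=1e-12)
        assert lfc[0, 0, 1] == pytest.approx(2.0, abs=1e-6)

    def test_antisymmetry(self):
        rng = np.random.default_rng(33)
        F = rng.dirichlet(np.ones(15), size=3).T
        fit = tc.TopicFit(L=np.full((1, 3), 1 / 3), F=F, k=3,
                          loglik_trace=np.zeros(1), seed=0)
        lfc = tc.topic_de(fit)
        np.testing.assert_allclose(lfc, -lfc.transpose(0, 2, 1), atol=1e-12)
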