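"""Collapsed Gibbs sampler: state handling, estimators, likelihoods."""

import math

import numpy as np
import pytest
import scipy.sparse as sp

from littopics.lda import (
    CollapsedGibbsLDA,
    LdaConfig,
    collapsed_word_log_likelihood,
    complete_data_log_likelihood,
    gibbs_sweep,
    init_state,
    predictive_word_prob,
)
from littopics.preprocess import DocumentTermMatrix
from littopics.synthetic import SyntheticSpec, generate_corpus, match_topics


def small_config(T, **kw):
    defaults = dict(n_topics=T, alpha=0.5, beta=0.1, n_iterations=10,
                    burn_in=0, sample_lag=1, seed=0)
    defaults.update(kw)
    return LdaConfig(**defaults)


class TestConfig:
    def test_alpha_defaults_to_50_over_T(self):
        assert LdaConfig(n_topics=25).alpha == pytest.approx(2.0)

    @pytest.mark.parametrize("bad", [
        dict(n_topics=0), dict(n_topics=2, alpha=-1.0), dict(n_topics=2, beta=0.0),
        dict(n_topics=2, burn_in=10, n_iterations=10), dict(n_topics=2, sample_lag=0),
    ])
    def test_invalid_configs_rejected(self, bad):
        with pytest.raises(ValueError):
            LdaConfig(**{"n_iterations": 20, **bad})


class TestInitState:
    def test_single_topic_assigns_everything_to_topic_zero(self, tiny_dtm):
        state = init_state(tiny_dtm, small_config(1))
        assert (state.z == 0).all()
        assert state.topic_totals[0] == tiny_dtm.n_tokens

    def test_same_seed_reproduces_state(self, tiny_dtm):
        cfg = small_config(3, seed=11)
        s1 = init_state(tiny_dtm, cfg)
        s2 = init_state(tiny_dtm, cfg)
        assert np.array_equal(s1.z, s2.z)
        assert np.array_equal(s1.doc_topic_counts, s2.doc_topic_counts)

    def test_count_tables_match_recount_oracle(self):
        rng = np.random.default_rng(3)
        counts = sp.csr_matrix(rng.integers(0, 4, size=(12, 9)))
        dtm = DocumentTermMatrix(counts, np.array([f"w{i}" for i in range(9)], dtype=object))
        state = init_state(dtm, small_config(4, seed=5))
        assert state.recount_consistent()
        assert (state.doc_topic_counts.sum(axis=1) == state.doc_lengths).all()
        assert (state.topic_word_counts.sum(axis=1) == state.topic_totals).all()


class TestGibbsSweep:
    def test_single_topic_sweep_is_noop_on_assignments(self, tiny_dtm):
        cfg = small_config(1)
        rng = np.random.default_rng(0)
        state = init_state(tiny_dtm, cfg, rng)
        z_before = state.z.copy()
        gibbs_sweep(state, cfg, rng)
        assert np.array_equal(state.z, z_before)

    def test_count_consistency_preserved_over_many_sweeps(self, tiny_dtm):
        cfg = small_config(2)
        rng = np.random.default_rng(1)
        state = init_state(tiny_dtm, cfg, rng)
        for _ in range(200):
            gibbs_sweep(state, cfg, rng)
        assert state.recount_consistent()

    def test_disjoint_vocabulary_documents_separate(self):
        # two documents over disjoint 2-word vocabularies; T=2 must
        # concentrate each topic's mass on one vocabulary half
        counts = sp.csr_matrix(np.array([[8, 8, 0, 0], [0, 0, 8, 8]]))
        dtm = DocumentTermMatrix(counts, np.array(list("abcd"), dtype=object))
        model = CollapsedGibbsLDA(
            n_topics=2, alpha=0.1, beta=0.1, n_iterations=600,
            burn_in=300, sample_lag=10, random_state=4,
        ).fit(dtm)
        phi = model.components_
        half = phi[:, :2].sum(axis=1)  # mass on vocabulary half {a, b} per topic
        assert {half.argmax(), half.argmin()} == {0, 1}
        assert max(half) >= 0.95 and min(half) <= 0.05


class TestFit:
    def test_single_topic_closed_form(self, tiny_dtm):
        model = CollapsedGibbsLDA(
            n_topics=1, beta=0.1, n_iterations=4, burn_in=1, sample_lag=1, random_state=0
        ).fit(tiny_dtm)
        assert np.allclose(model.theta_, 1.0)
        counts = np.asarray(tiny_dtm.counts.sum(axis=0)).ravel()
        expected = (counts + 0.1) / (counts.sum() + 0.1 * tiny_dtm.n_terms)
        assert np.allclose(model.components_[0], expected, atol=1e-12)

    def test_zero_length_document_gets_uniform_theta_and_flag(self):
        counts = sp.csr_matrix(np.array([[3, 2], [0, 0]]))
        dtm = DocumentTermMatrix(counts, np.array(["a", "b"], dtype=object))
        model = CollapsedGibbsLDA(
            n_topics=2, alpha=0.5, n_iterations=20, burn_in=10, sample_lag=2, random_state=0
        ).fit(dtm)
        assert list(model.empty_doc_mask_) == [False, True]
        assert np.allclose(model.theta_[1], 0.5)

    def test_rows_sum_to_one(self, tiny_dtm):
        model = CollapsedGibbsLDA(
            n_topics=3, n_iterations=50, burn_in=20, sample_lag=5, random_state=2
        ).fit(tiny_dtm)
        assert np.allclose(model.theta_.sum(axis=1), 1.0, atol=1e-9)
        assert np.allclose(model.components_.sum(axis=1), 1.0, atol=1e-9)
        assert (model.theta_ >= 0).all() and (model.components_ >= 0).all()

    def test_recovers_disjoint_topics_by_cosine(self):
        spec = SyntheticSpec(
            n_topics=3, n_terms=30, years=[2000], docs_per_year=60,
            doc_length=40, disjoint_topics=True,
            base_alpha=np.array([0.5, 0.5, 0.5]), seed=9,
        )
        dtm, truth = generate_corpus(spec)
        model = CollapsedGibbsLDA(
            n_topics=3, alpha=0.5, beta=0.1, n_iterations=400,
            burn_in=200, sample_lag=10, random_state=1,
        ).fit(dtm)
        _, sims = match_topics(truth.phi_true, model.components_)
        assert (sims > 0.95).all()

    def test_diagnostics_trace_present(self, tiny_dtm):
        model = CollapsedGibbsLDA(
            n_topics=2, n_iterations=30, burn_in=10, sample_lag=2, random_state=0
        ).fit(tiny_dtm)
        assert model.sample_log_likelihoods_.shape == (10,)
        assert np.isfinite(model.sample_log_likelihoods_).all()


class TestPredictiveWordProb:
    def test_single_topic_returns_phi(self):
        phi = np.array([[0.2, 0.8]])
        assert predictive_word_prob(np.array([1.0]), phi, 1) == pytest.approx(0.8)

    def test_forced_arithmetic(self):
        theta = np.array([0.3, 0.7])
        phi = np.array([[0.1, 0.9], [0.5, 0.5]])
        assert predictive_word_prob(theta, phi, 0) == pytest.approx(0.38)

    def test_sums_to_one_over_vocabulary(self):
        rng = np.random.default_rng(0)
        theta = rng.dirichlet(np.ones(4))
        phi = rng.dirichlet(np.ones(7), size=4)
        total = sum(predictive_word_prob(theta, phi, v) for v in range(7))
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_out_of_vocabulary_index(self):
        with pytest.raises(IndexError):
            predictive_word_prob(np.array([1.0]), np.array([[0.5, 0.5]]), 2)


class TestCompleteDataLogLikelihood:
    def test_single_token_single_factor(self):
        counts = sp.csr_matrix(np.array([[1, 0]]))
        dtm = DocumentTermMatrix(counts, np.array(["a", "b"], dtype=object))
        state = init_state(dtm, small_config(1))
        theta = np.array([[1.0]])
        phi = np.array([[0.25, 0.75]])
        got = complete_data_log_likelihood(state, theta, phi)
        assert got == pytest.approx(math.log(1.0) + math.log(0.25), abs=1e-12)

    def test_hand_expanded_three_token_case(self):
        # doc0 = [a, a], doc1 = [b]; fixed assignments z = (0, 1, 1)
        counts = sp.csr_matrix(np.array([[2, 0], [0, 1]]))
        dtm = DocumentTermMatrix(counts, np.array(["a", "b"], dtype=object))
        state = init_state(dtm, small_config(2, seed=0))
        state.z[:] = [0, 1, 1]
        ndz, nzv, nz = state.recount()
        state.doc_topic_counts, state.topic_word_counts, state.topic_totals = ndz, nzv, nz
        theta = np.array([[0.6, 0.4], [0.3, 0.7]])
        phi = np.array([[0.9, 0.1], [0.2, 0.8]])
        # term-by-term: n_{0,0}=1, n_{0,1}=1, n_{1,1}=1 over theta;
        # topic0 emitted one 'a', topic1 emitted one 'a' and one 'b'
        expected = (
            math.log(0.6) + math.log(0.4) + math.log(0.7)
            + math.log(0.9) + math.log(0.2) + math.log(0.8)
        )
        got = complete_data_log_likelihood(state, theta, phi)
        assert got == pytest.approx(expected, abs=1e-12)

    def test_zero_probability_with_positive_count_gives_neg_inf(self, tiny_dtm):
        state = init_state(tiny_dtm, small_config(1))
        theta = np.ones((2, 1))
        phi = np.array([[1.0, 0.0, 0.0]])  # words b, c have counts but prob 0
        assert complete_data_log_likelihood(state, theta, phi) == -math.inf

    def test_label_relabeling_invariance(self, tiny_dtm):
        cfg = small_config(3, seed=8)
        rng = np.random.default_rng(8)
        state = init_state(tiny_dtm, cfg, rng)
        for _ in range(10):
            gibbs_sweep(state, cfg, rng)
        rng2 = np.random.default_rng(1)
        theta = rng2.dirichlet(np.ones(3), size=2)
        phi = rng2.dirichlet(np.ones(3), size=3)
        base = complete_data_log_likelihood(state, theta, phi)
        perm = np.array([2, 0, 1])
        state.z = perm[state.z]
        ndz, nzv, nz = state.recount()
        state.doc_topic_counts, state.topic_word_counts, state.topic_totals = ndz, nzv, nz
        inv = np.argsort(perm)  # theta'[:, perm[k]] must equal theta[:, k]
        relabeled = complete_data_log_likelihood(state, theta[:, inv], phi[inv])
        assert relabeled == pytest.approx(base, abs=1e-10)


class TestCollapsedWordLogLikelihood:
    def test_single_token_is_uniform_prior_predictive(self):
        counts = sp.csr_matrix(np.array([[1, 0, 0]]))
        dtm = DocumentTermMatrix(counts, np.array(["a", "b", "c"], dtype=object))
        for beta in (0.1, 0.5, 2.0):
            cfg = small_config(1, beta=beta)
            state = init_state(dtm, cfg)
            assert collapsed_word_log_likelihood(state, cfg) == pytest.approx(
                math.log(1 / 3), abs=1e-12
            )

    def test_two_tokens_same_word_polya_urn(self):
        # V=2, beta=1, both tokens word 'a', T=1: (1/2) * (2/3)
        counts = sp.csr_matrix(np.array([[2, 0]]))
        dtm = DocumentTermMatrix(counts, np.array(["a", "b"], dtype=object))
        cfg = small_config(1, beta=1.0)
        state = init_state(dtm, cfg)
        assert collapsed_word_log_likelihood(state, cfg) == pytest.approx(
            math.log(0.5 * 2 / 3), abs=1e-12
        )

    def test_matches_sequential_predictive_chain_rule(self, tiny_dtm):
        # independent oracle: multiply collapsed one-token-at-a-time predictives
        cfg = small_config(2, beta=0.3, seed=6)
        rng = np.random.default_rng(6)
        state = init_state(tiny_dtm, cfg, rng)
        for _ in range(5):
            gibbs_sweep(state, cfg, rng)
        V = state.n_terms
        beta = cfg.beta
        nzv = np.zeros((2, V))
        nz = np.zeros(2)
        ll = 0.0
        for k, v in zip(state.z, state.word_ids):
            ll += math.log((nzv[k, v] + beta) / (nz[k] + V * beta))
            nzv[k, v] += 1
            nz[k] += 1
        assert collapsed_word_log_likelihood(state, cfg) == pytest.approx(ll, abs=1e-10)


class TestExchangeability:
    def test_posterior_mean_theta_permutes_with_documents(self, tiny_dtm):
        # exact posterior means via enumeration: reversing document order
        # must reverse the theta rows
        from littopics.selection import exact_assignment_log_posterior

        cfg = small_config(2)

        def exact_mean_theta(dtm):
            assigns, logpost = exact_assignment_log_posterior(dtm, 2, cfg)
            post = np.exp(logpost)
            state = init_state(dtm, cfg)
            acc = np.zeros((2, 2))
            for z, p in zip(assigns, post):
                state.z[:] = z
                ndz, _, _ = state.recount()
                theta = (ndz + cfg.alpha) / (ndz.sum(axis=1, keepdims=True) + 2 * cfg.alpha)
                acc += p * theta
            return acc

        fwd = exact_mean_theta(tiny_dtm)
        rev_counts = tiny_dtm.counts.toarray()[::-1]
        rev = exact_mean_theta(
            DocumentTermMatrix(sp.csr_matrix(rev_counts), tiny_dtm.vocab.copy())
        )
        assert np.allclose(fwd, rev[::-1], atol=1e-12)
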