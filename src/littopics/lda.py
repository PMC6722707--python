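"""Latent Dirichlet Allocation via collapsed Gibbs sampling.

The model: each document d draws a topic mixture theta_d ~ Dirichlet(alpha);
each token draws a topic z ~ Multinomial(theta_d) and then a word
w ~ Multinomial(phi_z), with phi_k ~ Dirichlet(beta). The sampler integrates
theta and phi out analytically and resamples one token assignment at a time
from the standard collapsed conditional

    p(z_i = k | z_-i, w) ∝ (n_dk + alpha) * (n_kv + beta) / (n_k + V beta),

where the counts exclude token i. Point estimates theta-hat and phi-hat are
posterior means over retained post-burn-in samples (single chain; averaging
across chains is unsafe under label switching).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.special import gammaln
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .preprocess import DocumentTermMatrix

__all__ = [
    "LdaConfig",
    "GibbsState",
    "CollapsedGibbsLDA",
    "init_state",
    "gibbs_sweep",
    "fit_lda",
    "predictive_word_prob",
    "complete_data_log_likelihood",
    "collapsed_word_log_likelihood",
    "collapsed_assignment_log_prior",
]


# ---------------------------------------------------------------------------
# sweep kernel: numba-compiled when available, pure Python otherwise

def _sweep_py(doc_ids, word_ids, z, ndz, nzv, nz, alpha, beta, u):
    T = ndz.shape[1]
    V = nzv.shape[1]
    vbeta = V * beta
    cum = np.empty(T)
    for i in range(doc_ids.shape[0]):
        d = doc_ids[i]
        v = word_ids[i]
        k = z[i]
        ndz[d, k] -= 1
        nzv[k, v] -= 1
        nz[k] -= 1
        total = 0.0
        for t in range(T):
            total += (ndz[d, t] + alpha) * (nzv[t, v] + beta) / (nz[t] + vbeta)
            cum[t] = total
        r = u[i] * total
        k = 0
        while cum[k] < r and k < T - 1:
            k += 1
        z[i] = k
        ndz[d, k] += 1
        nzv[k, v] += 1
        nz[k] += 1


try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _sweep_kernel = njit(_sweep_py, cache=False)
except ImportError:  # pragma: no cover
    _sweep_kernel = _sweep_py


# ---------------------------------------------------------------------------
# state

@dataclass
class LdaConfig:
    """Sampler configuration. alpha defaults to 50/T, beta to 0.1."""

    n_topics: int
    alpha: float | None = None
    beta: float = 0.1
    n_iterations: int = 2000
    burn_in: int = 1000
    sample_lag: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_topics < 1:
            raise ValueError("n_topics must be >= 1")
        if self.alpha is None:
            self.alpha = 50.0 / self.n_topics
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("alpha and beta must be positive")
        if not (0 <= self.burn_in < self.n_iterations):
            raise ValueError("require 0 <= burn_in < n_iterations")
        if self.sample_lag < 1:
            raise ValueError("sample_lag must be >= 1")


@dataclass
class GibbsState:
    """Token topic assignments and their count tables.

    ``doc_ids``/``word_ids`` are the token stream in document order;
    ``z`` holds one topic index per token. The count tables are always
    the exact tally implied by ``z`` (see :meth:`recount_consistent`).
    """

    doc_ids: np.ndarray
    word_ids: np.ndarray
    z: np.ndarray
    doc_topic_counts: np.ndarray  # D x T
    topic_word_counts: np.ndarray  # T x V
    topic_totals: np.ndarray  # T
    doc_lengths: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.doc_lengths is None:
            self.doc_lengths = self.doc_topic_counts.sum(axis=1)

    @property
    def n_topics(self) -> int:
        return self.doc_topic_counts.shape[1]

    @property
    def n_terms(self) -> int:
        return self.topic_word_counts.shape[1]

    def recount(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Re-tally the three count tables directly from assignments."""
        D, T = self.doc_topic_counts.shape
        V = self.topic_word_counts.shape[1]
        ndz = np.zeros((D, T), dtype=np.int64)
        nzv = np.zeros((T, V), dtype=np.int64)
        np.add.at(ndz, (self.doc_ids, self.z), 1)
        np.add.at(nzv, (self.z, self.word_ids), 1)
        return ndz, nzv, nzv.sum(axis=1)

    def recount_consistent(self) -> bool:
        ndz, nzv, nz = self.recount()
        return (
            np.array_equal(ndz, self.doc_topic_counts)
            and np.array_equal(nzv, self.topic_word_counts)
            and np.array_equal(nz, self.topic_totals)
        )


def _token_stream(dtm: DocumentTermMatrix | sp.spmatrix) -> tuple[np.ndarray, np.ndarray, int, int]:
    counts = dtm.counts if isinstance(dtm, DocumentTermMatrix) else sp.csr_matrix(dtm)
    counts = sp.csr_matrix(counts)
    coo = counts.tocoo()
    order = np.lexsort((coo.col, coo.row))  # document order, column order within doc
    reps = coo.data[order].astype(np.int64)
    doc_ids = np.repeat(coo.row[order].astype(np.int64), reps)
    word_ids = np.repeat(coo.col[order].astype(np.int64), reps)
    return doc_ids, word_ids, counts.shape[0], counts.shape[1]


def init_state(dtm, config: LdaConfig, rng: np.random.Generator | None = None) -> GibbsState:
    """Assign every token a uniformly random topic and tally counts."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    doc_ids, word_ids, D, V = _token_stream(dtm)
    if D == 0:
        raise ValueError("empty document-term matrix")
    T = config.n_topics
    z = rng.integers(T, size=doc_ids.shape[0], dtype=np.int64)
    state = GibbsState(
        doc_ids=doc_ids,
        word_ids=word_ids,
        z=z,
        doc_topic_counts=np.zeros((D, T), dtype=np.int64),
        topic_word_counts=np.zeros((T, V), dtype=np.int64),
        topic_totals=np.zeros(T, dtype=np.int64),
    )
    ndz, nzv, nz = state.recount()
    state.doc_topic_counts = ndz
    state.topic_word_counts = nzv
    state.topic_totals = nz
    state.doc_lengths = ndz.sum(axis=1)
    return state


def gibbs_sweep(state: GibbsState, config: LdaConfig, rng: np.random.Generator) -> GibbsState:
    """Resample every token once, in document order. Mutates ``state``."""
    u = rng.random(state.z.shape[0])
    _sweep_kernel(
        state.doc_ids, state.word_ids, state.z,
        state.doc_topic_counts, state.topic_word_counts, state.topic_totals,
        float(config.alpha), float(config.beta), u,
    )
    return state


# ---------------------------------------------------------------------------
# likelihood quantities

def predictive_word_prob(theta_d: np.ndarray, phi: np.ndarray, v: int) -> float:
    """P(w = v | d) = sum_k theta_dk * phi_kv."""
    theta_d = np.asarray(theta_d, dtype=float)
    phi = np.asarray(phi, dtype=float)
    if not 0 <= v < phi.shape[1]:
        raise IndexError(f"word index {v} outside vocabulary of size {phi.shape[1]}")
    return float(theta_d @ phi[:, v])


def complete_data_log_likelihood(state: GibbsState, theta: np.ndarray, phi: np.ndarray) -> float:
    """log P(Z, W | theta, phi) = sum n_dk log theta_dk + sum n_kv log phi_kv.

    0 * log 0 is taken as 0; a zero probability with a positive count
    yields -inf rather than an exception.
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        lt = np.where(state.doc_topic_counts > 0, np.log(theta), 0.0)
        lp = np.where(state.topic_word_counts > 0, np.log(phi), 0.0)
        out = float(np.sum(state.doc_topic_counts * lt) + np.sum(state.topic_word_counts * lp))
    return out


def collapsed_word_log_likelihood(state: GibbsState, config: LdaConfig) -> float:
    """log P(W | z, beta), with phi integrated out against Dirichlet(beta).

    Equals sum_k [ log G(V beta) - log G(n_k + V beta)
                   + sum_v ( log G(n_kv + beta) - log G(beta) ) ].
    """
    beta = float(config.beta)
    V = state.n_terms
    nzv = state.topic_word_counts
    nz = state.topic_totals
    out = (
        state.n_topics * gammaln(V * beta)
        - gammaln(nz + V * beta).sum()
        + gammaln(nzv + beta).sum()
        - state.n_topics * V * gammaln(beta)
    )
    return float(out)


def collapsed_assignment_log_prior(state: GibbsState, config: LdaConfig) -> float:
    """log P(z | alpha), with theta integrated out against Dirichlet(alpha)."""
    alpha = float(config.alpha)
    T = state.n_topics
    ndz = state.doc_topic_counts
    lens = state.doc_lengths
    D = ndz.shape[0]
    out = (
        D * gammaln(T * alpha)
        - gammaln(lens + T * alpha).sum()
        + gammaln(ndz + alpha).sum()
        - D * T * gammaln(alpha)
    )
    return float(out)


# ---------------------------------------------------------------------------
# estimator

class CollapsedGibbsLDA(BaseEstimator):
    """LDA fitted by collapsed Gibbs sampling.

    Parameters
    ----------
    n_topics : int
        Number of topics T.
    alpha : float, optional
        Symmetric document-topic Dirichlet parameter; defaults to 50/T.
    beta : float, default=0.1
        Symmetric topic-word Dirichlet parameter.
    n_iterations, burn_in, sample_lag : int
        Total sweeps, discarded initial sweeps, and the thinning interval
        for retained samples.
    random_state : int, default=0
        Seed for the single sampling chain.

    Attributes
    ----------
    components_ : np.ndarray, shape (T, V)
        phi-hat: posterior-mean topic-word distributions (rows sum to 1).
    theta_ : np.ndarray, shape (D, T)
        theta-hat: posterior-mean document-topic distributions. Zero-length
        documents get a uniform row and are flagged in ``empty_doc_mask_``.
    sample_log_likelihoods_ : np.ndarray
        Collapsed word log-likelihood log P(W|z, beta) at each retained sample.
    state_ : GibbsState
        Final sampler state.
    """

    def __init__(
        self,
        n_topics: int = 10,
        alpha: float | None = None,
        beta: float = 0.1,
        n_iterations: int = 2000,
        burn_in: int = 1000,
        sample_lag: int = 10,
        random_state: int = 0,
    ):
        self.n_topics = n_topics
        self.alpha = alpha
        self.beta = beta
        self.n_iterations = n_iterations
        self.burn_in = burn_in
        self.sample_lag = sample_lag
        self.random_state = random_state

    def _config(self) -> LdaConfig:
        return LdaConfig(
            n_topics=self.n_topics,
            alpha=self.alpha,
            beta=self.beta,
            n_iterations=self.n_iterations,
            burn_in=self.burn_in,
            sample_lag=self.sample_lag,
            seed=self.random_state,
        )

    def fit(self, X, y=None):
        """Run the chain on a DocumentTermMatrix or sparse count matrix."""
        config = self._config()
        rng = np.random.default_rng(self.random_state)
        state = init_state(X, config, rng)
        T = config.n_topics
        V = state.n_terms
        D = state.doc_topic_counts.shape[0]
        lens = state.doc_lengths

        theta_acc = np.zeros((D, T))
        phi_acc = np.zeros((T, V))
        n_samples = 0
        sample_lls = []
        complete_lls = []
        for it in range(config.n_iterations):
            gibbs_sweep(state, config, rng)
            if it >= config.burn_in and (it - config.burn_in) % config.sample_lag == 0:
                theta_s = (state.doc_topic_counts + config.alpha) / (
                    lens + T * config.alpha
                )[:, None]
                phi_s = (state.topic_word_counts + config.beta) / (
                    state.topic_totals + V * config.beta
                )[:, None]
                theta_acc += theta_s
                phi_acc += phi_s
                n_samples += 1
                sample_lls.append(collapsed_word_log_likelihood(state, config))
                complete_lls.append(complete_data_log_likelihood(state, theta_s, phi_s))
        if n_samples == 0:  # defensive; config validation prevents this
            raise RuntimeError("no samples retained")

        theta = theta_acc / n_samples
        phi = phi_acc / n_samples
        empty = lens == 0
        theta[empty] = 1.0 / T
        theta /= theta.sum(axis=1, keepdims=True)
        phi /= phi.sum(axis=1, keepdims=True)

        self.components_ = phi
        self.theta_ = theta
        self.empty_doc_mask_ = empty
        self.sample_log_likelihoods_ = np.array(sample_lls)
        self.complete_data_log_likelihoods_ = np.array(complete_lls)
        self.state_ = state
        self.n_samples_ = n_samples
        self.config_ = config
        return self

    def fit_transform(self, X, y=None):
        return self.fit(X).theta_

    def transform(self, X=None):
        """Return theta-hat for the training corpus."""
        check_is_fitted(self, "theta_")
        return self.theta_


def fit_lda(dtm, config: LdaConfig):
    """Functional wrapper: returns (theta, phi, diagnostics dict)."""
    model = CollapsedGibbsLDA(
        n_topics=config.n_topics, alpha=config.alpha, beta=config.beta,
        n_iterations=config.n_iterations, burn_in=config.burn_in,
        sample_lag=config.sample_lag, random_state=config.seed,
    ).fit(dtm)
    diagnostics = {
        "sample_log_likelihoods": model.sample_log_likelihoods_,
        "complete_data_log_likelihoods": model.complete_data_log_likelihoods_,
        "n_samples": model.n_samples_,
        "empty_doc_mask": model.empty_doc_mask_,
        "seed": config.seed,
    }
    return model.theta_, model.components_, diagnostics
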