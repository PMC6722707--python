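"""Choosing the number of topics T by harmonic-mean marginal likelihood.

For each candidate T a collapsed Gibbs chain is run and log P(W | T) is
estimated from the retained samples' collapsed word log-likelihoods
ll_s = log P(W | z_s, beta) via the harmonic-mean identity

    log P(W|T)  ~  -( logsumexp(-ll_s) - log S ).

The estimator is known to be high-variance and optimistically biased, but it
is the standard procedure for this selection task and is exact in the
translation and constant-input identities asserted by the tests. An
exhaustive-enumeration evidence computation is provided as an independent
oracle for tiny instances.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .lda import (
    CollapsedGibbsLDA,
    LdaConfig,
    collapsed_assignment_log_prior,
    collapsed_word_log_likelihood,
    init_state,
)

__all__ = [
    "ModelSelectionResult",
    "TopicCountSelector",
    "harmonic_mean_log_evidence",
    "select_n_topics",
    "exact_log_evidence_bruteforce",
    "exact_assignment_log_posterior",
]

logger = logging.getLogger(__name__)

_TIE_TOL = 1e-9


def harmonic_mean_log_evidence(sample_lls) -> float:
    """Harmonic-mean estimate of log evidence from sample log-likelihoods.

    Computed entirely in the log domain, so it is stable for
    log-likelihoods of magnitude 1e4 and beyond.
    """
    lls = np.asarray(sample_lls, dtype=float)
    if lls.ndim != 1 or lls.size < 2:
        raise ValueError("need at least 2 sample log-likelihoods")
    return float(-(logsumexp(-lls) - np.log(lls.size)))


@dataclass
class ModelSelectionResult:
    """Per-candidate evidence estimates and the selected topic count."""

    grid: list[int]
    log_evidence: list[float]
    chosen_T: int
    seeds: dict[int, int]

    def as_table(self):
        import pandas as pd

        return pd.DataFrame({"n_topics": self.grid, "log_evidence": self.log_evidence})


class TopicCountSelector(BaseEstimator):
    """Grid search over the topic count T, scored by harmonic-mean evidence.

    One chain per candidate; candidate seeds are derived deterministically
    from ``random_state``. Ties within 1e-9 nats resolve to the smallest T
    (parsimony). A candidate whose fit fails is excluded with a warning.

    Attributes
    ----------
    result_ : ModelSelectionResult
    best_n_topics_ : int
    models_ : dict mapping T -> fitted CollapsedGibbsLDA
    """

    def __init__(
        self,
        grid=(2, 5, 10, 15, 20),
        alpha: float | None = None,
        beta: float = 0.1,
        n_iterations: int = 2000,
        burn_in: int = 1000,
        sample_lag: int = 10,
        random_state: int = 0,
        keep_models: bool = False,
    ):
        self.grid = grid
        self.alpha = alpha
        self.beta = beta
        self.n_iterations = n_iterations
        self.burn_in = burn_in
        self.sample_lag = sample_lag
        self.random_state = random_state
        self.keep_models = keep_models

    def fit(self, X, y=None):
        grid = sorted(set(int(t) for t in self.grid))
        if not grid or grid[0] < 1:
            raise ValueError("grid must be non-empty with all candidates >= 1")
        master = np.random.default_rng(self.random_state)
        seeds = {T: int(master.integers(2**31)) for T in grid}

        log_evidence: dict[int, float] = {}
        self.models_ = {}
        for T in grid:
            try:
                model = CollapsedGibbsLDA(
                    n_topics=T, alpha=self.alpha, beta=self.beta,
                    n_iterations=self.n_iterations, burn_in=self.burn_in,
                    sample_lag=self.sample_lag, random_state=seeds[T],
                ).fit(X)
                log_evidence[T] = harmonic_mean_log_evidence(model.sample_log_likelihoods_)
                if self.keep_models:
                    self.models_[T] = model
            except Exception as exc:  # candidate excluded, selection continues
                logger.warning("candidate T=%d failed: %s", T, exc)
                warnings.warn(f"topic-count candidate T={T} failed and was excluded: {exc}")
        if not log_evidence:
            raise RuntimeError("every candidate topic count failed to fit")

        valid = sorted(log_evidence)
        best_le = max(log_evidence.values())
        chosen = next(T for T in valid if log_evidence[T] >= best_le - _TIE_TOL)
        self.result_ = ModelSelectionResult(
            grid=valid,
            log_evidence=[log_evidence[T] for T in valid],
            chosen_T=chosen,
            seeds={T: seeds[T] for T in valid},
        )
        self.best_n_topics_ = chosen
        return self

    def transform(self, X=None):
        check_is_fitted(self, "result_")
        return self.result_


def select_n_topics(dtm, grid, config: LdaConfig | None = None, **kwargs) -> ModelSelectionResult:
    """Functional wrapper over :class:`TopicCountSelector`."""
    if config is not None:
        kwargs.setdefault("alpha", None if config.alpha is None else config.alpha)
        kwargs.setdefault("beta", config.beta)
        kwargs.setdefault("n_iterations", config.n_iterations)
        kwargs.setdefault("burn_in", config.burn_in)
        kwargs.setdefault("sample_lag", config.sample_lag)
        kwargs.setdefault("random_state", config.seed)
    sel = TopicCountSelector(grid=grid, **kwargs).fit(dtm)
    return sel.result_


# ---------------------------------------------------------------------------
# exhaustive-enumeration oracles (tiny instances only)

_MAX_TOKENS = 12
_MAX_TOPICS = 3


def _enumerated_terms(dtm, T: int, config: LdaConfig):
    state = init_state(dtm, config, np.random.default_rng(0))
    N = state.z.shape[0]
    if N > _MAX_TOKENS or T > _MAX_TOPICS:
        raise ValueError(
            f"enumeration limited to <= {_MAX_TOKENS} tokens and <= {_MAX_TOPICS} topics "
            f"(got N={N}, T={T})"
        )
    terms = []
    assignments = []
    for z in itertools.product(range(T), repeat=N):
        state.z[:] = z
        ndz, nzv, nz = state.recount()
        state.doc_topic_counts, state.topic_word_counts, state.topic_totals = ndz, nzv, nz
        ll = collapsed_word_log_likelihood(state, config) + collapsed_assignment_log_prior(
            state, config
        )
        terms.append(ll)
        assignments.append(z)
    return assignments, np.array(terms)


def exact_log_evidence_bruteforce(dtm, T: int, config: LdaConfig | None = None) -> float:
    """Exact log P(W | T) by summing P(W|z, beta) P(z|alpha) over all T^N z.

    Refuses instances above 12 tokens or 3 topics.
    """
    if config is None:
        config = LdaConfig(n_topics=T)
    _, terms = _enumerated_terms(dtm, T, config)
    return float(logsumexp(terms))


def exact_assignment_log_posterior(dtm, T: int, config: LdaConfig | None = None):
    """Exact posterior log P(z | W) over all assignment vectors.

    Returns (assignments, log_posterior) with assignments as tuples; the
    independent oracle for sampler-correctness checks.
    """
    if config is None:
        config = LdaConfig(n_topics=T)
    assignments, terms = _enumerated_terms(dtm, T, config)
    return assignments, terms - logsumexp(terms)
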