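"""Synthetic corpora from a known LDA process with year-dependent prevalence.

Documents for year y draw their topic mixture from Dirichlet(a_y) with

    a_y = base_alpha + trend_slopes * (y - years[0]),

so a topic's expected prevalence E[theta_k] = a_yk / sum(a_y) drifts linearly
when the slope vector sums to zero (the sum then stays constant and the
expected mean-theta slope is trend_slopes_k / sum(base_alpha) exactly).
Topic-word rows are symmetric-Dirichlet draws, or block-disjoint supports for
well-separated topics. Token counts are assembled into the same
DocumentTermMatrix the preprocessing pipeline produces, with the full
designed vocabulary kept so columns align with the true phi.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.optimize import linear_sum_assignment

from .preprocess import DocumentTermMatrix

__all__ = [
    "SyntheticSpec",
    "SyntheticTruth",
    "generate_phi",
    "generate_corpus",
    "match_topics",
]


@dataclass
class SyntheticSpec:
    """Ground-truth parameters for corpus generation.

    doc_length is the Poisson mean of document token counts (floored at 1,
    emulating short abstracts). phi_concentration is the symmetric Dirichlet
    parameter for topic-word rows; with disjoint_topics=True each topic
    instead owns an equal, non-overlapping slice of the vocabulary.
    """

    n_topics: int = 3
    n_terms: int = 60
    years: list[int] = field(default_factory=lambda: list(range(1991, 2019)))
    docs_per_year: int = 10
    doc_length: float = 50.0
    phi_concentration: float = 0.1
    disjoint_topics: bool = False
    base_alpha: np.ndarray | None = None
    trend_slopes: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.base_alpha is None:
            self.base_alpha = np.full(self.n_topics, 2.0)
        if self.trend_slopes is None:
            self.trend_slopes = np.zeros(self.n_topics)
        self.base_alpha = np.asarray(self.base_alpha, dtype=float)
        self.trend_slopes = np.asarray(self.trend_slopes, dtype=float)
        self.years = [int(y) for y in self.years]
        if self.n_topics < 1 or self.n_terms < 1:
            raise ValueError("n_topics and n_terms must be >= 1")
        if self.disjoint_topics and self.n_terms < self.n_topics:
            raise ValueError("disjoint topics need n_terms >= n_topics")
        if self.base_alpha.shape != (self.n_topics,) or self.trend_slopes.shape != (
            self.n_topics,
        ):
            raise ValueError("base_alpha and trend_slopes must have length n_topics")
        if self.docs_per_year < 1 or self.doc_length < 1:
            raise ValueError("docs_per_year and doc_length must be >= 1")
        # prevalence weights must stay positive across the whole year span
        for y in (self.years[0], self.years[-1]):
            if np.any(self.alpha_for_year(y) <= 0):
                raise ValueError(
                    f"prevalence weights become non-positive in year {y}; "
                    "shrink trend_slopes or raise base_alpha"
                )

    def alpha_for_year(self, year: int) -> np.ndarray:
        return self.base_alpha + self.trend_slopes * (year - self.years[0])

    @property
    def expected_mean_theta_slope(self) -> np.ndarray:
        """Exact per-year drift of E[theta] when slopes sum to zero."""
        if not np.isclose(self.trend_slopes.sum(), 0.0):
            raise ValueError("closed form requires trend_slopes summing to zero")
        return self.trend_slopes / self.base_alpha.sum()


@dataclass
class SyntheticTruth:
    """The generating parameters actually drawn for one corpus."""

    phi_true: np.ndarray
    theta_true: np.ndarray
    doc_years: np.ndarray
    assignments: list[np.ndarray]  # per-document topic index per token


def generate_phi(spec: SyntheticSpec, rng: np.random.Generator | None = None) -> np.ndarray:
    """Draw the T x V topic-word matrix."""
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    T, V = spec.n_topics, spec.n_terms
    if spec.disjoint_topics:
        phi = np.zeros((T, V))
        bounds = np.linspace(0, V, T + 1).astype(int)
        for k in range(T):
            lo, hi = bounds[k], bounds[k + 1]
            block = rng.dirichlet(np.full(hi - lo, max(spec.phi_concentration, 1.0)))
            phi[k, lo:hi] = block
        return phi
    return rng.dirichlet(np.full(V, spec.phi_concentration), size=T)


def generate_corpus(spec: SyntheticSpec) -> tuple[DocumentTermMatrix, SyntheticTruth]:
    """Sample a corpus and return it with its generating truth.

    Vocabulary terms are zero-padded synthetic words ("w00", "w01", ...) so
    lexicographic vocabulary order equals column order.
    """
    rng = np.random.default_rng(spec.seed)
    phi = generate_phi(spec, rng)
    T, V = phi.shape

    doc_years = []
    thetas = []
    assignments = []
    rows, cols, vals = [], [], []
    doc = 0
    for year in spec.years:
        a_y = spec.alpha_for_year(year)
        if np.any(a_y <= 0):
            raise ValueError(f"non-positive prevalence weight in year {year}")
        for _ in range(spec.docs_per_year):
            theta = rng.dirichlet(a_y)
            length = max(1, int(rng.poisson(spec.doc_length)))
            z = rng.choice(T, size=length, p=theta)
            word_counts = np.zeros(V, dtype=np.int64)
            for k in np.unique(z):
                word_counts += rng.multinomial(int(np.sum(z == k)), phi[k])
            nz = np.nonzero(word_counts)[0]
            rows.extend([doc] * len(nz))
            cols.extend(nz.tolist())
            vals.extend(word_counts[nz].tolist())
            doc_years.append(year)
            thetas.append(theta)
            assignments.append(z)
            doc += 1

    width = len(str(V - 1))
    vocab = np.array([f"w{j:0{width}d}" for j in range(V)], dtype=object)
    counts = sp.csr_matrix((vals, (rows, cols)), shape=(doc, V), dtype=np.int64)
    dtm = DocumentTermMatrix(counts, vocab, np.array(doc_years), min_count=1)
    truth = SyntheticTruth(
        phi_true=phi,
        theta_true=np.array(thetas),
        doc_years=np.array(doc_years),
        assignments=assignments,
    )
    return dtm, truth


def match_topics(phi_true: np.ndarray, phi_est: np.ndarray):
    """One-to-one map of true topics onto estimated topics.

    Solves the assignment problem maximizing total cosine similarity
    (Hungarian algorithm, optimal for any topic count). The estimated set
    may be larger than the true set. Returns (mapping, similarities) where
    mapping[k] is the estimated topic matched to true topic k.
    """
    phi_true = np.asarray(phi_true, dtype=float)
    phi_est = np.asarray(phi_est, dtype=float)
    if phi_true.shape[1] != phi_est.shape[1]:
        raise ValueError("vocabulary sizes differ between true and estimated phi")
    if phi_est.shape[0] < phi_true.shape[0]:
        raise ValueError("estimated topic count must be >= true topic count")
    tn = phi_true / np.linalg.norm(phi_true, axis=1, keepdims=True)
    en = phi_est / np.linalg.norm(phi_est, axis=1, keepdims=True)
    sim = tn @ en.T
    row, col = linear_sum_assignment(-sim)
    mapping = {int(r): int(c) for r, c in zip(row, col)}
    sims = np.array([sim[r, mapping[r]] for r in range(phi_true.shape[0])])
    return mapping, sims
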