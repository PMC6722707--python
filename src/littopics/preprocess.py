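"""Abstract text -> document-term matrix.

Cleaning follows the standard text-mining recipe for abstract corpora:
lowercase, strip punctuation/digits/whitespace, drop stop words, Porter-stem,
then drop terms whose corpus-wide frequency falls below a minimum (default 5).
Documents that end up empty are kept as all-zero rows so that document indices
stay aligned with per-document metadata (publication years in particular);
downstream consumers decide how to treat them.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import scipy.sparse as sp
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from ._porter import porter_stem

__all__ = [
    "TokenizedDoc",
    "DocumentTermMatrix",
    "AbstractVectorizer",
    "load_default_stopwords",
    "tokenize_clean",
    "stem_tokens",
    "build_dtm",
]

_TOKEN_SPLIT = re.compile(r"[^a-z]+")


def load_default_stopwords() -> frozenset[str]:
    """English stop-word list shipped with the package (Glasgow IR list)."""
    text = resources.files("littopics.data").joinpath("stopwords_en.txt").read_text()
    return frozenset(w for w in text.split() if w)


def tokenize_clean(text: str, stopwords: frozenset[str] | set[str] | None = None) -> list[str]:
    """Lowercase, split on non-alphabetic characters, drop stop words.

    Punctuation, digits and whitespace act as separators, so hyphenated
    terms split into their parts. Token order is preserved.
    """
    if stopwords is None:
        stopwords = load_default_stopwords()
    tokens = _TOKEN_SPLIT.split(text.lower())
    return [t for t in tokens if t and t not in stopwords]


def stem_tokens(tokens: list[str]) -> list[str]:
    """Porter-stem each token; length is preserved."""
    return [porter_stem(t) for t in tokens]


@dataclass
class TokenizedDoc:
    """One document's position in the corpus and its cleaned, stemmed tokens."""

    doc_id: int
    tokens: list[str]


@dataclass
class DocumentTermMatrix:
    """Sparse document x term count matrix with its vocabulary.

    Attributes
    ----------
    counts : scipy.sparse.csr_matrix
        D x V integer counts.
    vocab : np.ndarray of str
        Lexicographically sorted, duplicate-free term list of length V.
    doc_years : np.ndarray of int, or None
        Publication year per document (row).
    min_count : int
        Corpus-frequency threshold the vocabulary was filtered at.
    """

    counts: sp.csr_matrix
    vocab: np.ndarray
    doc_years: np.ndarray | None = None
    min_count: int = 1
    empty_doc_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        self.vocab = np.asarray(self.vocab, dtype=object)
        if len(set(self.vocab)) != len(self.vocab):
            raise ValueError("vocabulary contains duplicate terms")
        if self.doc_years is not None:
            self.doc_years = np.asarray(self.doc_years, dtype=int)
            if len(self.doc_years) != self.counts.shape[0]:
                raise ValueError("doc_years length does not match document count")
        if self.empty_doc_mask is None:
            self.empty_doc_mask = np.asarray(self.counts.sum(axis=1)).ravel() == 0

    @property
    def n_docs(self) -> int:
        return self.counts.shape[0]

    @property
    def n_terms(self) -> int:
        return self.counts.shape[1]

    @property
    def n_tokens(self) -> int:
        return int(self.counts.sum())


def build_dtm(
    docs: list[TokenizedDoc] | list[list[str]],
    doc_years=None,
    min_count: int = 5,
) -> DocumentTermMatrix:
    """Count tokens into a sparse matrix, dropping rare terms.

    Terms with total corpus frequency below ``min_count`` are removed from
    the vocabulary. Documents left without tokens stay as all-zero rows and
    are flagged in ``empty_doc_mask``. The vocabulary is sorted
    lexicographically.
    """
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    token_lists = [d.tokens if isinstance(d, TokenizedDoc) else list(d) for d in docs]
    if len(token_lists) == 0:
        raise ValueError("cannot build a document-term matrix from zero documents")

    freq: dict[str, int] = {}
    for toks in token_lists:
        for t in toks:
            freq[t] = freq.get(t, 0) + 1
    vocab = sorted(t for t, c in freq.items() if c >= min_count)
    index = {t: j for j, t in enumerate(vocab)}

    rows, cols, vals = [], [], []
    for i, toks in enumerate(token_lists):
        counts: dict[int, int] = {}
        for t in toks:
            j = index.get(t)
            if j is not None:
                counts[j] = counts.get(j, 0) + 1
        for j, c in counts.items():
            rows.append(i)
            cols.append(j)
            vals.append(c)
    mat = sp.csr_matrix(
        (vals, (rows, cols)), shape=(len(token_lists), len(vocab)), dtype=np.int64
    )
    return DocumentTermMatrix(mat, np.array(vocab, dtype=object), doc_years, min_count)


class AbstractVectorizer(BaseEstimator, TransformerMixin):
    """Transform raw abstracts into a document-term count matrix.

    Parameters
    ----------
    min_count : int, default=5
        Minimum corpus-wide term frequency; rarer terms are dropped.
    stopwords : set of str, optional
        Lowercase stop-word set. Defaults to the packaged English list.
    stem : bool, default=True
        Apply the Porter stemmer after cleaning.

    Attributes
    ----------
    vocabulary_ : np.ndarray of str
        Terms retained after frequency filtering, lexicographic order.
    dtm_ : DocumentTermMatrix
        The matrix built by the last ``fit``.
    """

    def __init__(self, min_count: int = 5, stopwords=None, stem: bool = True):
        self.min_count = min_count
        self.stopwords = stopwords
        self.stem = stem

    def _tokenize(self, text: str, stopwords) -> list[str]:
        toks = tokenize_clean(text, stopwords)
        return stem_tokens(toks) if self.stem else toks

    def fit(self, raw_documents, y=None, doc_years=None):
        stopwords = self.stopwords if self.stopwords is not None else load_default_stopwords()
        token_lists = [self._tokenize(doc, stopwords) for doc in raw_documents]
        self.dtm_ = build_dtm(token_lists, doc_years=doc_years, min_count=self.min_count)
        self.vocabulary_ = self.dtm_.vocab
        return self

    def transform(self, raw_documents):
        check_is_fitted(self, "vocabulary_")
        stopwords = self.stopwords if self.stopwords is not None else load_default_stopwords()
        index = {t: j for j, t in enumerate(self.vocabulary_)}
        rows, cols, vals = [], [], []
        n = 0
        for i, doc in enumerate(raw_documents):
            n = i + 1
            counts: dict[int, int] = {}
            for t in self._tokenize(doc, stopwords):
                j = index.get(t)
                if j is not None:
                    counts[j] = counts.get(j, 0) + 1
            for j, c in counts.items():
                rows.append(i)
                cols.append(j)
                vals.append(c)
        return sp.csr_matrix((vals, (rows, cols)), shape=(n, len(index)), dtype=np.int64)

    def fit_transform(self, raw_documents, y=None, **fit_params):
        self.fit(raw_documents, **fit_params)
        return self.dtm_.counts

    def get_feature_names_out(self, input_features=None):
        check_is_fitted(self, "vocabulary_")
        return np.asarray(self.vocabulary_, dtype=object)
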