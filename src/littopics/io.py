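"""Plain-text serialization of matrices and result tables.

The document-term matrix travels as a MatrixMarket sparse triplet file plus
a vocabulary file (one term per line) and, optionally, a years file (one
integer per document row). Dense theta/phi matrices and summary tables are
written as tab-delimited text with a header row.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .preprocess import DocumentTermMatrix

__all__ = ["write_dtm", "read_dtm", "write_matrix", "read_matrix", "write_table"]


def write_dtm(dtm: DocumentTermMatrix, prefix: str) -> None:
    """Write ``<prefix>.mtx``, ``<prefix>.vocab.txt`` and ``<prefix>.years.txt``."""
    scipy.io.mmwrite(prefix + ".mtx", dtm.counts)
    with open(prefix + ".vocab.txt", "w") as fh:
        fh.write("\n".join(str(t) for t in dtm.vocab) + "\n")
    if dtm.doc_years is not None:
        np.savetxt(prefix + ".years.txt", dtm.doc_years, fmt="%d")


def read_dtm(prefix: str, min_count: int = 1) -> DocumentTermMatrix:
    counts = sp.csr_matrix(scipy.io.mmread(prefix + ".mtx"))
    with open(prefix + ".vocab.txt") as fh:
        vocab = np.array([line.strip() for line in fh if line.strip()], dtype=object)
    years_path = prefix + ".years.txt"
    years = np.loadtxt(years_path, dtype=int) if os.path.exists(years_path) else None
    return DocumentTermMatrix(counts, vocab, years, min_count=min_count)


def write_matrix(values: np.ndarray, path: str, col_prefix: str = "c") -> None:
    """Dense matrix as TSV with a header row naming the columns."""
    cols = [f"{col_prefix}{j}" for j in range(np.asarray(values).shape[1])]
    pd.DataFrame(values, columns=cols).to_csv(path, sep="\t", index=False)


def read_matrix(path: str) -> np.ndarray:
    return pd.read_csv(path, sep="\t").to_numpy(dtype=float)


def write_table(df: pd.DataFrame, path: str, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)
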