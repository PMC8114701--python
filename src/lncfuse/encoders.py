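"""The two sequence encodings: p-nucleotide token vectors and one-hot matrices.

*p-nucleotide encoding* tokenizes a sequence with a non-overlapping window
of ``p`` bases (both window length and stride equal ``p``); each of the
``4**p`` possible words maps to a unique positive integer and 0 is reserved
for trailing zero-padding.  The word->integer map is lexicographic with
digit order A<T<C<G, matching the one-hot row order, so it is invertible::

    token(w) = 1 + sum_i digit(w[i]) * 4**(p-1-i),  digit(A,T,C,G) = 0,1,2,3

*One-hot encoding* represents a sequence as a 4xN binary matrix with rows
(A, T, C, G); column j is the unit vector of base j, and sequences shorter
than N get trailing all-zero columns.

Batch widths (the token-vector length ``floor(max L / p)`` and the one-hot
column count ``N = max L``) are derived from the training set; longer
test-time sequences are truncated with a warning.
"""

from __future__ import annotations

import itertools
import logging
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from lncfuse.io import Transcript

logger = logging.getLogger(__name__)

BASE_ORDER = "ATCG"
_DIGIT = {b: i for i, b in enumerate(BASE_ORDER)}


def _as_seq(t: "Transcript | str") -> str:
    return t.seq if isinstance(t, Transcript) else t


def token_index(word: str) -> int:
    """Integer token (1 .. 4**p) of a p-base word."""
    idx = 0
    for ch in word:
        idx = idx * 4 + _DIGIT[ch]
    return idx + 1


def token_word(token: int, p: int) -> str:
    """Inverse of :func:`token_index` for a given word length ``p``."""
    if not 1 <= token <= 4**p:
        raise ValueError(f"token {token} outside 1..{4 ** p}")
    digits = []
    x = token - 1
    for _ in range(p):
        digits.append(x % 4)
        x //= 4
    return "".join(BASE_ORDER[d] for d in reversed(digits))


def vocabulary(p: int) -> list[str]:
    """All 4**p words in token order (token i+1 is vocabulary()[i])."""
    return ["".join(w) for w in itertools.product(BASE_ORDER, repeat=p)]


def encode_pnt(
    t: "Transcript | str",
    p: int = 3,
    width: int | None = None,
    truncate: bool = False,
) -> np.ndarray:
    """Encode a sequence as a zero-padded p-nucleotide token vector.

    A trailing partial window (``L mod p != 0``) is discarded.  ``width``
    pads (trailing zeros) or, when ``truncate=True``, truncates to a fixed
    length; by default it is the unpadded token count ``floor(L / p)``.
    """
    seq = _as_seq(t)
    if p < 1:
        raise ValueError(f"p must be >= 1, got {p}")
    n_tokens = len(seq) // p
    tokens = np.fromiter(
        (token_index(seq[i * p : (i + 1) * p]) for i in range(n_tokens)),
        dtype=np.int64,
        count=n_tokens,
    )
    if width is None:
        return tokens
    if width < n_tokens:
        if not truncate:
            raise ValueError(
                f"width {width} < token count {n_tokens}; pass truncate=True "
                "to truncate long sequences"
            )
        logger.warning("truncating token vector from %d to %d", n_tokens, width)
        return tokens[:width]
    out = np.zeros(width, dtype=np.int64)
    out[:n_tokens] = tokens
    return out


def encode_onehot(t: "Transcript | str", n_columns: int | None = None) -> np.ndarray:
    """Encode a sequence as a 4 x N one-hot matrix (rows A, T, C, G).

    Shorter sequences are zero-padded on trailing columns; longer ones are
    truncated to the first N columns with a warning.
    """
    seq = _as_seq(t)
    L = len(seq)
    if n_columns is None:
        n_columns = L
    if n_columns < 1:
        raise ValueError(f"n_columns must be >= 1, got {n_columns}")
    if L > n_columns:
        logger.warning("truncating sequence from %d to %d columns", L, n_columns)
        seq = seq[:n_columns]
        L = n_columns
    mat = np.zeros((4, n_columns), dtype=np.int8)
    cols = np.fromiter((_DIGIT[ch] for ch in seq), dtype=np.int64, count=L)
    mat[cols, np.arange(L)] = 1
    return mat


def batch_width(samples: Sequence["Transcript | str"], p: int) -> int:
    """Token-vector width ``floor(max L / p)`` of a (training) batch."""
    if len(samples) == 0:
        raise ValueError("empty sample list")
    return max(len(_as_seq(t)) for t in samples) // p


def batch_columns(samples: Sequence["Transcript | str"]) -> int:
    """One-hot column count ``N = max L`` of a (training) batch."""
    if len(samples) == 0:
        raise ValueError("empty sample list")
    return max(len(_as_seq(t)) for t in samples)


def encode_pnt_batch(
    samples: Sequence["Transcript | str"], p: int = 3, width: int | None = None
) -> np.ndarray:
    """Stack token vectors of a batch into an (n, width) integer array."""
    if width is None:
        width = batch_width(samples, p)
    return np.stack([encode_pnt(t, p=p, width=width, truncate=True) for t in samples])


def encode_onehot_batch(
    samples: Sequence["Transcript | str"], n_columns: int | None = None
) -> np.ndarray:
    """Stack one-hot matrices of a batch into an (n, 4, N) array."""
    if n_columns is None:
        n_columns = batch_columns(samples)
    return np.stack([encode_onehot(t, n_columns=n_columns) for t in samples])


class PNucleotideEncoder(BaseEstimator, TransformerMixin):
    """Sklearn transformer wrapping the p-nucleotide token encoding.

    ``fit`` learns the padded width ``floor(max L / p)`` from the training
    batch (unless ``width`` is given); ``transform`` returns an (n, width)
    int64 array, truncating longer test-time sequences.
    """

    def __init__(self, p: int = 3, width: int | None = None):
        self.p = p
        self.width = width

    def fit(self, X, y=None):
        if self.p < 1:
            raise ValueError(f"p must be >= 1, got {self.p}")
        self.width_ = self.width if self.width is not None else batch_width(X, self.p)
        self.vocab_size_ = 4**self.p + 1  # words + padding token 0
        return self

    def transform(self, X) -> np.ndarray:
        return encode_pnt_batch(X, p=self.p, width=self.width_)


class OneHotSequenceEncoder(BaseEstimator, TransformerMixin):
    """Sklearn transformer wrapping the one-hot matrix encoding.

    ``fit`` learns ``n_columns_ = max L`` from the training batch (unless
    ``n_columns`` is given); ``transform`` returns an (n, 4, N) int8 array.
    """

    def __init__(self, n_columns: int | None = None):
        self.n_columns = n_columns

    def fit(self, X, y=None):
        self.n_columns_ = (
            self.n_columns if self.n_columns is not None else batch_columns(X)
        )
        return self

    def transform(self, X) -> np.ndarray:
        return encode_onehot_batch(X, n_columns=self.n_columns_)
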