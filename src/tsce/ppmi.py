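"""Count-based embeddings: temporal co-occurrence, PPMI transform, SVD.

Co-occurrence is counted over time segments (see
:func:`tsce.context.segment_visits`): every unordered pair of distinct
tokens in a segment contributes the product of their multiplicities.
Only the time regimes are supported — there is no patient-level or
baseline variant of this learner.

Probability space is ordered co-occurrence pairs (each unordered pair
counted twice), so marginals are row sums; natural log throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from collections import Counter
from pathlib import Path

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import svds

from .context import ContextSpec, segment_visits
from .records import Corpus
from .sgns import EmbeddingMatrix

__all__ = [
    "CooccurrenceMatrix",
    "PPMIMatrix",
    "SVDResult",
    "count_cooccurrence",
    "ppmi_transform",
    "svd_embed",
    "train_ppmi",
]


@dataclass
class CooccurrenceMatrix:
    """Symmetric token co-occurrence counts with a zero diagonal."""

    counts: sp.csr_matrix
    tokens: list[str]
    total_pairs: int

    def save_mtx(self, path: str | Path) -> None:
        from scipy.io import mmwrite

        mmwrite(str(path), self.counts)


@dataclass
class PPMIMatrix:
    """Positive pointwise mutual information transform of the counts."""

    values: sp.csr_matrix
    tokens: list[str]

    def save_mtx(self, path: str | Path) -> None:
        from scipy.io import mmwrite

        mmwrite(str(path), self.values)


@dataclass
class SVDResult:
    """Truncated SVD of the PPMI matrix; rows of U are the embeddings."""

    U: np.ndarray
    S: np.ndarray
    tokens: list[str]

    def to_embedding(self, weighted: bool = False) -> EmbeddingMatrix:
        """Rows of U as embeddings; optionally scaled by sqrt(S)."""
        vectors = self.U * np.sqrt(self.S) if weighted else self.U
        return EmbeddingMatrix(self.tokens, vectors)


def count_cooccurrence(
    corpus: Corpus, spec: ContextSpec, binary: bool = False
) -> CooccurrenceMatrix:
    """Count segment-level co-occurrences under a time regime.

    For each segment, each unordered pair of distinct tokens (i, j)
    increments C(i, j) and C(j, i) by the product of the tokens'
    multiplicities in the segment (or by 1 if ``binary``).  The diagonal
    stays zero: a concept does not co-occur with itself.
    """
    if spec.mode != "time":
        raise ValueError(
            "co-occurrence counting supports only time regimes "
            "(visit-level or N-day); there is no baseline variant"
        )
    vocab = corpus.vocabulary
    accum: Counter[tuple[int, int]] = Counter()
    for record in corpus.records:
        for segment in segment_visits(record, spec.half_window_days):
            multiplicities = Counter(
                vocab[t] for t in segment if t in vocab
            )
            items = sorted(multiplicities.items())
            for a in range(len(items)):
                i, mi = items[a]
                for b in range(a + 1, len(items)):
                    j, mj = items[b]
                    accum[(i, j)] += 1 if binary else mi * mj
    V = len(vocab)
    if accum:
        ij = np.array(list(accum.keys()), dtype=np.int64)
        vals = np.array(list(accum.values()), dtype=np.int64)
        rows = np.concatenate([ij[:, 0], ij[:, 1]])
        cols = np.concatenate([ij[:, 1], ij[:, 0]])
        data = np.concatenate([vals, vals])
        counts = sp.csr_matrix((data, (rows, cols)), shape=(V, V))
    else:
        counts = sp.csr_matrix((V, V), dtype=np.int64)
    total = int(sum(accum.values()))
    return CooccurrenceMatrix(counts=counts, tokens=list(vocab.tokens), total_pairs=total)


def ppmi_transform(cooc: CooccurrenceMatrix) -> PPMIMatrix:
    """max(0, ln p(i,j) - ln p(i) - ln p(j)) on the non-zero entries.

    p(i, j) = C(i, j) / (2 * total_pairs) over ordered pairs;
    p(i) is the row-sum marginal.
    """
    if cooc.total_pairs < 1:
        raise ValueError("empty co-occurrence matrix: no pairs counted")
    denom = 2.0 * cooc.total_pairs
    coo = cooc.counts.tocoo()
    marginals = np.asarray(cooc.counts.sum(axis=1)).ravel() / denom
    log_joint = np.log(coo.data / denom)
    pmi = log_joint - np.log(marginals[coo.row]) - np.log(marginals[coo.col])
    keep = pmi > 0
    values = sp.csr_matrix(
        (pmi[keep], (coo.row[keep], coo.col[keep])), shape=cooc.counts.shape
    )
    return PPMIMatrix(values=values, tokens=list(cooc.tokens))


def svd_embed(M: PPMIMatrix, d: int, seed: int = 0) -> SVDResult:
    """Truncated rank-d SVD of the PPMI matrix.

    Deterministic: the iterative solver is started from a seeded vector
    and column signs are canonicalized so each column of U has its
    largest-magnitude entry positive.
    """
    V = M.values.shape[0]
    if not 1 <= d <= V:
        raise ValueError(f"d must satisfy 1 <= d <= {V}, got {d}")
    if d >= V:  # svds needs k < min(shape); fall back to dense
        U, S, _ = np.linalg.svd(M.values.toarray(), full_matrices=False)
        U, S = U[:, :d], S[:d]
    else:
        rng = np.random.default_rng(seed)
        v0 = rng.random(V)
        U, S, _ = svds(M.values.astype(np.float64), k=d, v0=v0)
        order = np.argsort(S)[::-1]
        U, S = U[:, order], S[order]
    for j in range(U.shape[1]):
        lead = np.argmax(np.abs(U[:, j]))
        if U[lead, j] < 0:
            U[:, j] = -U[:, j]
    return SVDResult(U=U, S=S, tokens=list(M.tokens))


def train_ppmi(
    corpus: Corpus,
    spec: ContextSpec,
    dim: int,
    seed: int = 0,
    binary: bool = False,
    weighted: bool = False,
) -> EmbeddingMatrix:
    """Full pipeline: count -> PPMI -> truncated SVD -> embeddings."""
    cooc = count_cooccurrence(corpus, spec, binary=binary)
    ppmi = ppmi_transform(cooc)
    result = svd_embed(ppmi, d=dim, seed=seed)
    return result.to_embedding(weighted=weighted)
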