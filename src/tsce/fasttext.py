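"""Subword (character n-gram) concept embeddings.

A concept's target-side vector is the *sum* of the vectors of the
character n-grams of its rendered token string (type prefix included,
so "D_493.xx" codes share subword mass through both the "D_" namespace
and the ICD prefix).  The context (output) side uses whole-token vectors
only.  Training reuses the negative-sampling pair streams of the
skip-gram learner; scoring replaces the target vector with the n-gram
sum, and gradients are distributed over the constituent n-gram vectors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .context import ContextSpec
from .records import Corpus
from .sgns import (
    EmbeddingMatrix,
    SGNSConfig,
    TrainingError,
    _log_sigmoid,
    build_noise_distribution,
    collect_pairs,
)

__all__ = [
    "NGramConfig",
    "FastTextModel",
    "extract_ngrams",
    "compose_vector",
    "train_fasttext",
]


@dataclass
class NGramConfig:
    """N-gram extraction settings.

    Tokens are optionally wrapped in angle-bracket boundary markers
    before substring extraction; the (wrapped) whole token is appended
    as its own entry when ``include_whole_token``.  Tokens with corpus
    count below ``freq_threshold_P`` compose from character n-grams only
    (no whole-token entry).  ``bucket_count`` switches the exact n-gram
    table to hashed buckets (a speed/memory device only).
    """

    min_n: int = 3
    max_n: int = 6
    add_boundaries: bool = True
    include_whole_token: bool = True
    freq_threshold_P: int = 0
    bucket_count: int | None = None

    def __post_init__(self) -> None:
        if not 1 <= self.min_n <= self.max_n:
            raise ValueError(
                f"need 1 <= min_n <= max_n, got {self.min_n}..{self.max_n}"
            )
        if self.freq_threshold_P < 0:
            raise ValueError("freq_threshold_P must be >= 0")
        if self.bucket_count is not None and self.bucket_count < 1:
            raise ValueError("bucket_count must be >= 1")


def extract_ngrams(
    token: str, config: NGramConfig, count: int | None = None
) -> list[str]:
    """Character n-grams of a token, ordered by position then length.

    The whole (wrapped) token is appended last when configured and the
    token's corpus ``count`` (if given) reaches ``freq_threshold_P``.
    Duplicates are removed, first occurrence kept.
    """
    if not token:
        raise ValueError("token must be non-empty")
    wrapped = f"<{token}>" if config.add_boundaries else token
    grams: list[str] = []
    for i in range(len(wrapped)):
        for n in range(config.min_n, config.max_n + 1):
            if i + n <= len(wrapped):
                grams.append(wrapped[i : i + n])
    if config.include_whole_token and (
        count is None or count >= config.freq_threshold_P
    ):
        grams.append(wrapped)
    seen: set[str] = set()
    unique = []
    for g in grams:
        if g not in seen:
            seen.add(g)
            unique.append(g)
    return unique


def _hash_gram(gram: str, buckets: int) -> int:
    # FNV-1a over utf-8 bytes
    h = 0x811C9DC5
    for byte in gram.encode("utf-8"):
        h ^= byte
        h = (h * 0x01000193) & 0xFFFFFFFF
    return h % buckets


class FastTextModel:
    """N-gram vector table plus whole-token output vectors."""

    def __init__(
        self,
        vocabulary: list[str],
        config: NGramConfig,
        ngram_index: dict[str, int],
        ngram_vectors: np.ndarray,
        output_vectors: np.ndarray,
        token_rows: list[np.ndarray],
    ) -> None:
        self.vocabulary = list(vocabulary)
        self.config = config
        self.ngram_index = ngram_index
        self.ngram_vectors = ngram_vectors
        self.output_vectors = output_vectors
        self.token_rows = token_rows  # per-vocab-token n-gram row indices
        self._index = {t: i for i, t in enumerate(self.vocabulary)}
        self.epoch_losses: list[float] = []

    @property
    def dim(self) -> int:
        return self.ngram_vectors.shape[1]

    def gram_rows(self, token: str) -> np.ndarray:
        """Known n-gram table rows for an arbitrary (possibly OOV) token."""
        idx = self._index.get(token)
        if idx is not None:
            return self.token_rows[idx]
        rows = []
        for gram in extract_ngrams(token, self.config):
            if self.config.bucket_count is not None:
                rows.append(_hash_gram(gram, self.config.bucket_count))
            else:
                row = self.ngram_index.get(gram)
                if row is not None:
                    rows.append(row)
        return np.array(sorted(set(rows)), dtype=np.int64)

    def to_embedding(self) -> EmbeddingMatrix:
        """Composed vectors for every vocabulary token."""
        vectors = np.stack(
            [compose_vector(self, t) for t in self.vocabulary]
        )
        return EmbeddingMatrix(self.vocabulary, vectors, self.output_vectors)

    def save_ngrams(self, path: str | Path, fmt: str = "%.6f") -> None:
        with open(path, "w", encoding="utf-8") as handle:
            for gram, row in sorted(self.ngram_index.items(), key=lambda kv: kv[1]):
                values = "\t".join(fmt % x for x in self.ngram_vectors[row])
                handle.write(f"{gram}\t{values}\n")


def compose_vector(model: FastTextModel, token: str) -> np.ndarray:
    """Sum of the token's n-gram vectors (exact identity, no averaging).

    Unknown tokens compose from whatever of their n-grams are in the
    table; a token with no known n-grams yields a zero vector with a
    warning.
    """
    rows = model.gram_rows(token)
    if len(rows) == 0:
        warnings.warn(
            f"token {token!r} has no known n-grams; returning zero vector",
            stacklevel=2,
        )
        return np.zeros(model.dim)
    return model.ngram_vectors[rows].sum(axis=0)


def _build_gram_table(
    vocab_tokens: list[str],
    counts: dict[str, int],
    config: NGramConfig,
) -> tuple[dict[str, int], list[np.ndarray], int]:
    """Map every vocabulary token to its n-gram row indices."""
    ngram_index: dict[str, int] = {}
    token_rows: list[np.ndarray] = []
    for token in vocab_tokens:
        grams = extract_ngrams(token, config, count=counts[token])
        rows = []
        for gram in grams:
            if config.bucket_count is not None:
                rows.append(_hash_gram(gram, config.bucket_count))
            else:
                if gram not in ngram_index:
                    ngram_index[gram] = len(ngram_index)
                rows.append(ngram_index[gram])
        if not rows:
            raise TrainingError(
                f"token {token!r} has no n-grams under the current config "
                "(min_n too large and whole-token entry disabled?)"
            )
        token_rows.append(np.array(sorted(set(rows)), dtype=np.int64))
    n_rows = (
        config.bucket_count if config.bucket_count is not None else len(ngram_index)
    )
    return ngram_index, token_rows, n_rows


def train_fasttext(
    corpus: Corpus,
    spec: ContextSpec,
    sg_config: SGNSConfig,
    ng_config: NGramConfig | None = None,
) -> FastTextModel:
    """Negative-sampling SGD with subword-composed target scores.

    Same pair streams, noise distribution and learning-rate schedule as
    the whole-token learner; the target-side vector is the sum of the
    target's n-gram vectors and each constituent receives the full
    target gradient.  Deterministic given the seed.
    """
    from scipy.special import expit

    if ng_config is None:
        ng_config = NGramConfig()
    vocab = corpus.vocabulary
    if len(vocab) == 0:
        raise TrainingError("vocabulary is empty; nothing to train")
    pairs, weights = collect_pairs(
        corpus, spec, patient_weighting=sg_config.patient_weighting
    )
    if len(pairs) == 0:
        raise TrainingError("context pair stream is empty under the chosen window")

    ngram_index, token_rows, n_rows = _build_gram_table(
        list(vocab.tokens), vocab.counts, ng_config
    )
    rng = np.random.default_rng(sg_config.seed)
    V, dim = len(vocab), sg_config.dim
    z = (rng.random((n_rows, dim)) - 0.5) / dim
    w_out = np.zeros((V, dim))
    counts = np.array([vocab.counts[t] for t in vocab.tokens], dtype=np.float64)
    noise_cdf = build_noise_distribution(counts, sg_config.noise_exponent)

    model = FastTextModel(
        vocabulary=list(vocab.tokens),
        config=ng_config,
        ngram_index=ngram_index,
        ngram_vectors=z,
        output_vectors=w_out,
        token_rows=token_rows,
    )
    k = sg_config.negatives
    lr0 = sg_config.learning_rate
    lr_floor = lr0 / 10.0
    total = sg_config.epochs * len(pairs)
    step = 0
    for _ in range(sg_config.epochs):
        order = rng.permutation(len(pairs))
        epoch_loss = 0.0
        for idx in order:
            t, c = pairs[idx]
            lr = (lr0 + (lr_floor - lr0) * (step / total)) * weights[idx]
            rows_t = token_rows[t]
            v = z[rows_t].sum(axis=0)
            negs = np.searchsorted(noise_cdf, rng.random(k))
            out_rows = np.concatenate(([c], negs))
            scores = w_out[out_rows] @ v
            sig = expit(scores)
            epoch_loss += -_log_sigmoid(scores[0]) - _log_sigmoid(
                -scores[1:]
            ).sum()
            err = sig.copy()
            err[0] -= 1.0
            grad_v = err @ w_out[out_rows]
            np.add.at(w_out, out_rows, (-lr * err)[:, None] * v[None, :])
            z[rows_t] -= lr * grad_v[None, :]
            step += 1
        model.epoch_losses.append(epoch_loss / len(pairs))
    if not np.all(np.isfinite(z)) or not np.all(np.isfinite(w_out)):
        raise TrainingError("training diverged: non-finite vectors")
    return model
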