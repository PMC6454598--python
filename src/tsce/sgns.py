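"""Skip-gram with negative sampling over temporal context pair streams.

The published objective is a full softmax over the vocabulary; training
uses the standard negative-sampling surrogate (noise drawn from the
unigram distribution raised to 0.75).  The full softmax is kept as a
reference scorer (:func:`softmax_prob`) for testing.

The reference path is single-threaded and fully deterministic given the
config seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .context import ContextSpec, iter_pairs
from .records import Corpus

__all__ = [
    "SGNSConfig",
    "EmbeddingMatrix",
    "TrainingError",
    "softmax_prob",
    "ns_loss",
    "ns_gradients",
    "build_noise_distribution",
    "collect_pairs",
    "train_sgns",
]


class TrainingError(RuntimeError):
    """Raised when a learner cannot train on the given inputs."""


@dataclass
class SGNSConfig:
    """Hyper-parameters for negative-sampling skip-gram training.

    Epochs, learning rate and negative count are word2vec conventions;
    the embedding dimension default (200) matches the published setup.
    ``subsample`` (frequent-token subsampling) is off by default.
    ``patient_weighting`` scales each patient's pair updates by the
    reciprocal of its total event count; off by default (uniform pair
    streaming already weights patients by their pair mass).
    """

    dim: int = 200
    epochs: int = 5
    learning_rate: float = 0.025
    negatives: int = 5
    noise_exponent: float = 0.75
    seed: int = 0
    subsample: float = 0.0
    patient_weighting: bool = False

    def __post_init__(self) -> None:
        if self.dim < 1:
            raise ValueError("dim must be >= 1")
        if self.negatives < 1:
            raise ValueError("negatives must be >= 1")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


class EmbeddingMatrix:
    """Vocabulary-indexed input (published) and output (context) vectors."""

    def __init__(
        self,
        vocabulary: list[str],
        input_vectors: np.ndarray,
        output_vectors: np.ndarray | None = None,
    ) -> None:
        input_vectors = np.asarray(input_vectors, dtype=np.float64)
        if input_vectors.shape[0] != len(vocabulary):
            raise ValueError("input_vectors row count must equal vocabulary size")
        if output_vectors is None:
            output_vectors = np.zeros_like(input_vectors)
        output_vectors = np.asarray(output_vectors, dtype=np.float64)
        if output_vectors.shape != input_vectors.shape:
            raise ValueError("output_vectors shape must match input_vectors")
        self.vocabulary = list(vocabulary)
        self.input_vectors = input_vectors
        self.output_vectors = output_vectors
        self._index = {t: i for i, t in enumerate(self.vocabulary)}
        self.epoch_losses: list[float] = []

    @property
    def dim(self) -> int:
        return self.input_vectors.shape[1]

    def __len__(self) -> int:
        return len(self.vocabulary)

    def __contains__(self, token: str) -> bool:
        return token in self._index

    def index(self, token: str) -> int:
        try:
            return self._index[token]
        except KeyError:
            raise KeyError(f"token {token!r} not in vocabulary") from None

    def vector(self, token: str) -> np.ndarray:
        return self.input_vectors[self.index(token)]

    def save_word2vec(self, path: str | Path, fmt: str = "%.6f") -> None:
        """Write the input vectors in word2vec text format."""
        with open(path, "w", encoding="utf-8") as handle:
            handle.write(f"{len(self.vocabulary)} {self.dim}\n")
            for token, row in zip(self.vocabulary, self.input_vectors):
                values = " ".join(fmt % x for x in row)
                handle.write(f"{token} {values}\n")

    @classmethod
    def load_word2vec(cls, path: str | Path) -> "EmbeddingMatrix":
        with open(path, "r", encoding="utf-8") as handle:
            header = handle.readline().split()
            if len(header) != 2:
                raise ValueError("missing word2vec header line")
            n, dim = int(header[0]), int(header[1])
            tokens: list[str] = []
            rows = np.empty((n, dim), dtype=np.float64)
            for i in range(n):
                parts = handle.readline().rstrip("\n").split(" ")
                if len(parts) != dim + 1:
                    raise ValueError(f"embedding row {i} has wrong arity")
                tokens.append(parts[0])
                rows[i] = [float(x) for x in parts[1:]]
        return cls(tokens, rows)


def softmax_prob(model: EmbeddingMatrix, target: str, context: str) -> float:
    """Reference full-softmax probability p(context | target).

    exp(v'_ctx . v_tgt) / sum_C exp(v'_C . v_tgt), computed with the
    usual max-shift for numerical stability.
    """
    t = model.index(target)
    c = model.index(context)
    scores = model.output_vectors @ model.input_vectors[t]
    scores -= scores.max()
    exp = np.exp(scores)
    return float(exp[c] / exp.sum())


def _log_sigmoid(x: np.ndarray | float) -> np.ndarray | float:
    # log sigma(x) = -log(1 + exp(-x)), stable for both signs
    return -np.logaddexp(0.0, -np.asarray(x, dtype=np.float64))


def ns_loss(
    model: EmbeddingMatrix,
    target: str,
    context: str,
    negatives: list[str],
) -> float:
    """Negative-sampling loss for one pair:
    -log sigma(v'_ctx . v_tgt) - sum_neg log sigma(-v'_neg . v_tgt).
    """
    if not negatives:
        raise ValueError("negatives must be non-empty")
    v = model.input_vectors[model.index(target)]
    pos = model.output_vectors[model.index(context)] @ v
    negs = np.array(
        [model.output_vectors[model.index(n)] @ v for n in negatives]
    )
    return float(-_log_sigmoid(pos) - _log_sigmoid(-negs).sum())


def ns_gradients(
    v_target: np.ndarray,
    v_context: np.ndarray,
    v_negatives: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Analytic gradients of the negative-sampling loss.

    Returns (d_target, d_context, d_negatives) for input vector v_target,
    output vector v_context and the (k, dim) matrix of negative output
    vectors.
    """
    from scipy.special import expit

    pos_err = expit(v_context @ v_target) - 1.0  # sigma(s) - 1
    neg_err = expit(v_negatives @ v_target)  # sigma(s_neg)
    d_context = pos_err * v_target
    d_negatives = neg_err[:, None] * v_target[None, :]
    d_target = pos_err * v_context + neg_err @ v_negatives
    return d_target, d_context, d_negatives


def build_noise_distribution(
    counts: np.ndarray, exponent: float = 0.75
) -> np.ndarray:
    """Cumulative unigram^exponent distribution for negative sampling."""
    weights = np.asarray(counts, dtype=np.float64) ** exponent
    cdf = np.cumsum(weights)
    return cdf / cdf[-1]


def collect_pairs(
    corpus: Corpus, spec: ContextSpec, patient_weighting: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    """Materialize the full pair stream as arrays.

    Returns (pairs, weights): an (n, 2) int array and an (n,) float array
    of per-pair learning-rate multipliers (all ones unless
    patient_weighting, in which case each patient's pairs are scaled by
    1 / total_events).
    """
    pairs: list[tuple[int, int]] = []
    weights: list[float] = []
    for record in corpus.records:
        sub = Corpus(records=[record], vocabulary=corpus.vocabulary)
        record_pairs = list(iter_pairs(sub, spec))
        w = 1.0 / record.total_events if patient_weighting else 1.0
        pairs.extend(record_pairs)
        weights.extend([w] * len(record_pairs))
    if not pairs:
        return np.empty((0, 2), dtype=np.int64), np.empty(0)
    return np.array(pairs, dtype=np.int64), np.array(weights)


def train_sgns(
    corpus: Corpus, spec: ContextSpec, config: SGNSConfig
) -> EmbeddingMatrix:
    """Train skip-gram embeddings with negative sampling.

    SGD over the context-pair stream; learning rate decays linearly to
    a tenth of its initial value over all updates.  Deterministic given
    the config seed.  Mean per-epoch losses are stored on the returned
    model as ``epoch_losses``.
    """
    from scipy.special import expit

    vocab = corpus.vocabulary
    if len(vocab) == 0:
        raise TrainingError("vocabulary is empty; nothing to train")
    pairs, weights = collect_pairs(
        corpus, spec, patient_weighting=config.patient_weighting
    )
    if len(pairs) == 0:
        raise TrainingError(
            "context pair stream is empty under the chosen window "
            "(e.g. all patients may have single-event visits at N=0)"
        )

    rng = np.random.default_rng(config.seed)
    V, dim = len(vocab), config.dim
    w_in = (rng.random((V, dim)) - 0.5) / dim
    w_out = np.zeros((V, dim))
    counts = np.array([vocab.counts[t] for t in vocab.tokens], dtype=np.float64)
    noise_cdf = build_noise_distribution(counts, config.noise_exponent)
    keep_prob = _subsample_keep_probs(counts, config.subsample)

    k = config.negatives
    lr0 = config.learning_rate
    lr_floor = lr0 / 10.0
    total = config.epochs * len(pairs)
    model = EmbeddingMatrix(list(vocab.tokens), w_in, w_out)
    step = 0
    for _ in range(config.epochs):
        order = rng.permutation(len(pairs))
        epoch_loss = 0.0
        n_seen = 0
        for idx in order:
            t, c = pairs[idx]
            if keep_prob is not None and (
                rng.random() > keep_prob[t] or rng.random() > keep_prob[c]
            ):
                step += 1
                continue
            lr = lr0 + (lr_floor - lr0) * (step / total)
            lr *= weights[idx]
            negs = np.searchsorted(noise_cdf, rng.random(k))
            rows = np.concatenate(([c], negs))
            v = w_in[t]
            scores = w_out[rows] @ v
            sig = expit(scores)
            epoch_loss += -_log_sigmoid(scores[0]) - _log_sigmoid(
                -scores[1:]
            ).sum()
            n_seen += 1
            err = sig.copy()
            err[0] -= 1.0  # positive label
            grad_v = err @ w_out[rows]
            np.add.at(w_out, rows, (-lr * err)[:, None] * v[None, :])
            w_in[t] = v - lr * grad_v
            step += 1
        model.epoch_losses.append(epoch_loss / max(n_seen, 1))
    if not np.all(np.isfinite(w_in)) or not np.all(np.isfinite(w_out)):
        raise TrainingError("training diverged: non-finite vectors")
    return model


def _subsample_keep_probs(
    counts: np.ndarray, threshold: float
) -> np.ndarray | None:
    if threshold <= 0:
        return None
    freq = counts / counts.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        keep = np.sqrt(threshold / freq) + threshold / freq
    return np.minimum(keep, 1.0)
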