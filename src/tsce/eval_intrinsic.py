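"""Intrinsic evaluation of concept embeddings.

Three metrics over a concept-to-group mapping (ICD prefix built in,
arbitrary mappings via CSV):

* in-cluster distance — mean (1 - cosine) over all within-group pairs,
  averaged over groups (cohesion; smaller is better);
* out-cluster distance — mean (1 - cosine) over all cross-group pairs,
  averaged over group pairs (decoupling; larger is better);
* MCSM — for each grouped concept, a DCG-style discounted count of
  same-group concepts among its k nearest neighbors (larger is better).

Plus plain KNN queries against the full embedding vocabulary.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .sgns import EmbeddingMatrix

__all__ = [
    "Grouping",
    "MetricReport",
    "icd_prefix_group",
    "icd_prefix_grouping",
    "cosine",
    "in_cluster_distance",
    "out_cluster_distance",
    "mcsm",
    "knn_query",
    "evaluate",
]


def icd_prefix_group(code: str) -> str:
    """The ICD code prefix: everything before the first '.', or the
    whole code if there is no dot ("493.22" -> "493", "V10" -> "V10")."""
    if not code:
        raise ValueError("code must be non-empty")
    return code.split(".", 1)[0]


@dataclass
class Grouping:
    """Concept token -> group label mapping used by all metrics."""

    mapping: dict[str, str]
    name: str = "grouping"

    @classmethod
    def from_csv(cls, path: str | Path, name: str | None = None) -> "Grouping":
        """Load a two-column token,group CSV (header required)."""
        mapping: dict[str, str] = {}
        with open(path, "r", encoding="utf-8", newline="") as handle:
            reader = csv.reader(handle)
            header = next(reader, None)
            if header is None or len(header) < 2:
                raise ValueError("grouping CSV needs a token,group header")
            for row in reader:
                if len(row) < 2:
                    continue
                mapping[row[0]] = row[1]
        return cls(mapping=mapping, name=name or Path(path).stem)

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8", newline="") as handle:
            writer = csv.writer(handle)
            writer.writerow(["token", "group"])
            for token in sorted(self.mapping):
                writer.writerow([token, self.mapping[token]])

    def restrict(self, tokens) -> "Grouping":
        """Keep only tokens present in the given collection."""
        available = set(tokens)
        return Grouping(
            mapping={t: g for t, g in self.mapping.items() if t in available},
            name=self.name,
        )

    def groups(self) -> dict[str, list[str]]:
        by_group: dict[str, list[str]] = {}
        for token in sorted(self.mapping):
            by_group.setdefault(self.mapping[token], []).append(token)
        return by_group


def icd_prefix_grouping(
    tokens, code_types: tuple[str, ...] = ("D",)
) -> Grouping:
    """Group tokens of the given code types by their ICD prefix.

    Tokens render as "<type>_<code>"; the group label is the prefix of
    the code part.  Default restricts to diagnoses.
    """
    mapping = {}
    for token in tokens:
        if "_" not in token:
            continue
        code_type, code = token.split("_", 1)
        if code_type in code_types and code:
            mapping[token] = icd_prefix_group(code)
    return Grouping(mapping=mapping, name="icd-prefix")


def cosine(u: np.ndarray, w: np.ndarray) -> float:
    """Cosine similarity; 0 (distance 1) if either vector is zero."""
    u = np.asarray(u, dtype=np.float64)
    w = np.asarray(w, dtype=np.float64)
    if u.shape != w.shape:
        raise ValueError(f"dimension mismatch: {u.shape} vs {w.shape}")
    nu, nw = np.linalg.norm(u), np.linalg.norm(w)
    if nu == 0.0 or nw == 0.0:
        warnings.warn("zero-norm vector in cosine; returning 0", stacklevel=2)
        return 0.0
    return float(u @ w / (nu * nw))


def _normalized_rows(emb: EmbeddingMatrix, tokens: list[str]) -> np.ndarray:
    X = np.stack([emb.vector(t) for t in tokens])
    norms = np.linalg.norm(X, axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        X = np.where(norms > 0, X / norms, 0.0)
    return X


def in_cluster_distance(
    emb: EmbeddingMatrix, grouping: Grouping, weighting: str = "group"
) -> float:
    """Cohesion: per-group mean of (1 - cosine) over member pairs,
    averaged over groups (``weighting="group"``, default) or over
    concepts (``weighting="concept"``: group means weighted by size)."""
    grouping = grouping.restrict(emb.vocabulary)
    eligible = {g: ts for g, ts in grouping.groups().items() if len(ts) >= 2}
    if not eligible:
        raise ValueError("no group with >= 2 embedded members")
    means, sizes = [], []
    for _, tokens in sorted(eligible.items()):
        X = _normalized_rows(emb, tokens)
        sims = X @ X.T
        iu = np.triu_indices(len(tokens), k=1)
        means.append(float(np.mean(1.0 - sims[iu])))
        sizes.append(len(tokens))
    if weighting == "concept":
        return float(np.average(means, weights=sizes))
    return float(np.mean(means))


def out_cluster_distance(
    emb: EmbeddingMatrix, grouping: Grouping, weighting: str = "group"
) -> float:
    """Decoupling: per-group-pair mean of (1 - cosine) over cross pairs
    (normalized by |Ni|*|Nj|), averaged over group pairs."""
    grouping = grouping.restrict(emb.vocabulary)
    groups = sorted(grouping.groups().items())
    if len(groups) < 2:
        raise ValueError("need >= 2 groups for out-cluster distance")
    mats = {g: _normalized_rows(emb, ts) for g, ts in groups}
    means, weights_ = [], []
    for a in range(len(groups)):
        ga, ta = groups[a]
        for b in range(a + 1, len(groups)):
            gb, tb = groups[b]
            cross = mats[ga] @ mats[gb].T
            means.append(float(np.mean(1.0 - cross)))
            weights_.append(len(ta) * len(tb))
    if weighting == "concept":
        return float(np.average(means, weights=weights_))
    return float(np.mean(means))


def mcsm(emb: EmbeddingMatrix, grouping: Grouping, k: int = 40) -> float:
    """Discounted same-group count among each concept's k nearest
    neighbors, averaged over the grouped evaluation set.

    Neighbors are drawn from the grouped set itself, ranked by cosine
    descending with ties broken by token string ascending.  The default
    neighbor count is 40.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    grouping = grouping.restrict(emb.vocabulary)
    tokens = sorted(grouping.mapping)
    if len(tokens) < 2:
        raise ValueError("need >= 2 grouped tokens for MCSM")
    if len(tokens) < k + 1:
        warnings.warn(
            f"evaluation set has {len(tokens)} tokens < k+1={k + 1}; "
            "neighbor lists will be truncated",
            stacklevel=2,
        )
    labels = np.array([grouping.mapping[t] for t in tokens])
    X = _normalized_rows(emb, tokens)
    sims = X @ X.T
    discounts = 1.0 / np.log2(np.arange(1, k + 1) + 1)
    # ties broken by token string ascending: tokens are pre-sorted, so a
    # stable sort on -similarity preserves the string order among ties
    total = 0.0
    for i in range(len(tokens)):
        sim_row = sims[i].copy()
        sim_row[i] = -np.inf  # never own neighbor
        order = np.argsort(-sim_row, kind="stable")[: min(k, len(tokens) - 1)]
        hits = (labels[order] == labels[i]).astype(float)
        total += float(hits @ discounts[: len(order)])
    return total / len(tokens)


def knn_query(
    emb: EmbeddingMatrix, token: str, k: int = 5
) -> list[tuple[str, float]]:
    """Top-k most cosine-similar vocabulary tokens to the query token,
    excluding the query itself; ties broken by token string ascending."""
    qi = emb.index(token)
    tokens = emb.vocabulary
    X = _normalized_rows(emb, tokens)
    sims = X @ X[qi]
    candidates = [
        (tokens[i], float(sims[i])) for i in range(len(tokens)) if i != qi
    ]
    candidates.sort(key=lambda ts: (-ts[1], ts[0]))
    return candidates[: min(k, len(candidates))]


@dataclass
class MetricReport:
    """One evaluation row: embedding x grouping -> metric values."""

    embedding: str
    grouping: str
    d_in: float
    d_out: float
    mcsm: float
    k: int
    n_concepts: int = 0

    def to_json(self) -> str:
        return json.dumps(
            {
                "embedding": self.embedding,
                "grouping": self.grouping,
                "d_in": self.d_in,
                "d_out": self.d_out,
                "mcsm": self.mcsm,
                "k": self.k,
                "n_concepts": self.n_concepts,
            },
            indent=2,
            sort_keys=True,
        )


def evaluate(
    emb: EmbeddingMatrix,
    grouping: Grouping,
    k: int = 40,
    embedding_name: str = "embedding",
) -> MetricReport:
    """Compute all three metrics on the embedded, grouped concepts."""
    restricted = grouping.restrict(emb.vocabulary)
    if len(restricted.mapping) < 2:
        raise ValueError(
            "fewer than 2 grouped tokens overlap the embedding vocabulary"
        )
    return MetricReport(
        embedding=embedding_name,
        grouping=grouping.name,
        d_in=in_cluster_distance(emb, restricted),
        d_out=out_cluster_distance(emb, restricted),
        mcsm=mcsm(emb, restricted, k=k),
        k=k,
        n_concepts=len(restricted.mapping),
    )
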