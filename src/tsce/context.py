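"""Context-selection regimes shared by all embedding learners.

Three regimes are supported:

* ``baseline`` — a fixed token window over the linearized event sequence
  (visits in chronological order, events within a visit in seeded-random
  order), the standard skip-gram context.
* ``time`` with half-window ``N = 0`` — visit-level: the context of an
  event is exactly the other distinct events of the same visit.
* ``time`` with ``N > 0`` — calendar window: every event in every visit
  within N days before or after the target's visit (boundary inclusive).

For count-based (PPMI) training, :func:`segment_visits` partitions a
record's visits into non-overlapping (tumbling) time segments.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Iterator

import numpy as np

from .records import Corpus, PatientRecord, Vocabulary

__all__ = [
    "ContextSpec",
    "time_context_pairs",
    "baseline_pairs",
    "linearize",
    "segment_visits",
    "iter_pairs",
]


@dataclass(frozen=True)
class ContextSpec:
    """Which context regime is in force.

    mode="baseline" uses ``token_window`` (default 5 positions each side);
    mode="time" uses ``half_window_days`` (0 = visit-level).  ``seed``
    drives the intra-visit shuffle of the baseline linearization.
    """

    mode: str
    half_window_days: int = 0
    token_window: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("baseline", "time"):
            raise ValueError(f"mode must be 'baseline' or 'time', got {self.mode!r}")
        if self.half_window_days < 0:
            raise ValueError("half_window_days must be >= 0")
        if self.token_window < 1:
            raise ValueError("token_window must be >= 1")

    @classmethod
    def parse(cls, window: str, seed: int = 0) -> "ContextSpec":
        """Parse a CLI-style window selector.

        Accepted forms: ``baseline``, ``visit``, ``days:<span>`` where
        <span> is the total window span in days (halved, so ``days:30``
        means 15 days before or after the current visit).
        """
        if window == "baseline":
            return cls(mode="baseline", seed=seed)
        if window == "visit":
            return cls(mode="time", half_window_days=0, seed=seed)
        if window.startswith("days:"):
            span = int(window[len("days:"):])
            if span <= 0 or span % 2 != 0:
                raise ValueError(
                    f"window span must be a positive even day count, got {span}"
                )
            return cls(mode="time", half_window_days=span // 2, seed=seed)
        raise ValueError(f"unrecognized window selector {window!r}")

    def label(self) -> str:
        if self.mode == "baseline":
            return "baseline"
        if self.half_window_days == 0:
            return "T-visit"
        return f"T-{2 * self.half_window_days}days"


def time_context_pairs(
    record: PatientRecord,
    n_days: int,
    vocab: Vocabulary,
    yield_gaps: bool = False,
) -> Iterator[tuple]:
    """Emit (target, context) index pairs under the calendar-day window.

    For each event occurrence in visit t, pairs it with every event
    occurrence in every visit whose date is within ``n_days`` of visit
    t's date (inclusive; the current visit itself included), excluding
    only the target occurrence itself.  Tokens absent from ``vocab``
    (min-count filtered) are skipped.

    With ``yield_gaps=True`` yields (target, context, day_gap) triples.
    """
    if n_days < 0:
        raise ValueError("n_days must be >= 0")
    visits = record.visits
    dates = [v.date for v in visits]
    indexed = [
        [(vocab[t], t) for t in v.tokens if t in vocab] for v in visits
    ]
    for a, visit_tokens in enumerate(indexed):
        # candidate context visits: contiguous date range around visit a
        ctx_visits = [
            b
            for b in range(len(visits))
            if abs((dates[b] - dates[a]).days) <= n_days
        ]
        for target_idx, target_token in visit_tokens:
            for b in ctx_visits:
                gap = abs((dates[b] - dates[a]).days)
                for ctx_idx, ctx_token in indexed[b]:
                    if b == a and ctx_token == target_token:
                        continue  # an occurrence never pairs with itself
                    if yield_gaps:
                        yield (target_idx, ctx_idx, gap)
                    else:
                        yield (target_idx, ctx_idx)


def linearize(
    record: PatientRecord, seed: int = 0
) -> list[tuple[int, int]]:
    """Flatten a record into [(visit_position, token_string)] order used
    by the baseline window: visits chronological, events within a visit
    shuffled deterministically from (seed, patient_id).

    Returns a list of (visit_position, token) tuples.
    """
    rng = np.random.default_rng(
        [seed & 0xFFFFFFFF, zlib.crc32(record.patient_id.encode("utf-8"))]
    )
    sequence: list[tuple[int, str]] = []
    for pos, visit in enumerate(record.visits):
        tokens = list(visit.tokens)
        rng.shuffle(tokens)
        sequence.extend((pos, t) for t in tokens)
    return sequence


def baseline_pairs(
    record: PatientRecord,
    window: int,
    seed: int,
    vocab: Vocabulary,
) -> Iterator[tuple[int, int]]:
    """Standard skip-gram pairs within +/- ``window`` positions of the
    seeded linearization.  Unknown tokens are dropped before windowing.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    sequence = [
        vocab[t] for _, t in linearize(record, seed=seed) if t in vocab
    ]
    n = len(sequence)
    for i, target in enumerate(sequence):
        lo = max(0, i - window)
        hi = min(n, i + window + 1)
        for j in range(lo, hi):
            if j == i:
                continue
            yield (target, sequence[j])


def segment_visits(
    record: PatientRecord, n_days: int
) -> list[list[str]]:
    """Partition visits into tumbling time segments of span ``2 * n_days``.

    ``n_days = 0`` gives one segment per visit.  Otherwise visits are
    scanned in order: a visit joins the open segment iff its date is
    within ``2 * n_days`` days (inclusive) of the segment's *first*
    visit's date, else it opens a new segment.  Each segment is the
    concatenation (multiplicity across visits preserved) of its visits'
    tokens.
    """
    if n_days < 0:
        raise ValueError("n_days must be >= 0")
    if n_days == 0:
        return [list(v.tokens) for v in record.visits]
    span = 2 * n_days
    segments: list[list[str]] = []
    anchor = None
    for visit in record.visits:
        if anchor is None or (visit.date - anchor).days > span:
            segments.append([])
            anchor = visit.date
        segments[-1].extend(visit.tokens)
    return segments


def iter_pairs(corpus: Corpus, spec: ContextSpec) -> Iterator[tuple[int, int]]:
    """Stream (target, context) vocabulary-index pairs for a whole corpus
    under the given regime, record by record in corpus order."""
    vocab = corpus.vocabulary
    for record in corpus.records:
        if spec.mode == "baseline":
            yield from baseline_pairs(record, spec.token_window, spec.seed, vocab)
        else:
            yield from time_context_pairs(record, spec.half_window_days, vocab)
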