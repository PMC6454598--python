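"""Data model for longitudinal patient event sequences.

Patients are stored as chronologically ordered visits, each carrying a
calendar date (day resolution) and a *set* of coded clinical events of
type D (diagnosis), M (medication) or P (procedure).  The token identity
used by every downstream module is the rendering ``"<type>_<code>"``
(e.g. ``"D_493.22"``), which keeps the three code namespaces disjoint.

On-disk format is JSON lines, one patient per line::

    {"patient_id": "p1",
     "visits": [{"visit_id": "v1", "datetime": "2003-05-14",
                 "events": [{"type": "D", "code": "493.22"}, ...]}, ...]}
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

__all__ = [
    "CODE_TYPES",
    "ClinicalEvent",
    "Visit",
    "PatientRecord",
    "Vocabulary",
    "Corpus",
    "ParseError",
    "SchemaError",
    "read_records",
    "write_records",
    "clean_records",
    "build_vocabulary",
]

CODE_TYPES = ("D", "M", "P")


class ParseError(ValueError):
    """A JSONL line could not be parsed as JSON."""


class SchemaError(ValueError):
    """A parsed line is missing a field or has an invalid value."""


@dataclass(frozen=True, order=True)
class ClinicalEvent:
    """A single coded event: diagnosis (D), medication (M) or procedure (P)."""

    code_type: str
    code: str

    def __post_init__(self) -> None:
        if self.code_type not in CODE_TYPES:
            raise SchemaError(
                f"code_type must be one of {CODE_TYPES}, got {self.code_type!r}"
            )
        if not self.code:
            raise SchemaError("event code must be non-empty")

    @property
    def token(self) -> str:
        """Render the event as its vocabulary token, e.g. ``"D_493.22"``."""
        return f"{self.code_type}_{self.code}"


@dataclass(frozen=True)
class Visit:
    """One encounter: a date and a deduplicated set of clinical events.

    Events are stored sorted by (code_type, code) so that equality and
    serialization are deterministic; consumers that need the random
    within-visit order the source systems exhibit (the baseline token
    window) shuffle with their own seed.
    """

    visit_id: str
    date: _dt.date
    events: tuple[ClinicalEvent, ...]

    def __post_init__(self) -> None:
        if not isinstance(self.date, _dt.date) or isinstance(self.date, _dt.datetime):
            raise SchemaError(f"visit date must be a datetime.date, got {self.date!r}")
        deduped = tuple(sorted(set(self.events)))
        object.__setattr__(self, "events", deduped)

    @property
    def tokens(self) -> tuple[str, ...]:
        return tuple(e.token for e in self.events)

    def __len__(self) -> int:
        return len(self.events)


@dataclass(frozen=True)
class PatientRecord:
    """A patient's visits, sorted ascending by date."""

    patient_id: str
    visits: tuple[Visit, ...]

    def __post_init__(self) -> None:
        if not self.visits:
            raise SchemaError(f"patient {self.patient_id!r} has no visits")
        ordered = tuple(sorted(self.visits, key=lambda v: v.date))
        object.__setattr__(self, "visits", ordered)

    @property
    def n_visits(self) -> int:
        return len(self.visits)

    @property
    def total_events(self) -> int:
        """Total distinct events summed over visits (the per-patient mass)."""
        return sum(len(v) for v in self.visits)

    def iter_tokens(self) -> Iterator[str]:
        for visit in self.visits:
            yield from visit.tokens


class Vocabulary:
    """Ordered token table: descending count, ties broken by token string."""

    def __init__(self, counts: dict[str, int], min_count: int = 1) -> None:
        if min_count < 1:
            raise ValueError(f"min_count must be >= 1, got {min_count}")
        kept = {t: c for t, c in counts.items() if c >= min_count}
        self.tokens: list[str] = sorted(kept, key=lambda t: (-kept[t], t))
        self.counts: dict[str, int] = {t: kept[t] for t in self.tokens}
        self._index: dict[str, int] = {t: i for i, t in enumerate(self.tokens)}

    def __len__(self) -> int:
        return len(self.tokens)

    def __contains__(self, token: str) -> bool:
        return token in self._index

    def __getitem__(self, token: str) -> int:
        return self._index[token]

    def __iter__(self) -> Iterator[str]:
        return iter(self.tokens)

    def get(self, token: str, default: int | None = None) -> int | None:
        return self._index.get(token, default)

    def token(self, index: int) -> str:
        return self.tokens[index]


@dataclass
class Corpus:
    """A collection of patient records plus the vocabulary built over them."""

    records: list[PatientRecord]
    vocabulary: Vocabulary = field(default=None)  # type: ignore[assignment]
    min_count: int = 1

    def __post_init__(self) -> None:
        if self.vocabulary is None:
            self.vocabulary = build_vocabulary(self.records, self.min_count)

    @property
    def n_patients(self) -> int:
        return len(self.records)

    @property
    def n_visits(self) -> int:
        return sum(r.n_visits for r in self.records)

    @property
    def n_events(self) -> int:
        return sum(r.total_events for r in self.records)


def build_vocabulary(
    records: Iterable[PatientRecord], min_count: int = 1
) -> Vocabulary:
    """Count visit-level token occurrences and build the ordered vocabulary.

    Each visit contributes at most one count per token (events are
    deduplicated within a visit); repeats across visits all count.
    """
    counts: dict[str, int] = {}
    for record in records:
        for token in record.iter_tokens():
            counts[token] = counts.get(token, 0) + 1
    return Vocabulary(counts, min_count=min_count)


def _parse_date(value: object, line_no: int) -> _dt.date:
    if not isinstance(value, str):
        raise SchemaError(f"line {line_no}: datetime must be a string, got {value!r}")
    try:
        return _dt.date.fromisoformat(value)
    except ValueError as exc:
        raise SchemaError(f"line {line_no}: unparseable datetime {value!r}") from exc


def _parse_record(obj: dict, line_no: int) -> PatientRecord:
    try:
        patient_id = obj["patient_id"]
        raw_visits = obj["visits"]
    except (KeyError, TypeError) as exc:
        raise SchemaError(f"line {line_no}: missing required field {exc}") from exc
    visits = []
    for raw in raw_visits:
        try:
            visit_id = raw["visit_id"]
            date = _parse_date(raw["datetime"], line_no)
            raw_events = raw["events"]
        except (KeyError, TypeError) as exc:
            raise SchemaError(f"line {line_no}: missing required field {exc}") from exc
        events = []
        for ev in raw_events:
            try:
                events.append(ClinicalEvent(code_type=ev["type"], code=ev["code"]))
            except (KeyError, TypeError) as exc:
                raise SchemaError(
                    f"line {line_no}: missing required field {exc}"
                ) from exc
        visits.append(Visit(visit_id=visit_id, date=date, events=tuple(events)))
    if not visits:
        raise SchemaError(f"line {line_no}: patient {patient_id!r} has no visits")
    return PatientRecord(patient_id=patient_id, visits=tuple(visits))


def read_records(path: str | Path, min_count: int = 1) -> Corpus:
    """Read a patient-records JSONL file into a Corpus.

    Visits are re-sorted by date, events deduplicated, and the vocabulary
    built with the given min_count.
    """
    records: list[PatientRecord] = []
    with open(path, "r", encoding="utf-8") as handle:
        for line_no, line in enumerate(handle, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise ParseError(f"line {line_no}: malformed JSON: {exc}") from exc
            records.append(_parse_record(obj, line_no))
    return Corpus(records=records, min_count=min_count)


def write_records(corpus: Corpus, path: str | Path) -> None:
    """Write a corpus as JSONL; inverse of read_records on cleaned corpora."""
    with open(path, "w", encoding="utf-8") as handle:
        for record in corpus.records:
            obj = {
                "patient_id": record.patient_id,
                "visits": [
                    {
                        "visit_id": v.visit_id,
                        "datetime": v.date.isoformat(),
                        "events": [
                            {"type": e.code_type, "code": e.code} for e in v.events
                        ],
                    }
                    for v in record.visits
                ],
            }
            handle.write(json.dumps(obj, separators=(",", ":")) + "\n")


def clean_records(
    corpus: Corpus, min_date: _dt.date, max_date: _dt.date
) -> Corpus:
    """Drop every patient having any visit dated outside [min_date, max_date].

    Surviving records are unchanged; the vocabulary is rebuilt.
    """
    if not min_date < max_date:
        raise ValueError(f"min_date {min_date} must precede max_date {max_date}")
    kept = [
        r
        for r in corpus.records
        if all(min_date <= v.date <= max_date for v in r.visits)
    ]
    return Corpus(records=kept, min_count=corpus.min_count)
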