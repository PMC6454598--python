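"""Seeded generator of longitudinal EHR-like corpora with known structure.

Each patient's timeline is a sequence of episodes.  An episode draws one
latent concept group; its visits sample events from that group's codes
(with some probability of a background medication code instead).  Visits
within an episode are a few days apart; consecutive episodes are
separated by long gaps, so calendar-window contexts provably never span
episodes.  The ground-truth token-to-group mapping is returned alongside
the corpus, which makes every learner and metric testable without any
external data.

Visit ids encode their provenance as "<patient>-e<episode>-v<visit>".
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field

import numpy as np

from .eval_intrinsic import Grouping
from .records import ClinicalEvent, Corpus, PatientRecord, Visit

__all__ = ["SynthConfig", "generate_corpus", "corpus_stats", "episode_of"]

IntRange = tuple[int, int]  # inclusive


@dataclass
class SynthConfig:
    """Generator settings; all integer distributions are inclusive
    uniform ranges.  The invariant ``intra gap max < inter gap min``
    guarantees the episode separation the time-window tests rely on."""

    n_patients: int = 2000
    n_groups: int = 10
    codes_per_group: int = 20
    background_codes: int = 20
    episodes_per_patient: IntRange = (1, 3)
    visits_per_episode: IntRange = (2, 4)
    intra_episode_gap_days: IntRange = (1, 10)
    inter_episode_gap_days: IntRange = (60, 400)
    events_per_visit: IntRange = (3, 5)
    noise_rate: float = 0.1
    shared_prefix: bool = True
    seed: int = 0
    start_date: _dt.date = field(default_factory=lambda: _dt.date(2000, 1, 1))
    start_jitter_days: int = 3650

    def __post_init__(self) -> None:
        for name in (
            "episodes_per_patient",
            "visits_per_episode",
            "intra_episode_gap_days",
            "inter_episode_gap_days",
            "events_per_visit",
        ):
            lo, hi = getattr(self, name)
            if not (1 <= lo <= hi):
                raise ValueError(f"{name} must be an increasing range >= 1")
        if not 0.0 <= self.noise_rate < 1.0:
            raise ValueError("noise_rate must lie in [0, 1)")
        if self.intra_episode_gap_days[1] >= self.inter_episode_gap_days[0]:
            raise ValueError(
                "intra-episode gap max must be below inter-episode gap min "
                "(episode separation invariant)"
            )
        if self.n_patients < 0 or self.n_groups < 1 or self.codes_per_group < 1:
            raise ValueError("patient/group/code counts out of range")

    def group_codes(self) -> list[list[str]]:
        """Diagnosis codes per group; with shared_prefix, group g's codes
        all share the ICD prefix str(401 + g)."""
        codes = []
        for g in range(self.n_groups):
            if self.shared_prefix:
                prefix = str(401 + g)
                codes.append(
                    [f"{prefix}.{j + 1:02d}" for j in range(self.codes_per_group)]
                )
            else:
                codes.append(
                    [f"{j + 1:02d}x{g:02d}" for j in range(self.codes_per_group)]
                )
        return codes

    def group_label(self, g: int) -> str:
        return str(401 + g) if self.shared_prefix else f"g{g}"


def generate_corpus(config: SynthConfig) -> tuple[Corpus, Grouping]:
    """Generate a corpus and its ground-truth grouping, deterministically
    from the config seed.  Background codes are left unmapped."""
    rng = np.random.default_rng(config.seed)
    codes = config.group_codes()
    background = [f"drug{i:03d}" for i in range(config.background_codes)]

    def draw(rg: IntRange) -> int:
        return int(rng.integers(rg[0], rg[1] + 1))

    records: list[PatientRecord] = []
    for p in range(config.n_patients):
        pid = f"p{p:05d}"
        day = config.start_date + _dt.timedelta(
            days=int(rng.integers(0, config.start_jitter_days + 1))
        )
        visits: list[Visit] = []
        for e in range(draw(config.episodes_per_patient)):
            if e > 0:
                day += _dt.timedelta(days=draw(config.inter_episode_gap_days))
            group = int(rng.integers(config.n_groups))
            for v in range(draw(config.visits_per_episode)):
                if v > 0:
                    day += _dt.timedelta(days=draw(config.intra_episode_gap_days))
                events = []
                for _ in range(draw(config.events_per_visit)):
                    if (
                        config.background_codes > 0
                        and rng.random() < config.noise_rate
                    ):
                        code = background[int(rng.integers(len(background)))]
                        events.append(ClinicalEvent("M", code))
                    else:
                        code = codes[group][
                            int(rng.integers(config.codes_per_group))
                        ]
                        events.append(ClinicalEvent("D", code))
                visits.append(
                    Visit(
                        visit_id=f"{pid}-e{e}-v{v}",
                        date=day,
                        events=tuple(events),
                    )
                )
        records.append(PatientRecord(patient_id=pid, visits=tuple(visits)))

    mapping = {
        f"D_{code}": config.group_label(g)
        for g, group_codes in enumerate(codes)
        for code in group_codes
    }
    return Corpus(records=records), Grouping(mapping=mapping, name="truth")


def episode_of(visit_id: str) -> int:
    """Recover the episode index encoded in a generated visit id."""
    return int(visit_id.rsplit("-", 2)[1][1:])


def corpus_stats(corpus: Corpus) -> dict:
    """Exact corpus summary: counts plus a consecutive-visit gap histogram."""
    gaps: dict[int, int] = {}
    for record in corpus.records:
        for a, b in zip(record.visits, record.visits[1:]):
            gap = (b.date - a.date).days
            gaps[gap] = gaps.get(gap, 0) + 1
    return {
        "patients": corpus.n_patients,
        "visits": corpus.n_visits,
        "events": corpus.n_events,
        "vocabulary_size": len(corpus.vocabulary),
        "gap_histogram": dict(sorted(gaps.items())),
    }
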