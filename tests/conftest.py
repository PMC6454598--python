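import datetime as dt

import numpy as np
import pytest

from tsce.context import ContextSpec
from tsce.records import ClinicalEvent, Corpus, PatientRecord, Visit
from tsce.sgns import SGNSConfig, train_sgns
from tsce.synthetic import SynthConfig, generate_corpus


def make_record(patient_id, visit_days, start=dt.date(2001, 1, 1)):
    """Build a record from {day_offset: [token, ...]} with D_ codes."""
    visits = []
    for i, (day, tokens) in enumerate(sorted(visit_days.items())):
        events = tuple(
            ClinicalEvent(t.split("_", 1)[0], t.split("_", 1)[1]) for t in tokens
        )
        visits.append(
            Visit(
                visit_id=f"{patient_id}-v{i}",
                date=start + dt.timedelta(days=day),
                events=events,
            )
        )
    return PatientRecord(patient_id=patient_id, visits=tuple(visits))


@pytest.fixture
def episodic_record():
    """Visits at days 0, 10 and 400 — two close, one far."""
    return make_record(
        "p1", {0: ["D_A", "D_B"], 10: ["D_C"], 400: ["D_D"]}
    )


@pytest.fixture(scope="session")
def recovery_corpus():
    """Small seeded corpus with clear group structure for recovery tests."""
    config = SynthConfig(
        n_patients=200, n_groups=5, codes_per_group=10, seed=11
    )
    return generate_corpus(config)


@pytest.fixture(scope="session")
def sg_visit_model(recovery_corpus):
    corpus, _ = recovery_corpus
    spec = ContextSpec(mode="time", half_window_days=0)
    return train_sgns(corpus, spec, SGNSConfig(dim=32, epochs=5, seed=11))


def random_records(n_records, rng, max_visits=5, max_events=4, n_codes=12):
    """Random small records for oracle-equivalence sweeps."""
    records = []
    for i in range(n_records):
        n_visits = int(rng.integers(1, max_visits + 1))
        days = sorted(
            int(d) for d in rng.choice(600, size=n_visits, replace=False)
        )
        visit_days = {}
        for day in days:
            k = int(rng.integers(1, max_events + 1))
            tokens = [
                f"D_c{int(c)}" for c in rng.choice(n_codes, size=k, replace=False)
            ]
            visit_days[day] = tokens
        records.append(make_record(f"r{i}", visit_days))
    return records


def corpus_of(records):
    return Corpus(records=list(records))
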