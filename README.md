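# tsce — time-sensitive clinical concept embeddings

Learn dense vector representations of coded clinical concepts
(diagnoses D, medications M, procedures P) from longitudinal patient
records, selecting each concept's training context by **calendar time**
rather than token position. Three learners share the same context
machinery:

* **sg** — skip-gram with negative sampling (a full-softmax reference
  scorer is kept for testing);
* **ppmi** — co-occurrence counting over temporal segments, positive
  PMI transform, truncated SVD (rows of U are the embeddings);
* **ft** — subword model: a concept's target vector is the sum of the
  character n-gram vectors of its token string, so unseen codes that
  share a prefix with trained codes still get meaningful vectors.

Three context regimes: `baseline` (fixed ±5-token window over the
linearized sequence), `visit` (contexts are the other events of the
same visit), and `days:<span>` (events within span/2 days before or
after the current visit; `days:30` means ±15 days). The ppmi learner
supports only the time regimes.

Evaluation is intrinsic: in-cluster distance (cohesion, smaller is
better), out-cluster distance (decoupling, larger is better), and a
DCG-style same-group nearest-neighbor score (default k=40), over a
concept→group mapping — the built-in ICD-prefix grouping (the code part
before the dot) or any two-column `token,group` CSV.

A seeded synthetic corpus generator produces patients with episodic
visit timing (short gaps inside an episode, ≥60-day gaps between
episodes) and latent concept groups, with the ground-truth grouping
returned alongside — so the whole pipeline is testable offline.

## CLI

```sh
# generate a synthetic corpus + ground-truth grouping
tsce simulate --out records.jsonl --grouping grouping.csv \
    --n-patients 2000 --seed 7

# train: sg | ppmi | ft  x  baseline | visit | days:<span>
tsce train --records records.jsonl --method sg --window visit \
    --dim 200 --seed 7 --out sg-visit.txt

# evaluate (word2vec text format in, JSON report out)
tsce evaluate --embeddings sg-visit.txt --grouping grouping.csv \
    --k 40 --out report.json

# nearest neighbors of a concept
tsce query --embeddings sg-visit.txt --token D_401.03 --k 5
```

Records are JSONL, one patient per line:

```json
{"patient_id": "p1", "visits": [{"visit_id": "v1",
  "datetime": "2003-05-14",
  "events": [{"type": "D", "code": "493.22"}]}]}
```

Embeddings are written in word2vec text format (`V dim` header, then
one `token v1 ... vdim` line each).

## Library use

```python
from tsce import (ContextSpec, SGNSConfig, SynthConfig,
                  generate_corpus, train_sgns, evaluate)

corpus, grouping = generate_corpus(SynthConfig(n_patients=500, seed=0))
spec = ContextSpec(mode="time", half_window_days=0)   # visit-level
emb = train_sgns(corpus, spec, SGNSConfig(dim=100, epochs=5, seed=0))
report = evaluate(emb, grouping, k=10)
print(report.to_json())
```
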