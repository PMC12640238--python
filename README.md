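# temporel

Few-shot LLM extraction of temporal relations between **phenotypes** and
**time expressions** in French clinical reports, packaged as a
backend-agnostic library and CLI. Because real pediatric corpora of this
kind are private, the package ships a seeded synthetic-corpus generator with
a latent patient timeline, so the whole pipeline is testable end to end
offline.

## What it does

* **Schema** — 7 temporal relation types (`BEGINS-AT`, `ENDS-AT`,
  `CONTAINS`, `OVERLAP`, `BEFORE-OVERLAP`, `BEFORE`, `SIMULTANEOUS`) plus a
  `NONE` outcome, between 10 temporal entity types (DOB, DOR, DOV, DOPV,
  DOFV, DOTHER, Age, Duration, Frequency, Time) and `Phenotype` mentions.
* **`temporel.corpus_io`** — BRAT standoff (.txt/.ann) reader/writer with
  round-trip identity.
* **`temporel.intervals`** — deterministic relation labeling over integer
  day spans; the gold-label oracle of the generator.
* **`temporel.synth`** — seeded French-flavored report generator with
  latent timelines, steerable relation-type mix (defaults to the published
  count distribution, available as `table1_fixture()`).
* **`temporel.context`** — candidate (temporal entity, phenotype) pair
  enumeration and extraction of entity-marked snippets (up to 1000
  whitespace tokens around each entity, XML-style markers).
* **`temporel.prompts`** — three prompt regimes from a curated example
  bank: multi-class (2 examples × 7 types = 14), binary (3 positive + 3
  NONE per relation), zero-shot (definition only).
* **`temporel.backend`** — chat-completions HTTP client for locally served
  models (stdlib only, no data leaves the configured host), deterministic
  oracle/noisy/scripted mocks, and total free-text → label answer parsing.
* **`temporel.classify`** — regime orchestration, including rarity-based
  conflict resolution for the binary decomposition (smallest training
  count wins, deterministic tie-break).
* **`temporel.evaluate`** — per-relation P/R/F1, macro/micro/weighted
  aggregates, confusion tally, and pairwise average-F1 inter-annotator
  agreement.

## CLI

```bash
# 1. generate a seeded synthetic corpus (BRAT .txt/.ann + timeline sidecars)
temporel generate --n-docs 50 --seed 7 --out corpus/

# 2. classify all candidate pairs (mock oracle by default; use --backend http
#    with --base-url/--model for a locally served chat-completions endpoint)
temporel extract --corpus corpus/ --regime binary --out run/

# 3. score predictions against the gold annotations
temporel evaluate --corpus corpus/ --predictions run/predictions.jsonl --out run/

# inspect a rendered prompt
temporel prompt-dump --corpus corpus/ --regime binary --relation BEGINS-AT
```

Every command writes a `manifest.json` (config, seed, schema version,
prompt-template hashes) sufficient to reproduce the run. Raw
prompt/response logging is opt-in, since prompts may embed clinical text.

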