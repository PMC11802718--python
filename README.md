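# sudspan

Zero-shot extraction of substance-use-disorder (SUD) diagnosis **severity
specifiers** from unstructured clinical notes.

Clinicians document DSM-5 SUD diagnoses — including severity ("mild",
"moderate", "severe") and remission status — as free text, in wildly
variable phrasings ("severe etoh use d/o", "mj ud", "meets criteria for
substance use disorder: cocaine [] mild (2-3); [] moderate (4-5); [x]
severe (6 or more)"). Structured ICD-10 codes do not carry this
granularity, so automated risk assessment needs text phenotyping. This
package implements a complete zero-shot workflow for that task across 11
SUD diagnostic categories (alcohol; opioids; cannabis; sedatives,
hypnotics/anxiolytics; cocaine; amphetamines; caffeine; hallucinogens;
nicotine; inhalants; other psychoactive substances), aimed at clinical-NLP
researchers who want a testable, backend-agnostic harness for this family
of methods.

## The workflow

1. **Prompting** — one prompt per category asks an instruction-tuned
   generation model to extract the reference to the category's use-disorder
   diagnosis with surrounding context, or answer the literal escape word
   `"unanswerable"`. Decoding is greedy (temperature 1, ≤100 new tokens),
   so runs are deterministic.
2. **Sliding-window chunking** — notes exceeding the model's maximum input
   length *L* (512 by default) are split into windows of
   *w = L − |prompt|* tokens whose starts advance by a document stride
   (128); the prompt is prepended to each chunk, giving one candidate
   answer per chunk.
3. **Post-processing** — candidates are reduced to one answer per
   (note, category) by a four-stage cascade: (i) must contain a category
   substance term; (ii) must contain a use-disorder phrase *after* the
   substance name; (iii) the candidate's lexicon-bearing content must be
   grounded in the note via maximal common substrings of ≥5 characters
   (5 = the length of the shortest real diagnosis string, "mj ud");
   (iv) if several distinct candidates survive, the one whose embedding has
   minimum Euclidean distance to the category's *proxy ground truth*
   (e.g. "alcohol use disorder/dependence") wins.
4. **Evaluation** — per-note **strict** F1 (binary exact match between
   normalised spans; an empty answer on a no-information note scores 1) and
   **relaxed** token-overlap P/R/F1
   (P = TP/(TP+FP), R = TP/(TP+FN), F1 their harmonic mean over token
   multisets), macro-averaged per category over positive, negative and all
   notes, plus a five-way error-scenario breakdown and a Pearson analysis
   of note length versus candidate count.
5. **Regex baseline** — rule patterns assembled from the same lexicons
   ((severity)? substance … disorder (severity/remission)?), a training-free
   benchmark whose answers are always verbatim note substrings but which
   cannot exclude "rule out" mentions.

Generation is behind a one-method backend contract. Three mock backends
(oracle, noisy, hallucinating) make every downstream stage testable without
a GPU; an adapter for Hugging Face seq2seq models is provided as an
optional extra. Real clinical corpora of this kind are not shareable, so
the package ships a seeded synthetic-note generator reproducing the
documented corpus structure (prevalences 3–33%, log-normal lengths,
comorbidity, checkbox/abbreviation/remission span styles, problem-list and
rule-out distractors) with verbatim gold spans.

## Worked example

```python
from sudspan import (CorpusSpec, PipelineConfig, generate_corpus, run_pipeline)

notes, gold = generate_corpus(CorpusSpec(n_notes=200, seed=7))
answers, report = run_pipeline(PipelineConfig(backend="noisy"), notes, gold=gold)
print(report["scores"].table[["n_pos", "strict_f1_pos", "relaxed_recall_pos",
                              "strict_f1_combined"]].head(3))
```

prints

```
          n_pos  strict_f1_pos  relaxed_recall_pos  strict_f1_combined
category
alcohol      66          0.000               1.000               0.670
opioid       30          0.000               1.000               0.850
cannabis     26          0.000               1.000               0.870
```

The noisy backend pads every true span with extra words, so relaxed recall
stays perfect (the gold span is always contained in the answer) while the
strict exact-match score collapses on positive notes — the characteristic
error profile of generative extraction, where the model tends to add
context rather than omit it. With `backend="oracle"` every strict macro F1
is 1.000, which is the designed upper bound: gold spans always survive the
filter cascade. The `examples/` directory walks each capability
(`01_generate_corpus.py`, `02_extract_and_postprocess.py`,
`03_regex_baseline.py`, `04_full_pipeline_evaluation.py`); a thin CLI
(`sudspan synth|extract|regex-extract|evaluate|report|run-all`) wraps the
same functions for shell use.

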