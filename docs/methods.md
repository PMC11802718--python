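# Methods

This note documents the modelling choices behind `sudspan`: what each stage
assumes, which parameters matter, what the synthetic corpus does and does
not emulate, and where the design was genuinely open.

## Task and scope

The task is span extraction: for each of 11 DSM-5 SUD categories and each
clinical note, return the single continuous string in which the clinician
documents that category's use-disorder diagnosis together with its severity
specifier (severity level and/or remission status), or an "unanswerable"
sentinel when the note carries no such diagnosis. Absence of an explicit
severity term is clinically equivalent to "unspecified" severity, so spans
without severity words are still valid targets. Negated and
historical-only mentions are excluded at the annotation level, not
algorithmically: the package performs no assertion/negation detection.

## Lexicons

Each category carries four term sets: substance names (with clinical
abbreviations: "etoh", "mj", "thc"), use-disorder phrases ("use disorder",
"dependence", "use d/o", "use do", "ud"), severity/remission specifiers,
and a proxy ground-truth phrase. Matching is plain substring containment
on lowercased, whitespace-collapsed text — word boundaries are deliberately
not enforced because abbreviations like "use d/o" and "use do" break them.
The shipped default config is reconstructed from attested example strings
plus DSM-5 category names and is user-replaceable.

Two deliberate term-set choices:

* **"substance use disorder" is shared across all categories.**
  Checkbox-style diagnoses ("meets criteria for substance use disorder:
  cocaine [] mild …") name the substance only *after* the generic
  use-disorder phrase; without the shared term, the ordering filter (ii)
  would reject every checkbox span. The cost is a small loss of category
  specificity in filter (i), accepted and documented here. The loader
  enforces cross-category disjointness of all other substance terms via an
  explicit allowlist.
* **Bare "stimulant" belongs to amphetamine.** Clinical notes sometimes
  record "stimulant use disorder" where the actual substance is cocaine;
  assigning the bare word to the amphetamine category reproduces that
  ambiguity rather than resolving it.

## Chunking

`stride` is the *advance* between consecutive window starts
(start += stride), following the sliding-window convention of
reading-comprehension systems; the alternative "stride = overlap" reading
is rejected but would be a one-line change. Defaults: maximum input 512
tokens, stride 128, window planned as 512 − |prompt| (462 for a 50-token
prompt). A final chunk shorter than the window is kept, not dropped.
Chunk boundaries are token-aligned and chunk text is produced by
detokenisation; character offsets are not guaranteed. Token counting uses
the generation backend's own tokenizer in real runs; a whitespace tokenizer
is the backend-free default used throughout the tests. Any span shorter
than window − stride + 1 tokens is guaranteed to appear intact in at least
one window.

## Backends

The generation contract is a single method, `generate(text, config) →
text`, deterministic under greedy decoding. The mock backends are
first-class: the oracle returns the gold span when it appears verbatim in
the chunk (an upper-bound extractor that makes the end-to-end strict-F1 =
1.0 test meaningful), the noisy mock pads oracle answers with fixed words
(recall 1, precision < 1 — the error profile generative models actually
exhibit), and the hallucinating mock injects wrong-category spans at a
seeded rate to exercise the grounding filter. The Hugging Face adapter
(optional extra) enforces greedy decoding regardless of model defaults.

## Post-processing

Filters (i) and (ii) are category containment and ordering checks; the
ordering ("a use-disorder phrase following the substance name") is
implemented as character-position ordering anchored at the *first*
substance occurrence — the simplest testable reading.

Filter (iii) is the one genuinely ambiguous stage. Read literally,
"filter if *any* common substring of length ≥5 fails (i)–(ii)" would
discard nearly everything, because most common substrings contain no
lexicon term. The implemented semantics is: the candidate must share at
least one maximal common substring of ≥5 characters with the note, **and**
the union of the candidate's shared material must itself pass (i)–(ii).
This keeps the filter a pure function of (candidate, note, lexicon) and
captures the intent — the lexicon-bearing part of the answer must be
grounded in the note. The threshold 5 comes from the shortest attested
diagnosis string ("mj ud") and is exposed as `min_len`. This is flagged as
a deviation-risk interpretation point.

Duplicate candidates from overlapping chunks are collapsed by exact string
match before counting survivors; otherwise every long note would trigger
proxy selection for its single diagnosis. Proxy selection uses minimum
Euclidean distance (equivalently, maximum negative-distance score) rather
than cosine similarity: Euclidean distance is sensitive to embedding
magnitude and therefore to answer length, which favours concise relevant
candidates over verbose multi-diagnosis ones; cosine remains available
behind the `metric` switch. Proxy phrases expand slash alternatives
("…disorder/dependence") and score each candidate by its best variant.
Ties break to the lowest chunk index.

The default embedder hashes character 3–5-grams into a 512-dimensional
count vector (scikit-learn `HashingVectorizer`, unnormalised so Euclidean
distance keeps its length sensitivity). It is a deterministic lexical
embedder, not a contextual encoder; any sentence encoder can be plugged in
through the one-method `EmbedderContract`. On the synthetic corpus the
proxy stage is rarely reached (the generator emits one span per positive
pair), so the embedder choice is not load-bearing for the shipped tests.

## Regex baseline

Patterns assemble (severity)? substance (filler)? disorder
(filler severity/remission)? (parenthetical)? with filler gaps bounded at
40 characters (enough for parentheticals like "(kratom)" without runaway
spans). Multiple hits reduce to leftmost-start-then-longest-end, one
evaluated answer per note. Every non-sentinel answer is asserted to be a
verbatim substring of the note. The baseline deliberately matches
"r/o …" (rule-out) mentions — rule patterns cannot encode assertion
status — and this limitation is pinned by a test.

## Evaluation

The token unit for relaxed scoring is the whitespace token after
lowercasing and punctuation isolation, with "/" kept intra-token ("d/o"
stays one token); model wordpieces would couple the metric to a backend.
Counting is multiset by default (repeated words in verbose generations
cost precision), with a set-mode switch. Strict matching normalises by
casefolding and whitespace collapse before exact comparison; the
unanswerable sentinel counts as the empty answer, so sentinel-vs-no-gold
scores 1. Literal character-identity strictness was rejected as fragile
to trailing whitespace. Macro averages are computed over notes within
each category, separately for positive notes, negative notes and combined
(the combined figure is the mean over all notes, not the mean of subgroup
means). Scenario labels classify relaxed (P, R) in order: both 1; only
R = 1; only P = 1; both 0; other. The candidate-count report counts
*surviving distinct* candidates per (note, category) — the quantity the
proxy stage actually arbitrates — and tests Pearson correlation against
note length with two-sided significance at 0.05/0.01/0.001.

## Synthetic corpus

The generator emulates the documented statistics of the study population:
577 notes (574 patients, a ~10% development split by patient with no
patient overlap), per-category prevalences spanning 0.03–0.33 with mean
0.10, log-normal lengths with median 423 tokens and log-SD 1.3436 (chosen
to match a ≈1043-token mean) clamped to [11, 10719], and 24.4% comorbidity
among positive notes.

Prevalences are enforced by **stratified exact-count allocation**
(round(n·p) positive notes per category) with comorbidity steered by
assigning extra category slots to a controlled fraction of positive notes.
Independent per-note Bernoulli draws could not satisfy both the prevalence
margins and the comorbidity rate simultaneously (under independence, these
prevalences would imply ~43% comorbidity). The binomial-3-SD fidelity
check is therefore met by construction.

The span grammar covers seven styles (plain, abbreviated, checkbox,
remission, parenthetical, slash-combined, unspecified) and reproduces every
attested variant string, including the checkbox criteria block and
"mj ud"-style abbreviations. Slash-combined spans
("cannabis/alcohol/opioid use disorder: mild") are emitted only on
comorbid notes and registered as gold for every named category. Two
structural guarantees are maintained and regression-tested:

* every gold span passes filters (i)–(iii) against its own note, so the
  oracle pipeline's perfect-score property is well-posed;
* no token-boundary truncation of one gold span equals another gold span,
  so a chunk window cutting a span cannot surface a second spurious oracle
  candidate (e.g. the bare string "alcohol use disorder" is never itself a
  gold span).

Distractors — past problem lists ("previous encounters problem list
includes: {x} cannabis abuse"), rule-out lines, and negated use — always
name categories that are *negative* for the note, and filler text contains
no substance terms, so distractor phrasing can never collide with a gold
span. Distractor rates (0.15 / 0.10 / 0.20 per note) are plausible
defaults, not published quantities.

What the generator does **not** emulate: clinician typos and neologisms,
genuine negation/assertion ambiguity inside diagnosis sections, section
vocabularies of 79 real note types, ICD-10/CPT-driven sampling, or any
lexical variation beyond its grammar. Passing the oracle tests therefore
shows the pipeline machinery is correct, not that any particular backend
would reach a given accuracy on real notes; real-model scores on real
corpora remain out of reach of this harness by design.

## Problem sizes and numerical choices

The end-to-end checks run the full 577-note corpus (≈6350 note-category
pairs, ≈35k generation calls per backend) with the mock backends; metric
oracles use 1000 random token-multiset pairs at 1e-12 agreement; the regex
groundedness sweep uses a 100-note corpus. Degenerate inputs are defined
explicitly: empty notes yield zero candidates and a warning; empty
candidate lists yield the sentinel with method `all_unanswerable`;
zero-variance candidate counts leave the Pearson coefficient undefined
(NaN) rather than zero; a prompt consuming the whole input budget is a
configuration error that names the required re-chunking window.

## Known limitations

* Filter (iii) is one defensible reading of an ambiguous specification;
  the config exposes `min_len` but not alternative quantifier semantics.
* The default embedder is lexical; answers that are semantically close but
  lexically disjoint from the proxy would be mis-ranked until a contextual
  encoder is plugged in.
* The regex rules are a reconstruction from the stated recipe, not a
  published rule file.
* Prompt refinement history (the iterative engineering that produced the
  final prompt wording) is not modelled; only the final template ships.
* Real-model behaviour (hallucination patterns, verbosity) is approximated
  by three stylised mocks; the mocks bound, but do not estimate, real
  accuracy.
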