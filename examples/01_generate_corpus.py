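"""Generate a synthetic clinical-note corpus and inspect its structure.

Builds the default 577-note corpus (per-category SUD prevalence 3-33%,
log-normal note lengths, 24.4% comorbidity among positive notes) and prints
the statistics a real corpus of this shape would exhibit.
"""

from collections import Counter

import numpy as np

from sudspan import CorpusSpec, dev_test_split, generate_corpus

spec = CorpusSpec(seed=42)
notes, gold = generate_corpus(spec)

lengths = [len(n["text"].split()) for n in notes]
print(f"notes: {len(notes)}   gold spans: {len(gold)}")
print(
    f"note length tokens: min {min(lengths)}, median {int(np.median(lengths))}, "
    f"mean {int(np.mean(lengths))}, max {max(lengths)}"
)

counts = Counter(g["category"] for g in gold)
print("\npositive notes per category (prevalence):")
for cat, k in counts.most_common():
    print(f"  {cat:<30s} {k:4d}  ({k / len(notes):.0%})")

per_note = Counter(g["note_id"] for g in gold)
multi = sum(1 for v in per_note.values() if v >= 2)
print(f"\ncomorbid positive notes: {multi}/{len(per_note)} = {multi / len(per_note):.1%}")

dev, test = dev_test_split(notes, dev_fraction=0.10, seed=0)
print(f"development/test split by patient: {len(dev)}/{len(test)} notes")

example = next(g for g in gold if "meets criteria" in g["span_text"])
print(f"\na checkbox-style gold span:\n  {example['span_text']}")
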