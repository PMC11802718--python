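"""Walk one clinical note through prompting, chunking and post-processing.

Shows the per-category prompt, the sliding-window chunk plan for a long
note, the per-chunk candidate answers from a mock generation backend, and
the four-stage reduction to a single final answer.
"""

from sudspan import (
    HashingNgramEmbedder,
    NoisyBackend,
    OracleBackend,
    SUDCategory,
    build_prompt,
    lexicon_map,
    postprocess_note,
    run_extraction,
)
from sudspan.chunker import WhitespaceTokenizer, make_chunks, plan_window

gold = [{"note_id": "n1", "category": "alcohol", "span_text": "severe etoh use d/o"}]
filler = " ".join(
    "patient seen today for routine follow up visit in the clinic".split() * 60
)
note = {"note_id": "n1", "text": f"{filler}\nassessment / diagnoses:\ndx: severe etoh use d/o"}

prompt = build_prompt(SUDCategory.alcohol, "<clinical note text>")
print("prompt:")
print(f"  {prompt}\n")

tok = WhitespaceTokenizer()
note_tokens = tok.tokenize(note["text"])
prompt_tokens = tok.tokenize(prompt.replace(" <clinical note text>", ""))
window = plan_window(prompt_tokens, max_len=512)
chunks = make_chunks(note_tokens, window, stride=128)
print(f"note has {len(note_tokens)} tokens; prompt {len(prompt_tokens)} tokens")
print(f"window {window} tokens, stride 128 -> {len(chunks)} chunks:")
for c in chunks:
    print(f"  tokens [{c.start_token}, {c.end_token})")

lex = lexicon_map()[SUDCategory.alcohol]
embedder = HashingNgramEmbedder()
for name, backend in [("oracle", OracleBackend(gold)), ("noisy", NoisyBackend(gold))]:
    candidates = run_extraction(note, SUDCategory.alcohol, backend)
    final = postprocess_note(candidates, note["text"], lex, embedder)
    print(f"\n{name} backend:")
    print(f"  per-chunk candidates: {[c.text for c in candidates]}")
    print(f"  final answer: {final.text!r}  (selection: {final.selection_method})")
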