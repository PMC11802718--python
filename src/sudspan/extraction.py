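"""Prompt construction and zero-shot candidate extraction.

One prompt per SUD category, following the refined template: the model is
asked to extract the reference to the category's use-disorder diagnosis with
its surrounding context, and to answer with the literal escape word
"unanswerable" when no such reference exists.  Only the category noun phrase
changes between categories.  Each note chunk is prompted independently,
yielding one candidate answer per chunk.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Protocol, Sequence

from .chunker import (
    Chunk,
    TokenizerContract,
    WhitespaceTokenizer,
    assemble_input,
    make_chunks,
    plan_window,
)
from .lexicon import CATEGORY_DISPLAY, SUDCategory

log = logging.getLogger(__name__)

#: Literal escape word the prompt instructs the model to emit.
UNANSWERABLE = "unanswerable"

DEFAULT_TEMPLATE = (
    "Extract the reference to {category} use disorder diagnosis with "
    "surrounding information relevant to it from the diagnoses section in "
    'the following note. If you can\'t find the answer, please respond '
    '"unanswerable". Note: {note}'
)


@dataclass(frozen=True)
class PromptTemplate:
    """A per-category prompt with a single ``{note}`` placeholder."""

    category: SUDCategory
    text: str = DEFAULT_TEMPLATE

    def __post_init__(self) -> None:
        if self.text.count("{note}") != 1:
            raise ValueError("template must contain exactly one {note} placeholder")
        if UNANSWERABLE not in self.text.lower():
            raise ValueError('template must contain the "unanswerable" escape word')

    def render(self, chunk_text: str) -> str:
        return self.text.format(
            category=CATEGORY_DISPLAY[self.category], note=chunk_text
        )

    def prefix(self) -> str:
        """The prompt with an empty note body (the tokens prepended to chunks)."""
        return self.render("").rstrip()


def default_templates() -> dict[SUDCategory, PromptTemplate]:
    return {c: PromptTemplate(category=c) for c in SUDCategory}


def build_prompt(
    category: SUDCategory,
    chunk_text: str,
    templates: Mapping[SUDCategory, PromptTemplate] | None = None,
) -> str:
    """Substitute the category display name and chunk into the template."""
    templates = templates if templates is not None else default_templates()
    if category not in templates:
        raise KeyError(f"no prompt template registered for {category.value}")
    return templates[category].render(chunk_text)


@dataclass(frozen=True)
class GenerationConfig:
    """Decoding settings: greedy decoding, temperature 1, 100 new tokens.

    Greedy decoding makes repeated calls on identical input deterministic
    for a given backend.
    """

    decoding: str = "greedy"
    temperature: float = 1.0
    max_new_tokens: int = 100


class GenerationBackend(Protocol):
    """Anything that maps an input text to a generated text."""

    def generate(self, input_text: str, config: GenerationConfig) -> str: ...


@dataclass(frozen=True)
class CandidateAnswer:
    """Raw backend output for one (note chunk, category) pair."""

    note_id: str
    category: SUDCategory
    chunk_index: int
    text: str


def is_unanswerable(text: str) -> bool:
    """Case-insensitive containment check for the escape word."""
    return UNANSWERABLE in text.lower()


@dataclass
class ExtractionParams:
    stride: int = 128
    max_len: int = 512
    window: int | None = None  # None: planned from the prompt length
    tokenizer: TokenizerContract = field(default_factory=WhitespaceTokenizer)


def run_extraction(
    note: Mapping[str, str],
    category: SUDCategory,
    backend: GenerationBackend,
    cfg: GenerationConfig | None = None,
    params: ExtractionParams | None = None,
    templates: Mapping[SUDCategory, PromptTemplate] | None = None,
) -> list[CandidateAnswer]:
    """Chunk one note, prompt the backend per chunk, collect raw candidates.

    ``note`` is a record with at least ``note_id`` and ``text``.  Backend
    failures on a chunk are logged and recorded as the unanswerable sentinel
    so the run continues; an empty note yields zero candidates and a warning.
    """
    cfg = cfg or GenerationConfig()
    params = params or ExtractionParams()
    templates = templates if templates is not None else default_templates()
    if category not in templates:
        raise KeyError(f"no prompt template registered for {category.value}")
    template = templates[category]

    note_id = str(note["note_id"])
    tok = params.tokenizer
    note_tokens = tok.tokenize(note["text"])
    if not note_tokens:
        log.warning("note %s is empty; no candidates generated", note_id)
        return []

    prompt_tokens = tok.tokenize(template.prefix())
    window = params.window or plan_window(prompt_tokens, params.max_len)
    chunks = make_chunks(note_tokens, window, params.stride, tok.detokenize)

    candidates: list[CandidateAnswer] = []
    for i, chunk in enumerate(chunks):
        input_text = assemble_input(prompt_tokens, chunk, params.max_len, tok.detokenize)
        try:
            out = backend.generate(input_text, cfg)
        except Exception:  # noqa: BLE001 - per-chunk failures must not abort the run
            log.exception("backend failed on note %s chunk %d", note_id, i)
            out = UNANSWERABLE
        candidates.append(CandidateAnswer(note_id, category, i, out))
    return candidates
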