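"""Generation backends.

The pipeline is backend-agnostic: anything honouring the
:class:`~sudspan.extraction.GenerationBackend` contract (text in, text out,
deterministic under greedy decoding) can drive it.  Three mock backends make
every downstream stage testable without a GPU-scale model:

* :class:`OracleBackend` returns the known gold span when it appears
  verbatim in the prompted chunk, else the unanswerable sentinel -- an
  upper-bound extractor.
* :class:`NoisyBackend` wraps the oracle and pads every positive answer with
  deterministic extra words, reproducing the characteristic
  "recall 1, precision < 1" behaviour of generative extraction.
* :class:`HallucinatingBackend` wraps the oracle and, at a seeded fixed
  rate, answers with a span from a *different* category, exercising the
  hallucination filters.

:class:`HFSeq2SeqBackend` adapts any instruction-tuned encoder-decoder model
from the ``transformers`` hub (imported lazily; an optional extra).
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np

from .extraction import (
    UNANSWERABLE,
    GenerationConfig,
    PromptTemplate,
    default_templates,
)
from .lexicon import SUDCategory


def spans_by_category(gold: Iterable[Mapping[str, str]]) -> dict[SUDCategory, list[str]]:
    """Unique gold span strings per category, longest first (ties: lexicographic).

    Longest-first ordering makes the oracle prefer a full span over a stored
    span that happens to be a substring of it.
    """
    acc: dict[SUDCategory, set[str]] = {}
    for rec in gold:
        cat = SUDCategory(rec["category"])
        acc.setdefault(cat, set()).add(rec["span_text"])
    return {c: sorted(s, key=lambda t: (-len(t), t)) for c, s in acc.items()}


class OracleBackend:
    """Return the gold span if it appears verbatim in the chunk, else the sentinel.

    The category is recovered from the (fixed, category-inlined) prompt
    prefix; the search is restricted to the chunk portion of the input.
    """

    def __init__(
        self,
        gold: Iterable[Mapping[str, str]],
        templates: Mapping[SUDCategory, PromptTemplate] | None = None,
    ) -> None:
        self._spans = spans_by_category(gold)
        templates = templates if templates is not None else default_templates()
        self._prefixes = {c: t.prefix() for c, t in templates.items()}

    def _split(self, input_text: str) -> tuple[SUDCategory | None, str]:
        for cat, prefix in self._prefixes.items():
            if input_text.startswith(prefix):
                return cat, input_text[len(prefix):]
        return None, input_text

    def generate(self, input_text: str, config: GenerationConfig) -> str:
        category, chunk_region = self._split(input_text)
        if category is None:
            return UNANSWERABLE
        for span in self._spans.get(category, ()):
            if span in chunk_region:
                return span
        return UNANSWERABLE


class NoisyBackend:
    """Oracle answers padded with deterministic prefix/suffix words."""

    def __init__(
        self,
        gold: Iterable[Mapping[str, str]],
        prefix: str = "per chart review",
        suffix: str = "as documented",
        templates: Mapping[SUDCategory, PromptTemplate] | None = None,
    ) -> None:
        self._oracle = OracleBackend(gold, templates)
        self._prefix = prefix
        self._suffix = suffix

    def generate(self, input_text: str, config: GenerationConfig) -> str:
        out = self._oracle.generate(input_text, config)
        if out == UNANSWERABLE:
            return out
        return f"{self._prefix} {out} {self._suffix}".strip()


class HallucinatingBackend:
    """Oracle that, at a fixed seeded rate, answers with a wrong-category span.

    Injected answers are recorded in :attr:`injections` as
    ``(prompted_category, injected_text)`` pairs so tests can measure how
    many hallucinations the post-processing filters remove.
    """

    def __init__(
        self,
        gold: Iterable[Mapping[str, str]],
        rate: float = 0.2,
        seed: int = 0,
        templates: Mapping[SUDCategory, PromptTemplate] | None = None,
    ) -> None:
        if not 0.0 <= rate <= 1.0:
            raise ValueError(f"rate must be in [0, 1], got {rate}")
        self._oracle = OracleBackend(gold, templates)
        self._spans = self._oracle._spans
        self._rate = rate
        self._rng = np.random.default_rng(seed)
        self.injections: list[tuple[SUDCategory, str]] = []

    def generate(self, input_text: str, config: GenerationConfig) -> str:
        category, _ = self._oracle._split(input_text)
        others = [c for c in self._spans if c != category and self._spans[c]]
        if category is not None and others and self._rng.random() < self._rate:
            donor = others[int(self._rng.integers(len(others)))]
            span = self._spans[donor][int(self._rng.integers(len(self._spans[donor])))]
            self.injections.append((category, span))
            return span
        return self._oracle.generate(input_text, config)


class HFSeq2SeqBackend:
    """Adapter for instruction-tuned seq2seq models on the HuggingFace hub.

    Requires the ``hf`` extra (transformers, torch, sentencepiece).  Greedy
    decoding is enforced regardless of the model's generation defaults.
    """

    def __init__(self, model_name: str = "google/flan-t5-small", device: str = "cpu") -> None:
        from transformers import AutoModelForSeq2SeqLM, AutoTokenizer  # lazy

        self.tokenizer = AutoTokenizer.from_pretrained(model_name)
        self.model = AutoModelForSeq2SeqLM.from_pretrained(model_name).to(device)
        self.device = device

    def generate(self, input_text: str, config: GenerationConfig) -> str:
        import torch  # lazy

        inputs = self.tokenizer(
            input_text, return_tensors="pt", truncation=True
        ).to(self.device)
        with torch.no_grad():
            out = self.model.generate(
                **inputs,
                do_sample=False,
                num_beams=1,
                temperature=config.temperature,
                max_new_tokens=config.max_new_tokens,
            )
        return self.tokenizer.decode(out[0], skip_special_tokens=True)
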