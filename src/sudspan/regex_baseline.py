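"""Rule-based extraction baseline.

Patterns combine the category's substance names, use-disorder phrases and
severity specifiers in the orderings seen in clinical text:

    (severity)? substance (filler)? disorder (filler severity/remission)? (parenthetical)?

with filler gaps bounded at 40 characters so parentheticals like
"(kratom)" or "(nitrous oxide)" are captured without producing runaway
spans.  Like any rigid string search, the baseline cannot tell an assigned
diagnosis from a "rule out" mention -- "r/o alcohol use disorder" matches,
which is a deliberate, documented limitation.

Every non-sentinel answer is a verbatim substring of the note: the defining
contrast with generative extraction.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .extraction import UNANSWERABLE
from .lexicon import CategoryLexicon, SUDCategory
from .postprocess import FinalAnswer

_FILLER = r"[^\n]{0,40}?"


class PatternError(ValueError):
    pass


@dataclass(frozen=True)
class RulePattern:
    category: SUDCategory
    pattern: re.Pattern
    description: str


def _alt(terms: list[str]) -> str:
    """Alternation of escaped terms, longest first so e.g. "use disorder"
    wins over "ud" at the same position."""
    return "|".join(re.escape(t) for t in sorted(terms, key=lambda t: (-len(t), t)))


def build_patterns(lex: CategoryLexicon) -> list[RulePattern]:
    """Compile the rule patterns for one category."""
    sev = _alt(lex.severity_terms)
    sub = _alt(lex.substance_terms)
    dis = _alt(lex.disorder_terms)
    core = rf"(?:(?:{sev})[\s:,\-]{{1,3}})?(?:{sub}){_FILLER}(?:{dis})"
    specs = [
        (
            core + rf"{_FILLER}(?:{sev})(?:\s*\([^)\n]{{0,40}}\))?",
            "substance-disorder with trailing severity/remission specifier",
        ),
        (
            core + r"(?:\s*\([^)\n]{0,40}\))?",
            "substance-disorder, optional leading severity and parenthetical",
        ),
    ]
    patterns = []
    for expr, desc in specs:
        try:
            patterns.append(
                RulePattern(lex.category, re.compile(expr, re.IGNORECASE), desc)
            )
        except re.error as exc:  # pragma: no cover - terms are escaped
            raise PatternError(f"{lex.category.value}: {exc}") from exc
    return patterns


def extract_regex(
    note_text: str,
    patterns: list[RulePattern],
    note_id: str = "",
) -> FinalAnswer:
    """First (leftmost, then longest) rule match, or the sentinel.

    One evaluated answer per note, matching how the baseline is scored
    against per-note gold spans.
    """
    if not patterns:
        raise PatternError("no patterns supplied")
    category = patterns[0].category
    best: re.Match | None = None
    for rp in patterns:
        for m in rp.pattern.finditer(note_text):
            if (
                best is None
                or m.start() < best.start()
                or (m.start() == best.start() and m.end() > best.end())
            ):
                best = m
    if best is None:
        return FinalAnswer(note_id, category, UNANSWERABLE, "regex")
    return FinalAnswer(note_id, category, best.group(0), "regex", n_candidates=1, n_survivors=1)
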