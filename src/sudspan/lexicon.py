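"""Substance-use-disorder category lexicons.

Eleven DSM-5 SUD diagnostic categories, each with a term set used by the
post-processing filters, the regex baseline and proxy-answer selection:

* ``substance_terms`` -- names and abbreviations of the substance
  ("alcohol", "etoh", "mj", ...),
* ``disorder_terms`` -- phrases signalling a use disorder
  ("use disorder", "dependence", "use d/o", "ud", ...),
* ``severity_terms`` -- DSM-5 severity specifiers and remission qualifiers,
* ``proxy_ground_truth`` -- a canonical per-category phrase used only to
  rank multiple surviving candidate answers in embedding space.

Matching is plain substring containment on lowercased, whitespace-collapsed
text.  Word-boundary matching is deliberately not used: clinical
abbreviations such as "use d/o" and "use do" break word-boundary
assumptions.
"""

from __future__ import annotations

from enum import Enum
from importlib import resources
from pathlib import Path

import yaml
from pydantic import BaseModel, field_validator, model_validator


class LexiconConfigError(ValueError):
    """Raised when a lexicon configuration file violates the contract."""


class SUDCategory(str, Enum):
    """The 11 substance-use-disorder diagnostic categories."""

    alcohol = "alcohol"
    opioid = "opioid"
    cannabis = "cannabis"
    sedative_hypnotic_anxiolytic = "sedative_hypnotic_anxiolytic"
    cocaine = "cocaine"
    amphetamine = "amphetamine"
    caffeine = "caffeine"
    hallucinogen = "hallucinogen"
    nicotine = "nicotine"
    inhalant = "inhalant"
    other_psychoactive = "other_psychoactive"


#: Human-readable noun phrase used when inlining the category into a prompt.
CATEGORY_DISPLAY: dict[SUDCategory, str] = {
    SUDCategory.alcohol: "alcohol",
    SUDCategory.opioid: "opioid",
    SUDCategory.cannabis: "cannabis",
    SUDCategory.sedative_hypnotic_anxiolytic: "sedative, hypnotic, or anxiolytic",
    SUDCategory.cocaine: "cocaine",
    SUDCategory.amphetamine: "amphetamine",
    SUDCategory.caffeine: "caffeine",
    SUDCategory.hallucinogen: "hallucinogen",
    SUDCategory.nicotine: "nicotine",
    SUDCategory.inhalant: "inhalant",
    SUDCategory.other_psychoactive: "other psychoactive substance",
}


def normalize(text: str) -> str:
    """Lowercase and collapse all whitespace runs to single spaces."""
    return " ".join(text.lower().split())


class CategoryLexicon(BaseModel):
    """Term sets for one SUD category."""

    category: SUDCategory
    substance_terms: list[str]
    disorder_terms: list[str]
    severity_terms: list[str]
    proxy_ground_truth: str

    @field_validator("substance_terms", "disorder_terms", "severity_terms")
    @classmethod
    def _terms_valid(cls, v: list[str]) -> list[str]:
        if not v:
            raise ValueError("term list must be non-empty")
        for t in v:
            if not t:
                raise ValueError("empty term")
            if t != t.lower():
                raise ValueError(f"term not lowercase: {t!r}")
        return v

    @field_validator("proxy_ground_truth")
    @classmethod
    def _proxy_lower(cls, v: str) -> str:
        if not v or v != v.lower():
            raise ValueError("proxy_ground_truth must be non-empty lowercase")
        return v

    @model_validator(mode="after")
    def _proxy_grounded(self) -> "CategoryLexicon":
        if not any(t in self.proxy_ground_truth for t in self.substance_terms):
            raise ValueError(
                f"{self.category.value}: proxy ground truth contains no substance term"
            )
        if not any(t in self.proxy_ground_truth for t in self.disorder_terms):
            raise ValueError(
                f"{self.category.value}: proxy ground truth contains no disorder term"
            )
        return self


def _first_position(norm_text: str, terms: list[str]) -> int:
    """Character offset of the earliest occurrence of any term, or -1."""
    best = -1
    for t in terms:
        p = norm_text.find(t)
        if p != -1 and (best == -1 or p < best):
            best = p
    return best


def contains_substance(text: str, lex: CategoryLexicon) -> bool:
    """True iff the normalised text contains at least one substance term."""
    norm = normalize(text)
    return any(t in norm for t in lex.substance_terms)


def contains_disorder(text: str, lex: CategoryLexicon) -> bool:
    """True iff a disorder term occurs at or after the first substance term.

    The ordering requirement operationalises "phrases representing use
    disorder ... following the substance names": a note like "use disorder
    without substance alcohol" does not qualify because the disorder phrase
    precedes the substance name.
    """
    norm = normalize(text)
    p = _first_position(norm, lex.substance_terms)
    if p == -1:
        return False
    return any(norm.find(t, p) != -1 for t in lex.disorder_terms)


def default_lexicon_path() -> Path:
    return Path(str(resources.files("sudspan").joinpath("data/default_lexicon.yaml")))


def load_lexicons(config_path: str | Path | None = None) -> list[CategoryLexicon]:
    """Load the 11 category lexicons from a YAML config file.

    The file has a ``categories`` mapping (one block per category with keys
    ``substance_terms``, ``disorder_terms``, ``severity_terms``,
    ``proxy_ground_truth``) and an optional ``shared_substance_terms`` list of
    terms that may legitimately occur in several categories (e.g. the generic
    "substance use disorder" phrase of checkbox-style diagnoses).

    Raises :class:`LexiconConfigError` naming the offending category when one
    is missing or a term list is empty.
    """
    path = Path(config_path) if config_path is not None else default_lexicon_path()
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict) or "categories" not in raw:
        raise LexiconConfigError(f"{path}: missing top-level 'categories' mapping")
    blocks = raw["categories"]
    missing = [c.value for c in SUDCategory if c.value not in blocks]
    if missing:
        raise LexiconConfigError(f"missing categories: {', '.join(missing)}")
    shared = set(raw.get("shared_substance_terms", []))

    lexicons: list[CategoryLexicon] = []
    for cat in SUDCategory:
        block = blocks[cat.value]
        try:
            lexicons.append(CategoryLexicon(category=cat, **block))
        except ValueError as exc:
            raise LexiconConfigError(f"category {cat.value}: {exc}") from exc

    # Substance terms must be category-specific except for the allowlist.
    seen: dict[str, str] = {}
    for lex in lexicons:
        for t in lex.substance_terms:
            if t in shared:
                continue
            if t in seen and seen[t] != lex.category.value:
                raise LexiconConfigError(
                    f"substance term {t!r} shared by {seen[t]} and "
                    f"{lex.category.value} but not in shared_substance_terms"
                )
            seen[t] = lex.category.value
    return lexicons


def lexicon_map(
    config_path: str | Path | None = None,
) -> dict[SUDCategory, CategoryLexicon]:
    return {lex.category: lex for lex in load_lexicons(config_path)}
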