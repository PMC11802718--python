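"""Seeded synthetic clinical-note corpora with gold SUD severity spans.

Real clinical corpora of this kind cannot be shared, so the harness runs on
simulated notes that reproduce the documented statistical structure of the
study population: 11 SUD categories with per-category positive prevalence
between 3% and 33% (mean 10%), note lengths log-normally distributed around
a 423-token median (clamped to 11-10719 tokens), multi-SUD comorbidity in
about 24.4% of positive notes, free-text structure without a fixed section
order, and distractor mentions (past problem lists, "rule out" diagnoses,
negated use) that carry substance words without constituting a diagnosis.

Gold spans follow the annotation convention of the source task: the
severity specifier together with the SUD mention as a single continuous
string, verbatim as it appears in the note; absence of a severity term
means "unspecified".  The span grammar covers plain, abbreviated,
checkbox, remission, parenthetical, slash-combined and
unspecified-severity phrasings, and can produce every diagnosis variant
string quoted in the source material.

Two structural guarantees keep the oracle-backend harness well-posed:

* every gold span passes post-processing filters (i)-(iii) against its own
  note;
* no token-boundary truncation of one gold span equals another gold span
  string, so a chunk window that cuts a span cannot surface a second,
  spurious candidate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from pydantic import BaseModel, Field, field_validator

from .lexicon import SUDCategory

# ---------------------------------------------------------------------------
# corpus specification

_DEFAULT_PREVALENCE: dict[SUDCategory, float] = {
    SUDCategory.alcohol: 0.33,
    SUDCategory.opioid: 0.15,
    SUDCategory.cannabis: 0.13,
    SUDCategory.nicotine: 0.12,
    SUDCategory.cocaine: 0.10,
    SUDCategory.amphetamine: 0.08,
    SUDCategory.sedative_hypnotic_anxiolytic: 0.06,
    SUDCategory.hallucinogen: 0.04,
    SUDCategory.caffeine: 0.03,
    SUDCategory.inhalant: 0.03,
    SUDCategory.other_psychoactive: 0.03,
}


class CorpusSpec(BaseModel):
    """Parameters of a synthetic corpus; the seed fixes it byte-for-byte."""

    n_notes: int = 577
    prevalence: dict[SUDCategory, float] = Field(
        default_factory=lambda: dict(_DEFAULT_PREVALENCE)
    )
    length_median: float = 423.0  # tokens; log-normal location
    length_sigma: float = 1.3436  # log-scale spread, matches a ~1043-token mean
    length_min: int = 11
    length_max: int = 10719
    comorbidity_rate: float = 0.244  # fraction of positive notes with >=2 SUDs
    problem_list_rate: float = 0.15  # past-problem-list distractor
    rule_out_rate: float = 0.10  # "r/o ..." distractor
    negation_rate: float = 0.20  # "denies ..." distractor
    seed: int = 0

    @field_validator("prevalence")
    @classmethod
    def _prev_valid(cls, v: dict[SUDCategory, float]) -> dict[SUDCategory, float]:
        for c, p in v.items():
            if not 0.0 < p <= 1.0:
                raise ValueError(f"prevalence for {c} must be in (0, 1], got {p}")
        return v

    @field_validator("n_notes")
    @classmethod
    def _n_valid(cls, v: int) -> int:
        if v < 0:
            raise ValueError("n_notes must be >= 0")
        return v


@dataclass(frozen=True)
class GoldAnnotation:
    """A per-category verbatim gold span of one note."""

    note_id: str
    category: SUDCategory
    span_text: str


# ---------------------------------------------------------------------------
# diagnosis span grammar

SEVERITIES = ["mild", "moderate", "severe"]
REMISSIONS = ["in remission", "in sustained remission", "in early remission"]

STYLES = (
    "plain",
    "abbreviated",
    "checkbox",
    "remission",
    "parenthetical",
    "slash_combined",
    "unspecified",
)

_SLASH_TRIO = (SUDCategory.cannabis, SUDCategory.alcohol, SUDCategory.opioid)


def _checkbox(substance: str, severity: str) -> str:
    ticks = {s: "x" if s == severity else "" for s in SEVERITIES}
    return (
        f"meets criteria for substance use disorder: {substance} "
        f"[{ticks['mild']}] mild (2-3); [{ticks['moderate']}] moderate (4-5); "
        f"[{ticks['severe']}] severe (6 or more)"
    )


# Template placeholders: {sev} severity, {rem} remission qualifier.  Literal
# templates reproduce attested real-world variants verbatim.  The grammar is
# audited (tests) so no token-boundary truncation of one rendering equals
# another rendering.
_TEMPLATES: dict[SUDCategory, dict[str, list[str]]] = {
    SUDCategory.alcohol: {
        "plain": ["{sev} alcohol use disorder", "alcohol use disorder mod/severe"],
        "abbreviated": ["{sev} etoh use d/o"],
        "remission": ["alcohol use disorder, {rem}"],
        "parenthetical": ["alcohol (etoh) use disorder - {sev}"],
        "unspecified": ["alcohol (etoh) use d/o"],
    },
    SUDCategory.opioid: {
        "plain": ["{sev} opioid use disorder"],
        "parenthetical": [
            "opioid (heroin/ vicodin) use disorder - severe (on agonist therapy)",
            "opioid (kratom) use disorder - {sev}",
        ],
        "remission": ["opioid use disorder, {rem}"],
        "unspecified": [
            "opioid (kratom) use disorder, severity unspecified",
            "opioid (kratom) use d/o",
        ],
    },
    SUDCategory.cannabis: {
        "plain": ["{sev} cannabis use disorder"],
        "abbreviated": ["{sev} mj ud"],
        "remission": ["cannabis use disorder, {rem}", "marijuana user (in remission)"],
        "parenthetical": ["cannabis (thc vape) use disorder, {sev}"],
        "unspecified": ["cannabis (thc) use d/o"],
    },
    SUDCategory.sedative_hypnotic_anxiolytic: {
        "plain": [
            "{sev} sedative use disorder",
            "sedative hypnotic use disorder, severe (xanax)",
        ],
        "remission": [
            "(ephedrine) sedative use disorder, in sustained remission",
            "benzodiazepine use disorder, {rem}",
        ],
        "unspecified": ["sedative (valium) use d/o"],
    },
    SUDCategory.cocaine: {
        "plain": ["{sev} cocaine use disorder"],
        "checkbox": ["__checkbox__"],
        "remission": ["cocaine use disorder, {rem}"],
        "unspecified": ["cocaine (crack) use d/o"],
    },
    SUDCategory.amphetamine: {
        "plain": ["{sev} amphetamine use disorder"],
        "abbreviated": ["{sev} meth use d/o"],
        "parenthetical": [
            "amphetamine (methamphetamine) or other stimulant, without "
            "perceptual disturbances disorder, sever, in remission",
        ],
        "unspecified": ["amphetamine (methamphetamine) use d/o"],
    },
    SUDCategory.caffeine: {
        "plain": ["{sev} caffeine use disorder"],
        "abbreviated": ["{sev} caffeine use do"],
        "remission": ["caffeine use disorder, {rem}"],
    },
    SUDCategory.hallucinogen: {
        "plain": ["{sev} hallucinogen use disorder"],
        "remission": [
            "other hallucinogen use disorder (mdma/ecstasy), moderate, in remission",
        ],
        "unspecified": ["hallucinogen (lsd) use d/o"],
    },
    SUDCategory.nicotine: {
        "plain": ["{sev} nicotine use disorder"],
        "parenthetical": ["tobacco (cigarette) use disorder ({sev})"],
        "remission": ["nicotine use disorder, {rem}"],
        "unspecified": ["nicotine (cigarette) use d/o"],
    },
    SUDCategory.inhalant: {
        "plain": ["{sev} inhalant (nitrous oxide) use d/o"],
        "remission": ["inhalant use disorder, {rem}"],
        "unspecified": ["inhalant (glue) use d/o"],
    },
    SUDCategory.other_psychoactive: {
        "plain": [
            "other psychoactive substance use disorder, {sev}",
            "other/unknown substance disorder: severe (coricidin)",
        ],
        "unspecified": ["other psychoactive substance use d/o"],
    },
}

# Checkbox phrasing is available to every category (it names the substance
# after the generic use-disorder phrase).
for _cat, _styles in _TEMPLATES.items():
    _styles.setdefault("checkbox", ["__checkbox__"])

_SUBSTANCE_NAME: dict[SUDCategory, str] = {
    SUDCategory.alcohol: "alcohol",
    SUDCategory.opioid: "opioid",
    SUDCategory.cannabis: "cannabis",
    SUDCategory.sedative_hypnotic_anxiolytic: "sedative",
    SUDCategory.cocaine: "cocaine",
    SUDCategory.amphetamine: "amphetamine",
    SUDCategory.caffeine: "caffeine",
    SUDCategory.hallucinogen: "hallucinogen",
    SUDCategory.nicotine: "nicotine",
    SUDCategory.inhalant: "inhalant",
    SUDCategory.other_psychoactive: "substance",
}


def render_diagnosis(
    category: SUDCategory, style: str, rng: np.random.Generator
) -> str:
    """Draw one diagnosis span string of the given style for the category."""
    if style not in STYLES:
        raise ValueError(f"unknown style {style!r}; known: {', '.join(STYLES)}")
    if style == "slash_combined":
        if category not in _SLASH_TRIO:
            raise ValueError(f"slash_combined is not available for {category.value}")
        subs = "/".join(_SUBSTANCE_NAME[c] for c in _SLASH_TRIO)
        return f"{subs} use disorder: {rng.choice(SEVERITIES)}"
    styles = _TEMPLATES[category]
    if style not in styles:
        raise ValueError(f"style {style!r} is not available for {category.value}")
    template = styles[style][int(rng.integers(len(styles[style])))]
    if template == "__checkbox__":
        return _checkbox(_SUBSTANCE_NAME[category], str(rng.choice(SEVERITIES)))
    return template.format(sev=rng.choice(SEVERITIES), rem=rng.choice(REMISSIONS))


def available_styles(category: SUDCategory) -> list[str]:
    styles = sorted(_TEMPLATES[category])
    if category in _SLASH_TRIO:
        styles.append("slash_combined")
    return styles


# ---------------------------------------------------------------------------
# note scaffolding

_NOTE_TYPES = [
    "mental health",
    "suicide prevention",
    "psychiatry",
    "psychology",
    "nursing",
    "education",
    "administrative",
    "primary care",
    "social work",
    "pharmacy",
]

# Free-text filler avoids every substance term so no accidental positive
# mention can form outside the diagnosis and distractor blocks.
_FILLER_SENTENCES = [
    "patient seen today for routine follow up visit in the outpatient clinic.",
    "vital signs stable and within normal limits at the time of this visit.",
    "patient reports sleeping well and appetite has been adequate recently.",
    "discussed coping skills and relapse prevention strategies at length today.",
    "no acute distress noted during the interview and examination.",
    "continues to attend weekly group sessions and individual counseling.",
    "labs reviewed and no new abnormalities were identified this visit.",
    "patient ambulates independently and denies any new physical complaints.",
    "plan to continue current regimen and follow up in four weeks.",
    "veteran expresses motivation to maintain recovery goals going forward.",
    "mood reported as stable with no current safety concerns identified.",
    "patient was oriented to person place and time throughout the encounter.",
    "reviewed treatment adherence and no side effects were reported today.",
    "housing remains stable and patient is engaged with community resources.",
    "sleep hygiene education provided and patient verbalized understanding.",
    "no suicidal or homicidal ideation reported at this time.",
]

_SECTION_HEADERS = [
    "chief complaint:",
    "history of present illness:",
    "interval history:",
    "observations:",
    "plan:",
]


def _sample_length(spec: CorpusSpec, rng: np.random.Generator) -> int:
    mu = math.log(spec.length_median)
    length = int(round(math.exp(rng.normal(mu, spec.length_sigma))))
    return int(min(max(length, spec.length_min), spec.length_max))


def _draw_spans(
    categories: list[SUDCategory], rng: np.random.Generator
) -> list[tuple[tuple[SUDCategory, ...], str]]:
    """Render one span per positive category.

    Comorbid notes covering >=2 of the slash-combinable trio may document
    those categories as a single combined span shared by all of them.
    """
    spans: list[tuple[tuple[SUDCategory, ...], str]] = []
    remaining = list(categories)
    trio = [c for c in _SLASH_TRIO if c in remaining]
    if len(trio) >= 2 and rng.random() < 0.5:
        subs = "/".join(_SUBSTANCE_NAME[c] for c in _SLASH_TRIO if c in trio)
        sev = rng.choice(SEVERITIES)
        spans.append((tuple(trio), f"{subs} use disorder: {sev}"))
        remaining = [c for c in remaining if c not in trio]
    for c in remaining:
        pool = available_styles(c)
        pool = [s for s in pool if s != "slash_combined"]
        style = pool[int(rng.integers(len(pool)))]
        spans.append(((c,), render_diagnosis(c, style, rng)))
    return spans


def generate_note(
    spec: CorpusSpec,
    rng: np.random.Generator,
    categories: list[SUDCategory] | None = None,
    note_id: str = "note-00000",
    patient_id: str = "pt-00000",
) -> tuple[dict, list[GoldAnnotation]]:
    """Generate one note and its gold annotations.

    ``categories`` fixes the positive categories; when None, each category
    is positive independently with its spec prevalence.
    """
    if categories is None:
        categories = [
            c for c in SUDCategory if rng.random() < spec.prevalence.get(c, 0.0)
        ]
    target_len = _sample_length(spec, rng)
    negatives = [c for c in SUDCategory if c not in categories]

    blocks: list[list[str]] = []
    gold: list[GoldAnnotation] = []

    if categories:
        dx_lines = ["assessment / diagnoses:"]
        for cats, span in _draw_spans(categories, rng):
            dx_lines.append(f"dx: {span}")
            for c in cats:
                gold.append(GoldAnnotation(note_id, c, span))
        blocks.append(dx_lines)

    if negatives and rng.random() < spec.problem_list_rate:
        c = negatives[int(rng.integers(len(negatives)))]
        blocks.append(
            [
                "previous encounters problem list includes:",
                f"{{x}} {_SUBSTANCE_NAME[c]} abuse",
            ]
        )
    if negatives and rng.random() < spec.rule_out_rate:
        c = negatives[int(rng.integers(len(negatives)))]
        blocks.append([f"r/o {_SUBSTANCE_NAME[c]} use disorder"])
    if negatives and rng.random() < spec.negation_rate:
        c = negatives[int(rng.integers(len(negatives)))]
        blocks.append([f"patient denies {_SUBSTANCE_NAME[c]} use at this time."])

    header = [f"note type: {_NOTE_TYPES[int(rng.integers(len(_NOTE_TYPES)))]} note"]
    fixed_tokens = sum(len(line.split()) for b in blocks + [header] for line in b)

    filler_blocks: list[list[str]] = []
    tokens = fixed_tokens
    while tokens < target_len:
        lines = [_SECTION_HEADERS[int(rng.integers(len(_SECTION_HEADERS)))]]
        for _ in range(int(rng.integers(2, 5))):
            lines.append(
                _FILLER_SENTENCES[int(rng.integers(len(_FILLER_SENTENCES)))]
            )
        block_tokens = sum(len(line.split()) for line in lines)
        if tokens + block_tokens > target_len and tokens >= spec.length_min:
            break  # stay at or under the sampled (clamped) length
        filler_blocks.append(lines)
        tokens += block_tokens

    # No fixed section order: diagnosis and distractor blocks land anywhere.
    all_blocks = blocks + filler_blocks
    order = rng.permutation(len(all_blocks))
    lines = list(header)
    for i in order:
        lines.extend(all_blocks[int(i)])
    note = {
        "note_id": note_id,
        "patient_id": patient_id,
        "note_type": header[0].removeprefix("note type: ").removesuffix(" note"),
        "text": "\n".join(lines),
    }
    return note, gold


# ---------------------------------------------------------------------------
# corpus-level allocation

def _allocate_categories(
    spec: CorpusSpec, rng: np.random.Generator
) -> list[list[SUDCategory]]:
    """Assign positive categories to notes.

    Per-category positive counts are fixed at round(n * prevalence)
    (stratified allocation), and the fraction of positive notes carrying two
    or more categories is steered to the comorbidity rate.  Independent
    per-note draws cannot satisfy both the prevalence margins and the
    comorbidity rate simultaneously.
    """
    n = spec.n_notes
    cats = list(SUDCategory)
    m = {c: int(round(n * spec.prevalence.get(c, 0.0))) for c in cats}
    total = sum(m.values())
    assigned: list[list[SUDCategory]] = [[] for _ in range(n)]
    if total == 0 or n == 0:
        return assigned
    m_max = max(m.values())
    cr = spec.comorbidity_rate
    n_multi_cats = sum(1 for v in m.values() if v > 0)
    if n_multi_cats < 2:
        cr = 0.0

    n_pos = int(round(total / (1 - cr + 2.2 * cr))) if cr > 0 else total
    n_pos = min(max(n_pos, m_max, math.ceil(total / len(cats))), n, total)
    extra = total - n_pos  # category slots beyond one per positive note
    n2 = 0 if extra == 0 else min(max(int(round(cr * n_pos)), 1), extra, n_pos)

    order = rng.permutation(n)
    pos_notes = [int(i) for i in order[:n_pos]]
    capacity = {i: 1 for i in pos_notes}
    comorbid = pos_notes[:n2]
    for j in range(extra):  # round-robin: comorbid notes mostly carry 2-3 SUDs
        capacity[comorbid[j % n2]] += 1

    for c in sorted(cats, key=lambda c: -m[c]):
        if m[c] == 0:
            continue
        eligible = [i for i in pos_notes if capacity[i] > 0 and c not in assigned[i]]
        shuffled = [eligible[int(k)] for k in rng.permutation(len(eligible))]
        chosen = sorted(shuffled, key=lambda i: -capacity[i])[: m[c]]
        if len(chosen) < m[c]:  # pragma: no cover - allocation is sized to fit
            raise RuntimeError("category allocation infeasible")
        for i in chosen:
            assigned[i].append(c)
            capacity[i] -= 1
    return assigned


def generate_corpus(spec: CorpusSpec) -> tuple[list[dict], list[dict]]:
    """Generate a full corpus: note records and gold annotation records.

    Deterministic per seed (byte-identical output); a handful of patients
    contribute two notes, mirroring a notes-to-patients ratio slightly
    above one.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_notes
    assigned = _allocate_categories(spec, rng)

    n_dup = int(round(0.005 * n))
    patient_index = list(range(n))
    for k in range(n_dup):
        patient_index[n - 1 - k] = patient_index[k]

    notes: list[dict] = []
    gold: list[dict] = []
    width = max(5, len(str(max(n - 1, 0))))
    for i in range(n):
        note, anns = generate_note(
            spec,
            rng,
            categories=assigned[i],
            note_id=f"note-{i:0{width}d}",
            patient_id=f"pt-{patient_index[i]:0{width}d}",
        )
        notes.append(note)
        gold.extend(
            {"note_id": a.note_id, "category": a.category.value, "span_text": a.span_text}
            for a in anns
        )
    return notes, gold


def dev_test_split(
    notes: list[dict], dev_fraction: float = 0.10, seed: int = 0
) -> tuple[list[str], list[str]]:
    """Split note ids into development and test sets by patient.

    A patient's notes all land on the same side, so there is no patient
    overlap between the splits.
    """
    patients = sorted({n["patient_id"] for n in notes})
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(patients))
    n_dev = int(math.ceil(dev_fraction * len(patients)))
    dev_patients = {patients[int(i)] for i in order[:n_dev]}
    dev = [n["note_id"] for n in notes if n["patient_id"] in dev_patients]
    test = [n["note_id"] for n in notes if n["patient_id"] not in dev_patients]
    return dev, test


#: The diagnosis variant strings attested in the source material's
#: variability discussion; every one is producible by the span grammar.
ATTESTED_VARIANTS: list[tuple[SUDCategory, str, str]] = [
    (SUDCategory.cannabis, "slash_combined", "cannabis/alcohol/opioid use disorder: mild"),
    (SUDCategory.alcohol, "plain", "alcohol use disorder mod/severe"),
    (SUDCategory.caffeine, "abbreviated", "moderate caffeine use do"),
    (
        SUDCategory.opioid,
        "parenthetical",
        "opioid (heroin/ vicodin) use disorder - severe (on agonist therapy)",
    ),
    (SUDCategory.cannabis, "remission", "marijuana user (in remission)"),
    (SUDCategory.cannabis, "parenthetical", "cannabis (thc vape) use disorder, mild"),
    (
        SUDCategory.sedative_hypnotic_anxiolytic,
        "remission",
        "(ephedrine) sedative use disorder, in sustained remission",
    ),
    (
        SUDCategory.sedative_hypnotic_anxiolytic,
        "plain",
        "sedative hypnotic use disorder, severe (xanax)",
    ),
    (
        SUDCategory.cocaine,
        "checkbox",
        "meets criteria for substance use disorder: cocaine "
        "[] mild (2-3); [] moderate (4-5); [x] severe (6 or more)",
    ),
    (
        SUDCategory.amphetamine,
        "parenthetical",
        "amphetamine (methamphetamine) or other stimulant, without "
        "perceptual disturbances disorder, sever, in remission",
    ),
    (
        SUDCategory.hallucinogen,
        "remission",
        "other hallucinogen use disorder (mdma/ecstasy), moderate, in remission",
    ),
    (
        SUDCategory.other_psychoactive,
        "plain",
        "other/unknown substance disorder: severe (coricidin)",
    ),
    (SUDCategory.inhalant, "plain", "moderate inhalant (nitrous oxide) use d/o"),
]
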