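"""Run the rule-based baseline and demonstrate its rule-out blind spot.

Regex patterns assemble severity, substance and use-disorder phrases into
match rules.  They extract cleanly phrased diagnoses verbatim, but cannot
tell an assigned diagnosis from a "rule out" mention.
"""

from sudspan import SUDCategory, build_patterns, extract_regex, lexicon_map

lexicons = lexicon_map()

cases = [
    (SUDCategory.alcohol, "dx: alcohol use disorder mod/severe"),
    (SUDCategory.caffeine, "a/p: moderate caffeine use do"),
    (SUDCategory.inhalant, "dx: moderate inhalant (nitrous oxide) use d/o"),
    (SUDCategory.alcohol, "assessment: alcohol use d/o, continuous use"),
    (SUDCategory.alcohol, "plan: r/o alcohol use disorder, recheck next visit"),
    (SUDCategory.alcohol, "no substance history documented"),
]

for category, text in cases:
    patterns = build_patterns(lexicons[category])
    answer = extract_regex(text, patterns)
    print(f"{category.value:<10s} {text!r}")
    print(f"           -> {answer.text!r}")

print(
    "\nnote: the r/o ('rule out') line above is matched even though it is not\n"
"an assigned diagnosis -- a structural limitation of rule-based extraction."
)
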