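"""Rule-based clinical concept recognizer.

Each lexicon synonym is compiled to a regular expression anchored at token
boundaries: a phrase matches when preceded by start-of-text or whitespace and
followed by end-of-text, whitespace, or one of ``. , ; )``.  That boundary
definition is what keeps the concept-3 phrase ``sclc`` from firing inside an
``nsclc`` token while still allowing punctuation-attached variants such as
``nsclc,`` or ``nsclc.`` to match.

On top of the literal dictionary, optional *generative* templates match
histology+site collocations that are not explicitly listed — e.g.
``adenoca lung`` or ``lung adenocarcinoma`` — as concept 1.  They are on by
default and can be disabled for strict-dictionary behavior.

Classification takes the earliest match in the report ("whichever comes
first"); a report with no match is labeled 0 with term and CUI ``"NA"``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .corpus_io import ReportRecord, normalize_whitespace
from .lexicon import Lexicon

NA = "NA"

#: Characters that count as a trailing token boundary, in addition to
#: whitespace and end-of-text.
BOUNDARY_CHARS = ".,;)"

# preceded by start or whitespace; followed by end, whitespace or boundary punctuation
_LEADING = r"(?<![^\s])"
_TRAILING = r"(?=$|\s|[.,;)])"

#: Generative concept-1 templates: optional histology prefix + "ca"/"carcinoma"
#: collocated with "lung" in either order.  "adeno" may attach directly
#: ("adenoca", "adenocarcinoma"); squamous variants (including the corpus
#: misspelling "sqaumous") appear as a separate token pair.
GENERATIVE_TEMPLATES = (
    r"(?:(?:squamous|sqaumous)\scell\s)?(?:adeno)?(?:ca\.?|carcinoma)\slung",
    r"lung\s(?:adeno)?(?:ca\.?|carcinoma)",
)


@dataclass(frozen=True)
class ConceptMatch:
    """One recognized disease-identification phrase in one report."""

    report_key: str
    concept_index: int
    cui: str
    surface: str
    offset: int


@dataclass
class PatternSet:
    """Compiled patterns grouped by concept index."""

    groups: dict[int, list[re.Pattern]] = field(default_factory=dict)
    cui_by_concept: dict[int, str] = field(default_factory=dict)
    generative: bool = True
    warnings: list[str] = field(default_factory=list)


def phrase_pattern(phrase: str) -> re.Pattern:
    """Compile one surface phrase with the boundary rules described above."""
    body = re.escape(phrase).replace(r"\ ", r"\s")
    return re.compile(_LEADING + body + _TRAILING)


def compile_patterns(lex: Lexicon, enable_generative: bool = True) -> PatternSet:
    """Compile every lexicon synonym (plus generative templates) to patterns."""
    pats = PatternSet(generative=enable_generative)
    for entry in lex.entries:
        group = [phrase_pattern(p) for p in sorted(entry.synonyms)]
        if not group:
            pats.warnings.append(
                f"entry {entry.preferred_label!r} has no synonyms; empty pattern group"
            )
        pats.groups[entry.concept_index] = group
        pats.cui_by_concept[entry.concept_index] = entry.cui
    if enable_generative and 1 in pats.groups:
        for template in GENERATIVE_TEMPLATES:
            pats.groups[1].append(re.compile(_LEADING + template + _TRAILING))
    return pats


def extract_first_concept(text: str, pats: PatternSet) -> ConceptMatch | None:
    """Earliest disease-identification phrase in ``text``, or None.

    Ties at equal offset are broken by longest surface form, then lowest
    concept index.  ``text`` must already be lowercase.
    """
    best: tuple[int, int, int] | None = None  # (offset, -len(surface), concept)
    best_match: ConceptMatch | None = None
    for concept_index in sorted(pats.groups):
        for pattern in pats.groups[concept_index]:
            m = pattern.search(text)
            if m is None:
                continue
            key = (m.start(), -len(m.group(0)), concept_index)
            if best is None or key < best:
                best = key
                best_match = ConceptMatch(
                    report_key="",
                    concept_index=concept_index,
                    cui=pats.cui_by_concept[concept_index],
                    surface=m.group(0),
                    offset=m.start(),
                )
    return best_match


def classify_report(
    record: ReportRecord, pats: PatternSet
) -> tuple[int, str, str]:
    """Label one preprocessed record: (concept label 0-3, term or NA, CUI or NA)."""
    text = record.unified_text
    if text is None:
        raise ValueError(f"record {record.key!r} has no unified text; run select_reports first")
    match = extract_first_concept(normalize_whitespace(text), pats)
    if match is None:
        return 0, NA, NA
    return match.concept_index, match.surface, match.cui


def classify_corpus(records: Sequence[ReportRecord], pats: PatternSet) -> pd.DataFrame:
    """Classify every record; one output row per report, order preserved.

    Columns: ``report_key, concept_label, extracted_term, cui, binary_label``
    where ``binary_label`` is 1 when any concept was found.
    """
    rows = []
    for rec in records:
        label, term, cui = classify_report(rec, pats)
        rows.append(
            {
                "report_key": rec.key,
                "concept_label": label,
                "extracted_term": term,
                "cui": cui,
                "binary_label": int(label > 0),
            }
        )
    return pd.DataFrame(
        rows, columns=["report_key", "concept_label", "extracted_term", "cui", "binary_label"]
    )


def brute_force_first_concept(
    text: str, lex: Lexicon, extra_concept1: Iterable[str] = ()
) -> ConceptMatch | None:
    """Independent oracle: slide every synonym over every position.

    Checks the same boundary conditions by direct character inspection rather
    than regular expressions.  ``extra_concept1`` allows the oracle to be given
    pre-expanded generative collocations as literal concept-1 phrases.
    """
    candidates: list[tuple[int, str, str]] = []  # (concept, phrase, cui)
    for entry in lex.entries:
        for phrase in entry.synonyms:
            candidates.append((entry.concept_index, phrase, entry.cui))
    c1 = lex.entry_for_index(1) if any(e.concept_index == 1 for e in lex.entries) else None
    for phrase in extra_concept1:
        if c1 is not None:
            candidates.append((1, phrase, c1.cui))

    best: tuple[int, int, int] | None = None
    best_match: ConceptMatch | None = None
    n = len(text)
    for concept_index, phrase, cui in candidates:
        plen = len(phrase)
        for start in range(0, n - plen + 1):
            if text[start : start + plen] != phrase:
                continue
            if start > 0 and not text[start - 1].isspace():
                continue
            end = start + plen
            if end < n and not (text[end].isspace() or text[end] in BOUNDARY_CHARS):
                continue
            key = (start, -plen, concept_index)
            if best is None or key < best:
                best = key
                best_match = ConceptMatch("", concept_index, cui, phrase, start)
            break  # earliest position for this phrase found
    return best_match
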