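"""Concept dictionary: load, customize, persist, and mine candidate phrases.

The lexicon maps lowercase surface phrases ("synonyms") to oncology concepts
identified by a small integer index and a UMLS CUI.  The bundled default
covers the three lung-carcinoma concepts used throughout the pipeline:

===============  ==========  =============================
concept_index    CUI         preferred label
===============  ==========  =============================
1                C0684249    Lung carcinoma
2                C0007131    Non-small cell lung carcinoma
3                C0149925    Small cell lung carcinoma
===============  ==========  =============================

Mapping files are CSV with columns ``preferred_label``, ``cui``,
``concept_index`` and a pipe-separated ``synonyms`` column.
"""

from __future__ import annotations

import csv
import re
from collections import Counter
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .errors import LexiconFormatError, LexiconValidationError, SynonymConflictError, UnknownLabelError

CUI_PATTERN = re.compile(r"^C\d{7}$")

#: Fixed concept_index -> CUI binding for the three lung-carcinoma concepts.
CONCEPT_CUI = {1: "C0684249", 2: "C0007131", 3: "C0149925"}

REQUIRED_COLUMNS = ("preferred_label", "cui", "concept_index", "synonyms")

DEFAULT_ANCHORS = frozenset({"lung", "ca", "carcinoma", "nsclc", "sclc"})


@dataclass(frozen=True)
class ConceptEntry:
    """One concept with its surface-phrase synonym set."""

    concept_index: int
    cui: str
    preferred_label: str
    synonyms: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not CUI_PATTERN.match(self.cui):
            raise LexiconValidationError(
                f"malformed CUI {self.cui!r} for entry {self.preferred_label!r}"
            )
        expected = CONCEPT_CUI.get(self.concept_index)
        if expected is not None and expected != self.cui:
            raise LexiconValidationError(
                f"concept_index {self.concept_index} is bound to {expected}, got {self.cui!r}"
            )
        bad = [s for s in self.synonyms if s != s.lower()]
        if bad:
            raise LexiconValidationError(f"synonyms must be lowercase: {bad!r}")

    def with_synonyms(self, extra: Iterable[str]) -> "ConceptEntry":
        return replace(self, synonyms=self.synonyms | {s.lower() for s in extra})


@dataclass(frozen=True)
class Lexicon:
    """Ordered collection of :class:`ConceptEntry` with phrase-uniqueness."""

    entries: tuple[ConceptEntry, ...]
    provenance: str = ""

    def __post_init__(self) -> None:
        owner: dict[str, str] = {}
        for entry in self.entries:
            for phrase in entry.synonyms:
                if phrase in owner:
                    raise SynonymConflictError(phrase, owner[phrase], entry.preferred_label)
                owner[phrase] = entry.preferred_label

    def entry_for_label(self, preferred_label: str) -> ConceptEntry:
        for entry in self.entries:
            if entry.preferred_label == preferred_label:
                return entry
        raise UnknownLabelError(f"no entry with preferred label {preferred_label!r}")

    def entry_for_index(self, concept_index: int) -> ConceptEntry:
        for entry in self.entries:
            if entry.concept_index == concept_index:
                return entry
        raise UnknownLabelError(f"no entry with concept index {concept_index}")

    def all_synonyms(self) -> frozenset[str]:
        out: set[str] = set()
        for entry in self.entries:
            out |= entry.synonyms
        return frozenset(out)

    def owner_of(self, phrase: str) -> ConceptEntry | None:
        phrase = phrase.lower()
        for entry in self.entries:
            if phrase in entry.synonyms:
                return entry
        return None


def _split_synonyms(raw: str) -> list[str]:
    if not raw or not raw.strip():
        return []
    return [p.strip().lower() for p in raw.split("|") if p.strip()]


def load_lexicon(path: str | Path) -> Lexicon:
    """Load a mapping file (CSV, pipe-separated ``synonyms`` column).

    Raises
    ------
    LexiconFormatError
        if a required column is missing.
    LexiconValidationError
        if a row carries a malformed CUI or concept binding.
    SynonymConflictError
        if one phrase is listed under two entries.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        for col in REQUIRED_COLUMNS:
            if col not in header:
                raise LexiconFormatError(f"mapping file {path} is missing column {col!r}")
        entries = []
        for i, row in enumerate(reader):
            cui = (row["cui"] or "").strip()
            if not CUI_PATTERN.match(cui):
                raise LexiconValidationError(
                    f"row {i + 2} of {path}: malformed CUI {cui!r}"
                )
            try:
                concept_index = int(row["concept_index"])
            except (TypeError, ValueError) as exc:
                raise LexiconValidationError(
                    f"row {i + 2} of {path}: concept_index {row['concept_index']!r}"
                ) from exc
            entries.append(
                ConceptEntry(
                    concept_index=concept_index,
                    cui=cui,
                    preferred_label=(row["preferred_label"] or "").strip(),
                    synonyms=frozenset(_split_synonyms(row["synonyms"] or "")),
                )
            )
    return Lexicon(entries=tuple(entries), provenance=f"loaded from {path.name}")


def default_lexicon() -> Lexicon:
    """The bundled three-concept dictionary."""
    with resources.as_file(
        resources.files("radconcept.data").joinpath("default_lexicon.csv")
    ) as p:
        lex = load_lexicon(p)
    return replace(lex, provenance="bundled default")


def save_lexicon(lex: Lexicon, path: str | Path) -> Path:
    """Write ``lex`` back to the CSV mapping dialect (round-trips with load)."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(REQUIRED_COLUMNS)
        for entry in lex.entries:
            writer.writerow(
                [
                    entry.preferred_label,
                    entry.cui,
                    entry.concept_index,
                    "|".join(sorted(entry.synonyms)),
                ]
            )
    return path


def add_synonyms(lex: Lexicon, additions: Mapping[str, str]) -> Lexicon:
    """Return a new lexicon with each phrase added under its preferred label.

    ``additions`` maps surface phrase -> preferred label.  Adding a phrase an
    entry already owns is a no-op (set semantics); adding a phrase owned by a
    *different* entry raises :class:`SynonymConflictError`; an unknown label
    raises :class:`UnknownLabelError`.  The input lexicon is not modified.
    """
    staged: dict[str, set[str]] = {e.preferred_label: set() for e in lex.entries}
    for phrase, label in additions.items():
        target = lex.entry_for_label(label)  # raises UnknownLabelError
        phrase_lc = phrase.lower()
        owner = lex.owner_of(phrase_lc)
        if owner is not None and owner.preferred_label != target.preferred_label:
            raise SynonymConflictError(phrase_lc, owner.preferred_label, target.preferred_label)
        staged[label].add(phrase_lc)
    new_entries = tuple(
        e.with_synonyms(staged[e.preferred_label]) if staged[e.preferred_label] else e
        for e in lex.entries
    )
    note = f"{lex.provenance}; +{sum(len(v) for v in staged.values())} synonyms"
    return Lexicon(entries=new_entries, provenance=note)


def _ngrams(tokens: Sequence[str], sizes: Iterable[int]) -> Iterable[str]:
    for n in sizes:
        for i in range(len(tokens) - n + 1):
            yield " ".join(tokens[i : i + n])


def propose_aberrant_terms(
    corpus: Iterable[str],
    lex: Lexicon,
    anchors: Iterable[str] = DEFAULT_ANCHORS,
    ngram_sizes: Iterable[int] = (1, 2, 3),
) -> list[str]:
    """Mine candidate phrases for *human* review; never mutates the lexicon.

    Returns corpus n-grams containing at least one anchor token that are not
    already lexicon synonyms, ranked by corpus frequency descending with ties
    broken lexicographically.
    """
    anchor_set = {a.lower() for a in anchors}
    if not anchor_set:
        raise ValueError("anchors must be non-empty")
    sizes = tuple(ngram_sizes)
    known = lex.all_synonyms()
    counts: Counter[str] = Counter()
    for text in corpus:
        tokens = text.lower().split()
        for gram in _ngrams(tokens, sizes):
            if gram in known:
                continue
            if anchor_set.intersection(gram.split()):
                counts[gram] += 1
    return sorted(counts, key=lambda g: (-counts[g], g))
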