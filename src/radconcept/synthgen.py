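"""Labeled synthetic radiology reports for exercising the whole pipeline.

Reports emulate a thoracic-oncology repository: findings + impression
sections, identifiers, a reporting-doctor signature, CT / PET/CT modalities
and a calendar date.  Positives embed a disease-identification phrase drawn
from the concept inventory (with punctuation-attached, abbreviated and
misspelled *variant* forms at a configurable rate); label-0 reports describe
other thoracic cancers or benign findings and contain no dictionary phrase;
*hard negatives* are lung-cancer reports phrased in ways the rule engine is
documented to miss ("ca left lung"), carrying ``gold_concept=1`` but
``rule_expected=0``.

Every report is deterministic given the corpus seed.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from datetime import date, timedelta

from .corpus_io import ReportRecord
from .errors import ParameterError

# -- phrase inventories ------------------------------------------------------

BASE_PHRASES = {
    1: ["ca lung", "carcinoma lung", "lung carcinoma", "lung ca"],
    2: ["nsclc", "non small cell lung carcinoma"],
    3: ["sclc", "small cell lung carcinoma"],
}

VARIANT_PHRASES = {
    1: [
        "ca. lung",
        "adenoca lung",
        "adenocarcinoma lung",
        "lung adenocarcinoma",
        "sqaumous cell ca lung",
        "sqaumous cell carcinoma lung",
    ],
    2: [
        "nsclc,",
        "nsclc;",
        "nsclc.",
        "nsclc)",
        "non small cell lung carcinoma.",
        "non small cell lung ca",
        "non small cell lung ca.",
    ],
    3: ["small cell lung ca"],
}

#: Interrupted / lobar phrasings the rule engine is documented to miss.
HARD_NEGATIVE_PHRASES = [
    "this is a case of ca left lung",
    "soft tissue mass in left upper lobe",
    "solitary cavitary lesion in left lung",
]

#: Expanded / out-of-dictionary phrasings used by the dialect-shifted corpus.
DIALECT_PHRASES = {
    1: ["lung cancer", "carcinoma of the lung", "bronchogenic carcinoma", "primary lung malignancy"],
    2: ["non-small cell cancer of the lung", "nonsmall cell lung cancer"],
    3: ["small cell cancer of the lung", "oat cell carcinoma"],
}

NEGATIVE_SENTENCES = [
    "known carcinoma of the esophagus with wall thickening in the mid third.",
    "circumferential gastric wall thickening consistent with stomach carcinoma.",
    "large heterogeneous soft tissue sarcoma involving the left thigh.",
    "esophageal growth noted with proximal dilatation.",
    "post operative status for gastric malignancy with no residual disease.",
    "no significant mediastinal lymphadenopathy.",
    "both lungs are clear with no focal lesion.",
    "mild pleural thickening on the right side, likely sequelae of old infection.",
    "liver, spleen and adrenals appear normal.",
    "no metabolically active disease elsewhere in the surveyed regions.",
]

FINDINGS_FILLER = [
    "the study was acquired from skull base to mid thigh.",
    "there is mild cardiomegaly without pericardial effusion.",
    "few subcentimetric pretracheal nodes are seen.",
    "degenerative changes are noted in the dorsal spine.",
    "trachea and main bronchi are patent.",
    "visualized bowel loops are unremarkable.",
    "no obvious bony lytic or sclerotic lesion.",
]

POSITIVE_TEMPLATES = [
    "known case of {phrase} on treatment.",
    "features are consistent with {phrase} with nodal disease.",
    "biopsy proven {phrase} for staging evaluation.",
    "follow up case of {phrase} showing partial response.",
    "appearances suggest {phrase} with mediastinal extension.",
]

EXTERNAL_POSITIVE_TEMPLATES = [
    "impression: findings compatible with {phrase}.",
    "there is a spiculated mass reflecting the patient's known {phrase}.",
    "stable appearance of {phrase} compared with the prior examination.",
    "interval progression of {phrase} with new nodal involvement.",
]

EXTERNAL_NEGATIVE_SENTENCES = [
    "indication: dysphagia with known esophageal carcinoma.",
    "the previously described gastric neoplasm is again demonstrated.",
    "no acute cardiopulmonary process.",
    "the lungs are grossly clear bilaterally.",
    "there is no pleural effusion or pneumothorax.",
    "soft tissue sarcoma of the chest wall, unchanged.",
    "the osseous structures are unremarkable.",
]

DOCTOR_POOL = ["Dr. A Sharma", "Dr. P Gupta", "Dr. R Iyer", "Dr. S Rao"]

_FIRST = ["Anil", "Sunita", "Rahul", "Priya", "Vikram", "Meena", "Arjun", "Kavita"]
_LAST = ["Kumar", "Desai", "Patil", "Nair", "Singh", "Joshi", "Reddy", "Menon"]


@dataclass
class SyntheticCorpusSpec:
    """Parameters governing one synthetic corpus draw."""

    n_reports: int = 100
    class_mix: tuple[float, float, float, float] = (0.6, 0.3, 0.07, 0.03)
    variant_rate: float = 0.3
    hard_negative_rate: float = 0.0
    modality_mix: dict = field(default_factory=lambda: {"CT": 0.6, "PET/CT": 0.4})
    year_range: tuple[int, int] = (2014, 2016)
    doctor_names: list = field(default_factory=lambda: list(DOCTOR_POOL))
    dmg: str = "TDMG"
    seed: int = 0

    def validate(self) -> None:
        if self.n_reports < 0:
            raise ParameterError("n_reports must be nonnegative")
        if abs(sum(self.class_mix) - 1.0) > 1e-9:
            raise ParameterError(f"class mix must sum to 1, got {sum(self.class_mix)}")
        for rate in (self.variant_rate, self.hard_negative_rate):
            if not 0.0 <= rate <= 1.0:
                raise ParameterError("rates must lie in [0, 1]")


def exact_class_counts(n: int, mix: tuple[float, ...]) -> list[int]:
    """Largest-remainder apportionment so counts sum to ``n`` exactly."""
    raw = [n * p for p in mix]
    counts = [int(x) for x in raw]
    remainder = n - sum(counts)
    order = sorted(range(len(mix)), key=lambda i: raw[i] - counts[i], reverse=True)
    for i in order[:remainder]:
        counts[i] += 1
    return counts


def _random_date(rng: random.Random, year_range: tuple[int, int]) -> date:
    start = date(year_range[0], 1, 1)
    end = date(year_range[1], 12, 31)
    return start + timedelta(days=rng.randrange((end - start).days + 1))


def _pick_modality(rng: random.Random, mix: dict) -> str:
    r = rng.random()
    acc = 0.0
    for modality, p in mix.items():
        acc += p
        if r <= acc:
            return modality
    return list(mix)[-1]


def _positive_phrase(rng: random.Random, concept: int, variant_rate: float) -> str:
    if VARIANT_PHRASES[concept] and rng.random() < variant_rate:
        return rng.choice(VARIANT_PHRASES[concept])
    return rng.choice(BASE_PHRASES[concept])


def _negative_body(rng: random.Random, sentences: list[str]) -> tuple[str, str]:
    findings = " ".join(rng.sample(sentences, k=rng.randint(2, 4)))
    impression = rng.choice(sentences)
    return findings, impression


def _positive_body(
    rng: random.Random, phrase: str, templates: list[str]
) -> tuple[str, str]:
    findings = " ".join(rng.sample(FINDINGS_FILLER, k=rng.randint(2, 3)))
    impression = rng.choice(templates).format(phrase=phrase)
    if rng.random() < 0.3:  # sometimes the phrase sits in the findings section
        findings, impression = (
            f"{impression} {findings}",
            "please correlate clinically.",
        )
    return findings, impression


def _make_record(
    rng: random.Random,
    i: int,
    spec: SyntheticCorpusSpec,
    gold: int,
    rule_expected: int,
    findings: str,
    impression: str,
) -> ReportRecord:
    doctor = rng.choice(spec.doctor_names)
    return ReportRecord(
        case_number=f"TMH-{spec.year_range[0]}-{i:05d}",
        gender=rng.choice(["Male", "Female"]),
        name=f"{rng.choice(_FIRST)} {rng.choice(_LAST)}",
        modality=_pick_modality(rng, spec.modality_mix),
        report_date=_random_date(rng, spec.year_range),
        findings=findings.capitalize(),
        impression=f"{impression.capitalize()} {doctor}",
        referred_by=rng.choice(spec.doctor_names),
        dmg=spec.dmg,
        gold_concept=gold,
        rule_expected=rule_expected,
    )


def _assemble(
    spec: SyntheticCorpusSpec,
    positive_templates: list[str],
    negative_sentences: list[str],
    dialect_rate: float,
) -> list[ReportRecord]:
    spec.validate()
    rng = random.Random(spec.seed)
    counts = exact_class_counts(spec.n_reports, spec.class_mix)
    labels = [lab for lab, c in enumerate(counts) for _ in range(c)]
    rng.shuffle(labels)

    n_hard = round(spec.hard_negative_rate * counts[1])
    hard_slots = set()
    concept1_positions = [j for j, lab in enumerate(labels) if lab == 1]
    if n_hard and concept1_positions:
        hard_slots = set(rng.sample(concept1_positions, min(n_hard, len(concept1_positions))))

    records: list[ReportRecord] = []
    for i, gold in enumerate(labels):
        if gold == 0:
            findings, impression = _negative_body(rng, negative_sentences)
            rec = _make_record(rng, i, spec, gold, 0, findings, impression)
        elif i in hard_slots:
            findings = " ".join(rng.sample(FINDINGS_FILLER, k=2))
            impression = rng.choice(HARD_NEGATIVE_PHRASES) + "."
            rec = _make_record(rng, i, spec, gold, 0, findings, impression)
        else:
            if dialect_rate > 0 and rng.random() < dialect_rate:
                phrase = rng.choice(DIALECT_PHRASES[gold])
                expected = 0  # out-of-dictionary phrasing: rules will miss it
            else:
                phrase = _positive_phrase(rng, gold, spec.variant_rate)
                expected = gold
            findings, impression = _positive_body(rng, phrase, positive_templates)
            rec = _make_record(rng, i, spec, gold, expected, findings, impression)
        records.append(rec)
    return records


def generate_corpus(spec: SyntheticCorpusSpec) -> list[ReportRecord]:
    """In-dialect corpus emulating the internal report repository."""
    return _assemble(spec, POSITIVE_TEMPLATES, NEGATIVE_SENTENCES, dialect_rate=0.0)


def generate_external_style(spec: SyntheticCorpusSpec, dialect_rate: float = 0.4) -> list[ReportRecord]:
    """Dialect-shifted corpus standing in for an external validation set.

    Same label semantics, different boilerplate, and a fraction of positives
    phrased in expanded out-of-dictionary forms so dictionary-based
    recognition degrades — the generalization-drop phenomenon.
    """
    if not 0.0 <= dialect_rate <= 1.0:
        raise ParameterError("dialect_rate must lie in [0, 1]")
    return _assemble(
        spec, EXTERNAL_POSITIVE_TEMPLATES, EXTERNAL_NEGATIVE_SENTENCES, dialect_rate=dialect_rate
    )
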