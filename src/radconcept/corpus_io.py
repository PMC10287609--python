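"""Report repository I/O, anonymization, cleaning, selection and pre-processing.

The repository format is a CSV with one report per row and columns
``case_number, gender, name, modality, report_date, findings, impression,
referred_by`` plus optional ``dmg``, ``gold_concept`` and ``rule_expected``
columns (the last two are emitted by the synthetic generator only).

Stage order matters and is enforced: ``read_reports`` -> ``anonymize`` ->
``clean_records`` -> ``select_reports`` -> ``preprocess``.  ``preprocess``
rejects text containing uppercase characters as a signal that cleaning was
skipped.
"""

from __future__ import annotations

import random
import re
from dataclasses import dataclass, field, replace
from datetime import date, datetime
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .errors import CorpusFormatError, PipelineOrderError

REPOSITORY_COLUMNS = (
    "case_number",
    "gender",
    "name",
    "modality",
    "report_date",
    "findings",
    "impression",
    "referred_by",
)

OPTIONAL_COLUMNS = ("dmg", "gold_concept", "rule_expected")

DATE_FORMAT = "%Y-%m-%d"

#: Tokens that stop-word removal must never delete: stripping any of these
#: would destroy a dictionary phrase such as "non small cell lung carcinoma".
DEFAULT_KEEP_TOKENS = frozenset({"non", "no", "not", "small", "cell"})

#: Minimal English stop-word list; the report corpus is boilerplate-heavy so a
#: short list suffices and keeps behavior auditable.
DEFAULT_STOPWORDS = frozenset(
    """a an the and or of in on at to for with is are was were be been this
    that these those it its as by from there has have had which""".split()
)

_SPECIAL_CHARS = re.compile(r"[^a-z0-9\s]")
_WS = re.compile(r"\s+")


@dataclass
class ReportRecord:
    """One radiology report as it moves through the pipeline."""

    case_number: str | None = None
    gender: str | None = None
    name: str | None = None
    pseudo_id: str | None = None
    modality: str = ""
    report_date: date | None = None
    findings: str = ""
    impression: str = ""
    referred_by: str = ""
    dmg: str = ""
    gold_concept: int | None = None
    rule_expected: int | None = None
    unified_text: str | None = None
    blank: bool = False
    cleaned: bool = False

    @property
    def key(self) -> str:
        return self.pseudo_id or self.case_number or ""


@dataclass
class AnonymizationLookup:
    """pseudo_id -> identifying fields, persisted separately from the corpus."""

    rows: list[dict] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=["pseudo_id", "case_number", "gender", "name"])

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        self.to_frame().to_csv(path, index=False)
        return path


@dataclass
class ReadResult:
    records: list[ReportRecord]
    errors: list[str] = field(default_factory=list)


def _parse_date(raw, row_index: int, errors: list[str]) -> date | None:
    if raw is None or (isinstance(raw, float) and pd.isna(raw)) or str(raw).strip() == "":
        errors.append(f"row {row_index}: missing report_date")
        return None
    try:
        return datetime.strptime(str(raw).strip(), DATE_FORMAT).date()
    except ValueError:
        errors.append(f"row {row_index}: unparseable report_date {raw!r}")
        return None


def read_reports(path: str | Path) -> ReadResult:
    """Read a report repository CSV.

    Missing required columns raise :class:`CorpusFormatError`.  Rows with
    unparseable dates are still returned (date set to None) alongside a
    row-indexed error report.  Rows whose findings and impression are both
    blank are flagged ``blank`` and excluded later by ``select_reports``.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in REPOSITORY_COLUMNS if c not in df.columns]
    if missing:
        raise CorpusFormatError(f"{path} is missing columns: {missing}")
    errors: list[str] = []
    records: list[ReportRecord] = []
    for i, row in enumerate(df.to_dict(orient="records")):
        findings = row["findings"]
        impression = row["impression"]
        rec = ReportRecord(
            case_number=row["case_number"] or None,
            gender=row["gender"] or None,
            name=row["name"] or None,
            pseudo_id=row.get("pseudo_id") or None,
            modality=row["modality"],
            report_date=_parse_date(row["report_date"], i, errors),
            findings=findings,
            impression=impression,
            referred_by=row["referred_by"],
            dmg=row.get("dmg", ""),
            gold_concept=int(row["gold_concept"]) if row.get("gold_concept", "") != "" else None,
            rule_expected=int(row["rule_expected"]) if row.get("rule_expected", "") != "" else None,
            blank=(findings.strip() == "" and impression.strip() == ""),
        )
        records.append(rec)
    return ReadResult(records=records, errors=errors)


def write_reports(records: Sequence[ReportRecord], path: str | Path) -> Path:
    """Serialize records to the repository CSV dialect (UTF-8, header row)."""
    path = Path(path)
    rows = []
    for r in records:
        rows.append(
            {
                "case_number": r.case_number or "",
                "gender": r.gender or "",
                "name": r.name or "",
                "pseudo_id": r.pseudo_id or "",
                "modality": r.modality,
                "report_date": r.report_date.strftime(DATE_FORMAT) if r.report_date else "",
                "findings": r.findings,
                "impression": r.impression,
                "referred_by": r.referred_by,
                "dmg": r.dmg,
                "gold_concept": "" if r.gold_concept is None else r.gold_concept,
                "rule_expected": "" if r.rule_expected is None else r.rule_expected,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False, encoding="utf-8")
    return path


def anonymize(
    records: Sequence[ReportRecord], seed: int = 0
) -> tuple[list[ReportRecord], AnonymizationLookup]:
    """Strip identifier fields, returning anonymized copies plus the lookup.

    pseudo_id assignment is deterministic given ``seed``.  Duplicate case
    numbers are mapped to distinct pseudo_ids (each row is its own patient as
    far as the corpus is concerned).
    """
    rng = random.Random(seed)
    suffixes = rng.sample(range(10**6), len(records))
    lookup = AnonymizationLookup()
    out: list[ReportRecord] = []
    for rec, suffix in zip(records, suffixes):
        pseudo = f"P{suffix:06d}"
        lookup.rows.append(
            {
                "pseudo_id": pseudo,
                "case_number": rec.case_number or "",
                "gender": rec.gender or "",
                "name": rec.name or "",
            }
        )
        out.append(replace(rec, case_number=None, gender=None, name=None, pseudo_id=pseudo))
    return out, lookup


def clean(text: str, doctor_names: Iterable[str] = ()) -> str:
    """Lowercase ``text`` and excise every configured doctor-name string.

    Idempotent: cleaning already-clean text is a no-op.
    """
    out = text.lower()
    for name in doctor_names:
        out = out.replace(name.lower(), "")
    return out


def clean_records(
    records: Sequence[ReportRecord], doctor_names: Iterable[str] = ()
) -> list[ReportRecord]:
    """Apply :func:`clean` to the findings and impression of every record."""
    names = list(doctor_names)
    out = []
    for rec in records:
        findings = clean(rec.findings, names)
        impression = clean(rec.impression, names)
        out.append(
            replace(
                rec,
                findings=findings,
                impression=impression,
                referred_by=clean(rec.referred_by, names),
                blank=(findings.strip() == "" and impression.strip() == ""),
                cleaned=True,
            )
        )
    return out


@dataclass
class SelectionResult:
    records: list[ReportRecord]
    excluded: dict[str, int] = field(default_factory=dict)


def select_reports(
    records: Sequence[ReportRecord],
    modalities: Iterable[str] | None = ("CT", "PET/CT"),
    year_range: tuple[int, int] | None = None,
    dmg_tag: str | None = None,
) -> SelectionResult:
    """Filter by modality / calendar-year range / disease group and unify text.

    Each selected record carries ``unified_text = findings + " " + impression``.
    Blank records (both sections empty) are always excluded.  Per-filter
    exclusion counts are returned so record-count conservation can be audited.
    """
    modality_set = set(modalities) if modalities is not None else None
    excluded = {"blank": 0, "modality": 0, "year": 0, "dmg": 0}
    kept: list[ReportRecord] = []
    for rec in records:
        if rec.blank or (rec.findings.strip() == "" and rec.impression.strip() == ""):
            excluded["blank"] += 1
            continue
        if modality_set is not None and rec.modality not in modality_set:
            excluded["modality"] += 1
            continue
        if year_range is not None:
            if rec.report_date is None or not (
                year_range[0] <= rec.report_date.year <= year_range[1]
            ):
                excluded["year"] += 1
                continue
        if dmg_tag is not None and rec.dmg != dmg_tag:
            excluded["dmg"] += 1
            continue
        unified = f"{rec.findings} {rec.impression}"
        kept.append(replace(rec, unified_text=unified))
    return SelectionResult(records=kept, excluded=excluded)


def preprocess(
    text: str,
    stopwords: Iterable[str] = DEFAULT_STOPWORDS,
    keep_tokens: Iterable[str] = DEFAULT_KEEP_TOKENS,
) -> tuple[list[str], str]:
    """Tokenize, remove stop words, remove special characters — in that order.

    Tokens listed in ``keep_tokens`` survive stop-word removal even when they
    appear in ``stopwords``.  Returns ``(tokens, normalized_text)`` where the
    normalized text is the whitespace-rejoined token sequence.

    Raises :class:`PipelineOrderError` on uppercase input (cleaning skipped).
    """
    if any(c.isupper() for c in text):
        raise PipelineOrderError("preprocess expects cleaned (lowercase) text")
    stop = set(stopwords) - set(keep_tokens)
    tokens = text.split()
    tokens = [t for t in tokens if t not in stop]
    tokens = [_SPECIAL_CHARS.sub("", t) for t in tokens]
    tokens = [t for t in tokens if t]
    return tokens, " ".join(tokens)


def normalize_whitespace(text: str) -> str:
    """Collapse runs of whitespace; the rule NER runs on this form by default."""
    return _WS.sub(" ", text).strip()
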