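"""End-to-end orchestration: ingest -> anonymize -> clean -> select ->
preprocess -> model -> evaluate, driven by one declarative config.

Every run writes a ``manifest.json`` naming the config hash and seeds so any
artifact can be traced to the exact configuration that produced it.  Rule and
ML stages are fully deterministic given the recorded seeds.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import pandas as pd
import yaml

from . import corpus_io, evaluation, lexicon, ner_rules
from .errors import RadconceptError

log = logging.getLogger("radconcept")


@dataclass
class PipelineConfig:
    reports_path: str = ""
    lexicon_path: str | None = None  # None -> bundled default
    output_dir: str = "run_output"
    doctor_names: list = field(default_factory=list)
    modalities: list = field(default_factory=lambda: ["CT", "PET/CT"])
    year_range: list | None = None
    dmg_tag: str | None = None
    stopwords: list | None = None
    keep_tokens: list | None = None
    ner_input: str = "cleaned"  # "cleaned" or "preprocessed"
    enable_generative: bool = True
    run_ner: bool = True
    run_evaluation: bool = True
    rounding: int = 2
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {k: v for k, v in raw.items() if k in cls.__dataclass_fields__}
        unknown = set(raw) - set(known)
        if unknown:
            raise RadconceptError(f"unknown config keys: {sorted(unknown)}")
        return cls(**known)

    def hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class RunArtifacts:
    output_dir: Path
    manifest: dict
    results_table: pd.DataFrame | None = None
    metrics_report: dict | None = None


def _write_manifest(outdir: Path, cfg: PipelineConfig, extra: dict) -> dict:
    manifest = {
        "config_hash": cfg.hash(),
        "seed": cfg.seed,
        "config": asdict(cfg),
        "created": time.strftime("%Y-%m-%dT%H:%M:%S"),
        **extra,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def run_pipeline(cfg: PipelineConfig) -> RunArtifacts:
    """Execute the configured stages in order; see module docstring."""
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage = "ingest"
    try:
        read = corpus_io.read_reports(cfg.reports_path)
        n_in = len(read.records)

        stage = "anonymize"
        anon, lookup = corpus_io.anonymize(read.records, seed=cfg.seed)
        lookup.save(outdir / "anonymization_lookup.csv")

        stage = "clean"
        cleaned = corpus_io.clean_records(anon, cfg.doctor_names)
        corpus_io.write_reports(cleaned, outdir / "anonymized_corpus.csv")

        stage = "select"
        selection = corpus_io.select_reports(
            cleaned,
            modalities=cfg.modalities,
            year_range=tuple(cfg.year_range) if cfg.year_range else None,
            dmg_tag=cfg.dmg_tag,
        )
        n_selected = len(selection.records)
        n_excluded = sum(selection.excluded.values())
        assert n_in == n_selected + n_excluded, "record-count conservation violated"

        stage = "preprocess"
        records = []
        stop = cfg.stopwords if cfg.stopwords is not None else corpus_io.DEFAULT_STOPWORDS
        keep = cfg.keep_tokens if cfg.keep_tokens is not None else corpus_io.DEFAULT_KEEP_TOKENS
        for rec in selection.records:
            _, normalized = corpus_io.preprocess(rec.unified_text, stop, keep)
            if cfg.ner_input == "preprocessed":
                rec = replace(rec, unified_text=normalized)
            else:
                rec = replace(rec, unified_text=corpus_io.normalize_whitespace(rec.unified_text))
            records.append(rec)

        results_table = None
        metrics_report = None
        if cfg.run_ner:
            stage = "ner"
            lex = (
                lexicon.load_lexicon(cfg.lexicon_path)
                if cfg.lexicon_path
                else lexicon.default_lexicon()
            )
            pats = ner_rules.compile_patterns(lex, enable_generative=cfg.enable_generative)
            results_table = ner_rules.classify_corpus(records, pats)
            results_table.to_csv(outdir / "ner_results.csv", index=False)

            if cfg.run_evaluation and any(r.gold_concept is not None for r in records):
                stage = "evaluate"
                gold = [r.gold_concept or 0 for r in records]
                pred = results_table["concept_label"].tolist()
                binary_true = [int(g > 0) for g in gold]
                binary_pred = results_table["binary_label"].tolist()
                overall = evaluation.metrics(
                    evaluation.confusion(binary_true, binary_pred), rounding=cfg.rounding
                )
                per_concept = {
                    lab: evaluation.metrics(c, rounding=cfg.rounding).as_dict()
                    for lab, c in evaluation.per_concept_confusion(gold, pred).items()
                }
                metrics_report = {
                    "overall": overall.as_dict(),
                    "per_concept": per_concept,
                }
                (outdir / "metrics_report.json").write_text(json.dumps(metrics_report, indent=2))

        manifest = _write_manifest(
            outdir,
            cfg,
            {
                "reports_in": n_in,
                "reports_selected": n_selected,
                "reports_excluded": selection.excluded,
            },
        )
        return RunArtifacts(
            output_dir=outdir,
            manifest=manifest,
            results_table=results_table,
            metrics_report=metrics_report,
        )
    except Exception:
        (outdir / "FAILED").write_text(f"stage: {stage}\n")
        log.exception("pipeline failed at stage %s", stage)
        raise
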