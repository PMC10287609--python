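# radconcept

Clinical concept-based classification of free-text radiology reports for lung
carcinoma. The package implements an end-to-end pipeline:

- **lexicon** — a customizable concept dictionary mapping surface phrases
  (including colloquial, abbreviated and misspelled forms) to three lung-cancer
  concepts with fixed UMLS CUIs (1 ↔ C0684249 lung carcinoma, 2 ↔ C0007131
  non-small cell, 3 ↔ C0149925 small cell), plus frequency-ranked candidate
  mining of "aberrant" terms for human review.
- **corpus_io** — report-repository CSV ingest, anonymization with a lookup
  table, cleaning (lowercasing, doctor-name removal), modality/year/disease-group
  selection with findings+impression unification, and ordered pre-processing
  (tokenization → stop-word removal → special-character removal).
- **ner_rules** — the rule-based concept recognizer: every synonym compiled to
  a boundary-aware pattern (preceded by start/whitespace, followed by
  end/whitespace/`. , ; )`), optional generative histology+site templates
  (`adenoca lung`, `lung adenocarcinoma`, …), earliest-match report labeling,
  and an independent brute-force scanner used as a test oracle.
- **ml_baseline** — tf-idf + gradient-boosted trees with nested stratified
  5-fold cross-validation (inner-loop grid search, repeated trials, leak-free
  per-fold vectorization).
- **dl_baseline** — two bidirectional-LSTM classifiers written directly in
  NumPy (no DL framework): `simple` (5 layers) and `dropout` (13 layers
  including dropout), trained with Adam/BPTT; gradients are verified against
  finite differences in the test suite.
- **evaluation** — confusion counts, sensitivity/PPV/NPV/F1/accuracy with
  explicit undefined-denominator handling and half-up rounding, 20-trial
  bootstrap with `mean(SD)` formatting, midrank ROC/AUC.
- **synthgen** — deterministic labeled synthetic corpora (no clinical data
  needed): clean positives, punctuation/misspelling variants, other-thoracic
  cancer negatives, interrupted-phrase hard negatives, and a dialect-shifted
  "external" corpus for generalization-drop experiments.
- **pipeline** — declarative YAML-driven orchestration with config-hash
  manifests and per-filter record-count conservation.

## CLI

All stages are subcommands of one entry point:

```bash
radconcept simulate --n 500 --seed 1 --out data/sim           # synthetic corpus
radconcept ner --reports data/sim/reports.csv --out ner.csv   # rule-based NER
radconcept train-ml --reports data/sim/reports.csv --trials 5 --out out/ml
radconcept train-dl --arch dropout --reports data/sim/reports.csv --out out/dl
radconcept evaluate --truth data/sim/gold_labels.csv --predictions ner.csv \
    --bootstrap-trials 20 --out metrics.json
radconcept run-all --config pipeline.yaml                     # full pipeline
```

A pipeline config is plain YAML; unknown keys are rejected:

```yaml
reports_path: data/sim/reports.csv
output_dir: run_output
doctor_names: ["dr. a sharma", "dr. p gupta"]
modalities: [CT, PET/CT]
year_range: [2014, 2016]
ner_input: cleaned        # or "preprocessed"
enable_generative: true
seed: 0
```

## Lexicon mapping files

CSV with columns `preferred_label, cui, concept_index, synonyms`, where
`synonyms` is pipe-separated (e.g. `"ca lung|lung carcinoma|nsclc,"`).
The bundled default (`radconcept/data/default_lexicon.csv`) covers the three
concepts including punctuation-attached variants and the corpus misspelling
`sqaumous cell ca lung`. `add_synonyms` extends entries immutably;
`propose_aberrant_terms` mines candidate phrases but never auto-adds them —
acceptance stays a human step.

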