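"""tf-idf + gradient-boosted-tree document classifier with nested CV.

The binary task is "report contains any of the three concepts" vs "none".
Features are tf-idf weights (smoothed idf, L2-normalized rows,
unigrams+bigrams, min document frequency 2 — all configurable).  Model
selection and evaluation use nested stratified 5-fold cross-validation
repeated for a configurable number of trials: each trial reshuffles the outer
split; grid search runs in the inner loop on outer-train folds only; the
outer-test fold never touches hyperparameter selection.  After all trials the
winning configuration is refit on the full internal set.

The boosted-tree learner is scikit-learn's ``GradientBoostingClassifier``
(same additive-tree family as XGBoost, which is not available offline).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Sequence

import numpy as np
from sklearn.ensemble import GradientBoostingClassifier
from sklearn.feature_extraction.text import TfidfVectorizer
from sklearn.model_selection import StratifiedKFold

from .errors import ModelStateError, StratificationError
from .evaluation import MetricSet, confusion, metrics

DEFAULT_GRID = {
    "max_depth": [3, 6],
    "learning_rate": [0.1, 0.3],
    "n_estimators": [50, 200],
}

DEFAULT_TFIDF = {"ngram_range": (1, 2), "min_df": 2, "sublinear_tf": False}


@dataclass
class TfidfModel:
    """Thin contract wrapper over a fitted ``TfidfVectorizer``."""

    vectorizer: TfidfVectorizer

    @property
    def vocabulary(self) -> dict[str, int]:
        return self.vectorizer.vocabulary_

    @property
    def idf(self) -> np.ndarray:
        return self.vectorizer.idf_

    @property
    def ngram_range(self) -> tuple[int, int]:
        return self.vectorizer.ngram_range

    @property
    def min_df(self):
        return self.vectorizer.min_df


def fit_tfidf(texts: Sequence[str], **params) -> TfidfModel:
    """Fit the tf-idf vocabulary and idf weights on ``texts``."""
    if len(texts) == 0:
        raise ValueError("cannot fit tf-idf on an empty corpus")
    opts = {**DEFAULT_TFIDF, **params}
    if len(texts) < opts.get("min_df", 1):
        opts["min_df"] = 1  # degenerate tiny corpus
    vec = TfidfVectorizer(**opts)
    vec.fit(texts)
    return TfidfModel(vectorizer=vec)


def transform(texts: Sequence[str], model: TfidfModel):
    """Document-term weight matrix (sparse CSR); unseen terms contribute nothing."""
    return model.vectorizer.transform(texts)


def _grid_points(grid: dict) -> list[dict]:
    keys = sorted(grid)
    return [dict(zip(keys, vals)) for vals in product(*(grid[k] for k in keys))]


@dataclass
class NestedCVResult:
    per_trial_fold_metrics: list[list[MetricSet]]
    chosen_params: list[dict]
    final_params: dict
    final_model: GradientBoostingClassifier | None
    final_vectorizer: TfidfModel | None
    seed: int
    n_outer: int
    n_trials: int
    #: per trial, per outer fold: the vocabulary the fold's model was trained
    #: on (empty when a shared global vectorizer was requested)
    fold_vocabularies: list[list[frozenset]] = field(default_factory=list)

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.fold_accuracies))

    @property
    def sd_accuracy(self) -> float:
        vals = self.fold_accuracies
        return float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0

    @property
    def fold_accuracies(self) -> list[float]:
        return [
            m.accuracy
            for trial in self.per_trial_fold_metrics
            for m in trial
            if m.accuracy is not None
        ]

    def trial_mean_accuracies(self) -> list[float]:
        return [
            float(np.mean([m.accuracy for m in trial if m.accuracy is not None]))
            for trial in self.per_trial_fold_metrics
        ]


def _check_stratifiable(y: np.ndarray, k: int) -> None:
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise StratificationError("need both classes present")
    small = counts.min()
    if small < k:
        raise StratificationError(
            f"smallest class has {small} members, cannot stratify into {k} folds"
        )


def _inner_select(
    texts: np.ndarray,
    y: np.ndarray,
    grid_list: list[dict],
    n_inner: int,
    tfidf_params: dict,
    rng_seed: int,
    vectorize_per_fold: bool,
    shared_vec: TfidfModel | None,
) -> dict:
    if len(grid_list) == 1:
        return grid_list[0]
    inner = StratifiedKFold(n_splits=n_inner, shuffle=True, random_state=rng_seed)
    best_score, best_params = -np.inf, grid_list[0]
    for params in grid_list:
        scores = []
        for tr, te in inner.split(texts, y):
            if vectorize_per_fold:
                vec = fit_tfidf(texts[tr], **tfidf_params)
            else:
                vec = shared_vec
            Xtr = transform(texts[tr], vec)
            Xte = transform(texts[te], vec)
            clf = GradientBoostingClassifier(random_state=rng_seed, **params)
            clf.fit(Xtr, y[tr])
            scores.append(float(np.mean(clf.predict(Xte) == y[te])))
        score = float(np.mean(scores))
        if score > best_score:
            best_score, best_params = score, params
    return best_params


def nested_cv_train(
    texts: Sequence[str],
    y: Sequence[int],
    grid: dict | None = None,
    n_outer: int = 5,
    n_trials: int = 20,
    n_inner: int = 3,
    seed: int = 0,
    tfidf_params: dict | None = None,
    vectorize_per_fold: bool = True,
) -> NestedCVResult:
    """Nested stratified cross-validation with repeated trials.

    ``vectorize_per_fold=True`` (default) refits the tf-idf vocabulary on each
    outer-train partition, so no test-fold vocabulary can leak into training;
    ``False`` selects the global-vectorizer variant for comparison.
    """
    texts = np.asarray(texts, dtype=object)
    y = np.asarray(y, dtype=int)
    grid_list = _grid_points(grid or DEFAULT_GRID)
    tfidf_params = tfidf_params or {}
    _check_stratifiable(y, n_outer)

    shared_vec = None if vectorize_per_fold else fit_tfidf(list(texts), **tfidf_params)

    per_trial_fold_metrics: list[list[MetricSet]] = []
    chosen_params: list[dict] = []
    fold_vocabularies: list[list[frozenset]] = []
    for trial in range(n_trials):
        trial_seed = seed + trial
        outer = StratifiedKFold(n_splits=n_outer, shuffle=True, random_state=trial_seed)
        fold_metrics: list[MetricSet] = []
        fold_vocabs: list[frozenset] = []
        trial_params: dict | None = None
        for fold_i, (tr, te) in enumerate(outer.split(texts, y)):
            params = _inner_select(
                texts[tr], y[tr], grid_list, n_inner, tfidf_params,
                trial_seed, vectorize_per_fold, shared_vec,
            )
            if fold_i == 0:
                trial_params = params
            vec = fit_tfidf(texts[tr], **tfidf_params) if vectorize_per_fold else shared_vec
            clf = GradientBoostingClassifier(random_state=trial_seed, **params)
            clf.fit(transform(texts[tr], vec), y[tr])
            pred = clf.predict(transform(texts[te], vec))
            fold_metrics.append(metrics(confusion(y[te], pred)))
            fold_vocabs.append(frozenset(vec.vocabulary) if vectorize_per_fold else frozenset())
        per_trial_fold_metrics.append(fold_metrics)
        chosen_params.append(trial_params or grid_list[0])
        fold_vocabularies.append(fold_vocabs)

    # winning configuration = modal choice across trials, refit on everything
    keys = [tuple(sorted(p.items())) for p in chosen_params]
    final_params = dict(max(set(keys), key=keys.count))
    final_vec = fit_tfidf(list(texts), **tfidf_params)
    final_model = GradientBoostingClassifier(random_state=seed, **final_params)
    final_model.fit(transform(list(texts), final_vec), y)

    return NestedCVResult(
        per_trial_fold_metrics=per_trial_fold_metrics,
        chosen_params=chosen_params,
        final_params=final_params,
        final_model=final_model,
        final_vectorizer=final_vec,
        seed=seed,
        n_outer=n_outer,
        n_trials=n_trials,
        fold_vocabularies=fold_vocabularies,
    )


def predict(result: NestedCVResult, texts: Sequence[str], threshold: float = 0.5):
    """Labels and positive-class scores from the refit final model."""
    if result.final_model is None or result.final_vectorizer is None:
        raise ModelStateError("nested_cv_train has not produced a refit final model")
    X = transform(list(texts), result.final_vectorizer)
    scores = result.final_model.predict_proba(X)[:, 1]
    labels = (scores >= threshold).astype(int)
    return labels, scores
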