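"""Confusion counts, derived metrics, bootstrap evaluation and ROC/AUC.

All classifiers in the pipeline are scored through this module so that every
reported number is recomputable from persisted per-document predictions.

Metric definitions (binary, positive label fixed per call):

* sensitivity = tp / (tp + fn)
* ppv         = tp / (tp + fp)
* npv         = tn / (tn + fn)
* accuracy    = (tp + tn) / total
* f1          = harmonic mean of ppv and sensitivity

A metric whose denominator is zero is *undefined* and reported as ``None`` —
never silently zero.  Report tables round half-up to a configurable number of
decimals (default 2); raw full-precision values are always retained.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Callable, Sequence

import numpy as np
from scipy.stats import rankdata

METRIC_NAMES = ("sensitivity", "ppv", "npv", "f1", "accuracy")


def round_half_up(value: float, places: int = 2) -> float:
    """Decimal half-up rounding (0.905 -> 0.91 at 2 places)."""
    q = Decimal(10) ** -places
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class MetricSet:
    """The five derived metrics; ``None`` marks an undefined denominator."""

    sensitivity: float | None
    ppv: float | None
    npv: float | None
    f1: float | None
    accuracy: float | None

    def rounded(self, places: int = 2) -> "MetricSet":
        vals = {
            name: (None if v is None else round_half_up(v, places))
            for name, v in self.as_dict().items()
        }
        return MetricSet(**vals)

    def as_dict(self) -> dict[str, float | None]:
        return {
            "sensitivity": self.sensitivity,
            "ppv": self.ppv,
            "npv": self.npv,
            "f1": self.f1,
            "accuracy": self.accuracy,
        }


def confusion(y_true: Sequence[int], y_pred: Sequence[int], positive_label: int = 1) -> ConfusionCounts:
    """Binary confusion counts treating ``positive_label`` as the positive class."""
    if len(y_true) != len(y_pred):
        raise ValueError(f"length mismatch: {len(y_true)} vs {len(y_pred)}")
    t = np.asarray(y_true) == positive_label
    p = np.asarray(y_pred) == positive_label
    return ConfusionCounts(
        tp=int(np.sum(t & p)),
        fp=int(np.sum(~t & p)),
        fn=int(np.sum(t & ~p)),
        tn=int(np.sum(~t & ~p)),
    )


def per_concept_confusion(
    y_true: Sequence[int], y_pred: Sequence[int], labels: Sequence[int] = (1, 2, 3)
) -> dict[int, ConfusionCounts]:
    """One-vs-rest confusion counts for each concept label."""
    return {lab: confusion(y_true, y_pred, positive_label=lab) for lab in labels}


def metrics(c: ConfusionCounts, rounding: int | None = None) -> MetricSet:
    """Derive the five metrics from confusion counts.

    ``rounding=None`` returns full precision; an integer applies half-up
    rounding to that many decimal places (the printed-table convention).
    """
    if c.total == 0:
        raise ValueError("cannot compute metrics from all-zero counts")

    def ratio(num: int, den: int) -> float | None:
        return None if den == 0 else num / den

    sens = ratio(c.tp, c.tp + c.fn)
    ppv = ratio(c.tp, c.tp + c.fp)
    npv = ratio(c.tn, c.tn + c.fn)
    acc = (c.tp + c.tn) / c.total
    if sens is None or ppv is None or (sens + ppv) == 0:
        f1 = None
    else:
        f1 = 2 * ppv * sens / (ppv + sens)
    out = MetricSet(sensitivity=sens, ppv=ppv, npv=npv, f1=f1, accuracy=acc)
    return out.rounded(rounding) if rounding is not None else out


@dataclass
class BootstrapResult:
    n_trials: int
    per_trial: list[MetricSet]
    mean: dict[str, float | None] = field(default_factory=dict)
    sd: dict[str, float | None] = field(default_factory=dict)
    undefined_counts: dict[str, int] = field(default_factory=dict)

    def formatted(self, places: int = 2) -> dict[str, str]:
        """Mean(SD) strings in the printed style, e.g. ``"0.77(0.02)"``."""
        out = {}
        for name in METRIC_NAMES:
            m, s = self.mean.get(name), self.sd.get(name)
            if m is None:
                out[name] = "NA"
            else:
                out[name] = f"{round_half_up(m, places):.{places}f}({round_half_up(s, places):.{places}f})"
        return out


def bootstrap_evaluate(
    y_true: Sequence[int],
    y_pred_fn: Callable[[np.ndarray], Sequence[int]],
    n_trials: int = 20,
    seed: int = 0,
    positive_label: int = 1,
) -> BootstrapResult:
    """Resample the evaluation set with replacement ``n_trials`` times.

    ``y_pred_fn`` receives the resampled index array and must return the
    predictions for those indices (for a fixed prediction vector ``pred`` pass
    ``lambda idx: pred[idx]``).  A metric undefined in a given trial is
    excluded from that metric's mean/SD, with the exclusion counted.
    """
    y_true = np.asarray(y_true)
    if len(y_true) == 0:
        raise ValueError("evaluation set is empty")
    rng = np.random.default_rng(seed)
    per_trial: list[MetricSet] = []
    for _ in range(n_trials):
        idx = rng.integers(0, len(y_true), size=len(y_true))
        pred = np.asarray(y_pred_fn(idx))
        per_trial.append(metrics(confusion(y_true[idx], pred, positive_label)))
    result = BootstrapResult(n_trials=n_trials, per_trial=per_trial)
    for name in METRIC_NAMES:
        vals = [getattr(m, name) for m in per_trial]
        defined = [v for v in vals if v is not None]
        result.undefined_counts[name] = len(vals) - len(defined)
        if defined:
            result.mean[name] = float(np.mean(defined))
            result.sd[name] = float(np.std(defined, ddof=1)) if len(defined) > 1 else 0.0
        else:
            result.mean[name] = None
            result.sd[name] = None
    return result


def roc_auc(y_true: Sequence[int], scores: Sequence[float]) -> float:
    """AUC via the midrank (Mann-Whitney U) convention."""
    y = np.asarray(y_true)
    s = np.asarray(scores, dtype=float)
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("roc_auc requires both classes present")
    ranks = rankdata(s)  # midranks for ties
    u = float(np.sum(ranks[y == 1])) - n_pos * (n_pos + 1) / 2.0
    return u / (n_pos * n_neg)


def roc_curve_points(y_true: Sequence[int], scores: Sequence[float]) -> np.ndarray:
    """(fpr, tpr, threshold) rows for plotting, descending threshold order."""
    y = np.asarray(y_true)
    s = np.asarray(scores, dtype=float)
    order = np.argsort(-s, kind="stable")
    y_sorted = y[order]
    s_sorted = s[order]
    distinct = np.where(np.diff(s_sorted))[0]
    cut = np.r_[distinct, len(s_sorted) - 1]
    tps = np.cumsum(y_sorted == 1)[cut]
    fps = np.cumsum(y_sorted == 0)[cut]
    n_pos = max(int(np.sum(y == 1)), 1)
    n_neg = max(int(np.sum(y == 0)), 1)
    fpr = np.r_[0.0, fps / n_neg]
    tpr = np.r_[0.0, tps / n_pos]
    thr = np.r_[math.inf, s_sorted[cut]]
    return np.column_stack([fpr, tpr, thr])
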