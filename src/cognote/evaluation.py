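"""Confusion-matrix metrics, percentile-bootstrap confidence intervals, and
paired bootstrap model comparison.

The five reported metrics are precision (PPV), recall (sensitivity), F1,
specificity, and NPV, plus accuracy:

    precision   = TP / (TP + FP)          recall = TP / (TP + FN)
    F1          = 2 P R / (P + R)    specificity = TN / (TN + FP)
    NPV         = TN / (TN + FN)       accuracy  = (TP + TN) / N

A metric with a zero denominator is *undefined* (``None``), never coerced to
zero.  Confidence intervals are percentile bootstrap over section resamples
(resampling by patient is available, since section-level resampling ignores
within-patient correlation); paired comparison applies the *same* resample
indices to both models and t-tests the replicate-wise metric differences.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .corpus import Corpus
from .ensemble import PredictionSet

__all__ = [
    "ConfusionMatrix",
    "MetricsReport",
    "confusion_matrix",
    "compute_metrics",
    "bootstrap_cis",
    "paired_metric_test",
]

METRIC_NAMES = ("precision", "recall", "f1", "specificity", "npv", "accuracy")


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion-matrix counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass
class MetricsReport:
    """Point metrics, each a fraction in [0, 1] or None when undefined,
    with optional per-metric percentile CIs."""

    precision: float | None
    recall: float | None
    f1: float | None
    specificity: float | None
    npv: float | None
    accuracy: float | None
    cis: dict[str, tuple[float, float]] = field(default_factory=dict)
    n_bootstrap: int = 0
    dropped_replicates: dict[str, int] = field(default_factory=dict)

    def as_dict(self) -> dict:
        out = {m: getattr(self, m) for m in METRIC_NAMES}
        if self.cis:
            out["cis"] = {k: list(v) for k, v in self.cis.items()}
            out["n_bootstrap"] = self.n_bootstrap
            out["dropped_replicates"] = dict(self.dropped_replicates)
        return out


def _align(pred: PredictionSet, gold: Corpus) -> tuple[np.ndarray, np.ndarray]:
    if set(pred.predictions) != set(gold.section_ids):
        raise ValueError(
            f"prediction ids of {pred.model_name!r} do not match the gold corpus"
        )
    y = np.asarray(gold.labels)
    yhat = np.asarray([pred.predictions[sid] for sid in gold.section_ids])
    return y, yhat


def confusion_matrix(pred: PredictionSet, gold: Corpus) -> ConfusionMatrix:
    y, yhat = _align(pred, gold)
    return ConfusionMatrix(
        tp=int(np.sum((y == 1) & (yhat == 1))),
        fp=int(np.sum((y == 0) & (yhat == 1))),
        fn=int(np.sum((y == 1) & (yhat == 0))),
        tn=int(np.sum((y == 0) & (yhat == 0))),
    )


def _safe_div(num: float, den: float) -> float | None:
    return num / den if den > 0 else None


def compute_metrics(cm: ConfusionMatrix) -> MetricsReport:
    p = _safe_div(cm.tp, cm.tp + cm.fp)
    r = _safe_div(cm.tp, cm.tp + cm.fn)
    f1 = _safe_div(2 * p * r, p + r) if (p is not None and r is not None and p + r > 0) else (
        0.0 if (p == 0 or r == 0) and p is not None and r is not None else None
    )
    return MetricsReport(
        precision=p,
        recall=r,
        f1=f1,
        specificity=_safe_div(cm.tn, cm.tn + cm.fp),
        npv=_safe_div(cm.tn, cm.tn + cm.fn),
        accuracy=_safe_div(cm.tp + cm.tn, cm.n),
    )


def _outcome_codes(y: np.ndarray, yhat: np.ndarray) -> np.ndarray:
    # 0=tn, 1=fp, 2=fn, 3=tp — one code per section, resampled jointly.
    return (2 * y + yhat).astype(np.int64)


_METRIC_FROM_COUNTS = {
    "precision": lambda tn, fp, fn, tp: np.where(tp + fp > 0, tp / np.maximum(tp + fp, 1), np.nan),
    "recall": lambda tn, fp, fn, tp: np.where(tp + fn > 0, tp / np.maximum(tp + fn, 1), np.nan),
    "specificity": lambda tn, fp, fn, tp: np.where(tn + fp > 0, tn / np.maximum(tn + fp, 1), np.nan),
    "npv": lambda tn, fp, fn, tp: np.where(tn + fn > 0, tn / np.maximum(tn + fn, 1), np.nan),
    "accuracy": lambda tn, fp, fn, tp: (tp + tn) / (tn + fp + fn + tp),
}


def _replicate_metrics(codes: np.ndarray, idx: np.ndarray) -> dict[str, np.ndarray]:
    """Metric value per bootstrap replicate (NaN where undefined)."""
    B = idx.shape[0]
    counts = np.zeros((B, 4))
    for b in range(B):
        counts[b] = np.bincount(codes[idx[b]], minlength=4)
    tn, fp, fn, tp = counts.T
    with np.errstate(invalid="ignore", divide="ignore"):
        out = {name: f(tn, fp, fn, tp) for name, f in _METRIC_FROM_COUNTS.items()}
        p, r = out["precision"], out["recall"]
        out["f1"] = np.where(p + r > 0, 2 * p * r / np.maximum(p + r, 1e-300), np.nan)
        both_zero = (p == 0) & (r == 0)
        out["f1"][both_zero] = 0.0
    return out


def bootstrap_cis(
    pred: PredictionSet,
    gold: Corpus,
    B: int = 1000,
    level: float = 0.95,
    seed: int = 0,
    by_patient: bool = False,
) -> MetricsReport:
    """Percentile-bootstrap CIs for all six metrics.

    Sections (or whole patients with ``by_patient``) are resampled with
    replacement B times; replicates on which a metric is undefined are
    dropped for that metric, with the count recorded in
    ``dropped_replicates``.
    """
    y, yhat = _align(pred, gold)
    n = len(y)
    if n < 2:
        raise ValueError("bootstrap needs at least 2 sections")
    if len(np.unique(y)) < 2:
        raise ValueError("gold labels contain a single class; CIs are degenerate")
    if B < 100:
        warnings.warn(f"B={B} is small; intervals will be noisy", stacklevel=2)
    rng = np.random.default_rng(seed)
    if by_patient:
        patients = np.asarray([s.patient_id for s in gold.sections])
        uniq, inv = np.unique(patients, return_inverse=True)
        members = [np.flatnonzero(inv == k) for k in range(len(uniq))]
        idx = np.empty((B, 0), dtype=object)
        rows = []
        for b in range(B):
            chosen = rng.integers(0, len(uniq), size=len(uniq))
            rows.append(np.concatenate([members[c] for c in chosen]))
        codes = _outcome_codes(y, yhat)
        reps = {m: np.empty(B) for m in METRIC_NAMES}
        for b, row in enumerate(rows):
            c = np.bincount(codes[row], minlength=4)
            rep = compute_metrics(ConfusionMatrix(tp=int(c[3]), fp=int(c[1]), fn=int(c[2]), tn=int(c[0])))
            for m in METRIC_NAMES:
                v = getattr(rep, m)
                reps[m][b] = np.nan if v is None else v
    else:
        idx = rng.integers(0, n, size=(B, n))
        reps = _replicate_metrics(_outcome_codes(y, yhat), idx)

    point = compute_metrics(confusion_matrix(pred, gold))
    lo_q, hi_q = (1 - level) / 2, 1 - (1 - level) / 2
    cis: dict[str, tuple[float, float]] = {}
    dropped: dict[str, int] = {}
    for m in METRIC_NAMES:
        vals = reps[m]
        ok = vals[~np.isnan(vals)]
        dropped[m] = int(len(vals) - len(ok))
        if len(ok):
            cis[m] = (float(np.quantile(ok, lo_q)), float(np.quantile(ok, hi_q)))
    point.cis = cis
    point.n_bootstrap = B
    point.dropped_replicates = dropped
    return point


def paired_metric_test(
    pred_a: PredictionSet,
    pred_b: PredictionSet,
    gold: Corpus,
    B: int = 1000,
    seed: int = 0,
) -> dict[str, tuple[float, float]]:
    """Paired t-test on replicate-wise metric differences (a minus b).

    The same B bootstrap resamples are applied to both models; replicates on
    which either metric is undefined are dropped for that metric.  If every
    paired difference is exactly zero the test reports (t=0, p=1) by
    convention.
    """
    y, yhat_a = _align(pred_a, gold)
    _, yhat_b = _align(pred_b, gold)
    n = len(y)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(B, n))
    reps_a = _replicate_metrics(_outcome_codes(y, yhat_a), idx)
    reps_b = _replicate_metrics(_outcome_codes(y, yhat_b), idx)
    out: dict[str, tuple[float, float]] = {}
    for m in METRIC_NAMES:
        d = reps_a[m] - reps_b[m]
        d = d[~np.isnan(d)]
        if len(d) == 0 or np.all(d == 0):
            out[m] = (0.0, 1.0)
            continue
        res = stats.ttest_1samp(d, 0.0)
        out[m] = (float(res.statistic), float(res.pvalue))
    return out
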