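"""Confusion-matrix metrics, ROC/AUC, and per-algorithm benchmarking.

All metrics are computed on the subset of variants an algorithm actually
scored; missing predictions are never imputed and are reported separately
as a count and a percentage of the full variant set.  Ratios with an
empty denominator are UNDEFINED (``None``), not zero, and serialize to
JSON ``null``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve as _sk_roc_curve

from .io_model import (
    AlgorithmSpec,
    Direction,
    LabeledVariantSet,
    ScoreTable,
    builtin_registry,
)

__all__ = [
    "ConfusionCounts",
    "MetricReport",
    "RocCurve",
    "binarize",
    "confusion_counts",
    "compute_metrics",
    "roc_points",
    "auc",
    "benchmark",
    "benchmark_frame",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 call-vs-label counts plus the unscored remainder."""

    TP: int
    TN: int
    FP: int
    FN: int
    n_missing: int = 0

    def __post_init__(self) -> None:
        for name in ("TP", "TN", "FP", "FN", "n_missing"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def n_total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN + self.n_missing

    @property
    def n_called(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


def _ratio(num: int, den: int) -> float | None:
    return None if den == 0 else num / den


@dataclass(frozen=True)
class MetricReport:
    """Benchmark metrics for one classifier; ``None`` marks UNDEFINED.

    Maintains SEN + FNR = 1, SPE + FPR = 1 and J = SEN + SPE - 1
    whenever the constituent ratios are defined.
    """

    SEN: float | None
    SPE: float | None
    ACC: float | None
    PPV: float | None
    NPV: float | None
    FPR: float | None
    FNR: float | None
    J: float | None
    AUC: float | None = None
    missing_count: int = 0
    missing_pct: float = 0.0

    def to_dict(self) -> dict:
        return {
            "SEN": self.SEN,
            "SPE": self.SPE,
            "ACC": self.ACC,
            "PPV": self.PPV,
            "NPV": self.NPV,
            "FPR": self.FPR,
            "FNR": self.FNR,
            "J": self.J,
            "AUC": self.AUC,
            "missing_count": self.missing_count,
            "missing_pct": self.missing_pct,
        }


@dataclass(frozen=True)
class RocCurve:
    """ROC points ordered by sweeping the decision threshold.

    ``fpr``/``tpr`` run from (0, 0) to (1, 1); ``thresholds`` are on the
    algorithm's native score scale (the first point has no finite
    generating threshold and carries ``inf``/``-inf`` accordingly).
    """

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    direction: Direction

    def __post_init__(self) -> None:
        if not (np.diff(self.fpr) >= 0).all():
            raise ValueError("FPR must be non-decreasing along the curve")
        if not (
            self.fpr[0] == 0 and self.tpr[0] == 0
            and self.fpr[-1] == 1 and self.tpr[-1] == 1
        ):
            raise ValueError("curve must run from (0,0) to (1,1)")


def _as_deleterious_mask(labels) -> np.ndarray:
    """Coerce labels (bool array, {0,1}, or label strings) to a bool mask."""
    if isinstance(labels, LabeledVariantSet):
        return labels.is_deleterious().to_numpy()
    arr = np.asarray(labels)
    if arr.dtype == bool:
        return arr
    if arr.dtype.kind in "iuf":
        return arr.astype(bool)
    return arr.astype(str) == "deleterious"


def binarize(scores, spec: AlgorithmSpec) -> pd.Series:
    """Apply an algorithm's threshold to raw scores.

    Returns a Series of ``"deleterious"`` / ``"neutral"`` with ``NaN``
    propagated for missing scores.  The comparison honours the spec's
    direction and operator strictness, so a score exactly at the
    threshold lands on the side the published cutoff dictates.
    """
    s = pd.Series(np.asarray(scores, dtype=float)) if not isinstance(
        scores, pd.Series
    ) else scores.astype(float)
    out = pd.Series(np.nan, index=s.index, dtype=object)
    present = s.notna()
    dele = s[present].map(spec.calls_deleterious)
    out[present] = np.where(dele, "deleterious", "neutral")
    return out


def confusion_counts(calls, labels) -> ConfusionCounts:
    """Tally calls against binary labels; missing calls are counted apart.

    ``calls`` may be the output of :func:`binarize` or any sequence of
    ``deleterious``/``neutral``/NaN aligned with ``labels``.
    """
    calls = pd.Series(calls).reset_index(drop=True)
    truth = _as_deleterious_mask(labels)
    if len(calls) != len(truth):
        raise ValueError("calls and labels must cover the same variants")
    missing = calls.isna().to_numpy()
    called_del = (calls == "deleterious").to_numpy()
    ok = ~missing
    return ConfusionCounts(
        TP=int(np.sum(ok & truth & called_del)),
        TN=int(np.sum(ok & ~truth & ~called_del)),
        FP=int(np.sum(ok & ~truth & called_del)),
        FN=int(np.sum(ok & truth & ~called_del)),
        n_missing=int(missing.sum()),
    )


def compute_metrics(c: ConfusionCounts, auc: float | None = None) -> MetricReport:
    """Derive the benchmark ratios from confusion counts.

    Sensitivity TP/(TP+FN), specificity TN/(TN+FP), accuracy, PPV, NPV,
    FPR, FNR and Youden's J = sensitivity + specificity - 1.  Any ratio
    whose denominator is zero is UNDEFINED (``None``).
    """
    sen = _ratio(c.TP, c.TP + c.FN)
    spe = _ratio(c.TN, c.TN + c.FP)
    return MetricReport(
        SEN=sen,
        SPE=spe,
        ACC=_ratio(c.TP + c.TN, c.n_called),
        PPV=_ratio(c.TP, c.TP + c.FP),
        NPV=_ratio(c.TN, c.TN + c.FN),
        FPR=_ratio(c.FP, c.FP + c.TN),
        FNR=_ratio(c.FN, c.FN + c.TP),
        J=(sen + spe - 1) if sen is not None and spe is not None else None,
        AUC=auc,
        missing_count=c.n_missing,
        missing_pct=_ratio(c.n_missing, c.n_total) or 0.0,
    )


def _oriented(scores: np.ndarray, direction: Direction) -> np.ndarray:
    """Map scores so that larger always means more deleterious."""
    return scores if direction is Direction.DELETERIOUS_IF_HIGH else -scores


def roc_points(scores, labels, direction: Direction) -> RocCurve:
    """ROC curve oriented by the algorithm's deleterious direction.

    One point per distinct observed threshold; missing scores are
    excluded.  Raises on single-class input, where no curve exists.
    """
    s = np.asarray(scores, dtype=float)
    truth = _as_deleterious_mask(labels)
    keep = ~np.isnan(s)
    s, truth = s[keep], truth[keep]
    if truth.all() or not truth.any():
        raise ValueError("ROC needs at least one variant of each class")
    oriented = _oriented(s, direction)
    fpr, tpr, thr = _sk_roc_curve(truth, oriented, drop_intermediate=False)
    # restore native-scale thresholds (first entry is the +inf sentinel)
    native = thr if direction is Direction.DELETERIOUS_IF_HIGH else -thr
    return RocCurve(fpr=fpr, tpr=tpr, thresholds=native, direction=direction)


def auc(curve_or_scores, labels=None, direction: Direction | None = None) -> float:
    """Area under the ROC curve by trapezoidal integration.

    Accepts either a fitted :class:`RocCurve` or raw
    ``(scores, labels, direction)``.  Equals the Mann-Whitney rank
    statistic — the probability a deleterious variant is scored more
    deleterious than a neutral one, ties counting one half.
    """
    if isinstance(curve_or_scores, RocCurve):
        curve = curve_or_scores
    else:
        if labels is None or direction is None:
            raise TypeError("auc(scores, labels, direction) requires all three")
        curve = roc_points(curve_or_scores, labels, direction)
    return float(np.trapezoid(curve.tpr, curve.fpr))


def benchmark(
    table: ScoreTable,
    labels: LabeledVariantSet,
    specs: Sequence[AlgorithmSpec] | None = None,
) -> dict[str, MetricReport]:
    """Benchmark every algorithm of a score table against labels.

    For each algorithm the confusion metrics are computed over the
    variants it scored; variants it could not score are reported as
    ``missing_count`` and ``missing_pct`` of the full labeled set.  AUC
    is ``None`` when fewer than one variant per class was scored.
    """
    if specs is None:
        by_name = {s.name: s for s in builtin_registry()}
        specs = [by_name[a] for a in table.algorithms if a in by_name]
    ids = [v.id for v in labels.variants]
    truth = labels.is_deleterious().to_numpy()
    reports: dict[str, MetricReport] = {}
    for spec in specs:
        if spec.name not in table.algorithms:
            raise KeyError(f"score table has no column {spec.name!r}")
        scores = table.scores[spec.name].reindex(ids)
        calls = binarize(scores, spec)
        counts = confusion_counts(calls, truth)
        s = scores.to_numpy(dtype=float)
        keep = ~np.isnan(s)
        auc_val: float | None = None
        if keep.any() and truth[keep].any() and not truth[keep].all():
            auc_val = auc(s[keep], truth[keep], spec.direction)
        reports[spec.name] = compute_metrics(counts, auc=auc_val)
    return reports


def benchmark_frame(reports: Mapping[str, MetricReport]) -> pd.DataFrame:
    """Arrange benchmark reports as a table sorted by descending AUC."""
    rows = []
    for name, r in reports.items():
        d = r.to_dict()
        d["algorithm"] = name
        d["missing"] = f"{r.missing_count} ({round(100 * r.missing_pct):d}%)"
        rows.append(d)
    df = pd.DataFrame(rows).set_index("algorithm")
    cols = ["SEN", "SPE", "ACC", "PPV", "NPV", "FPR", "FNR", "J", "AUC", "missing"]
    return df[cols].sort_values("AUC", ascending=False)
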