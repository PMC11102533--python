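"""Agreement and timing statistics for grader validation.

Covers the arithmetic used to certify an automatic grader against human
ground truth: the truth-vs-predicted confusion matrix, binary collapse
metrics (sensitivity, specificity, accuracy, F1) with explicit
undefined-value semantics, unweighted Cohen's kappa, and a two-sample
comparison of appraisal durations from summary statistics.

A metric whose denominator is zero is reported as :data:`UNDEFINED` — a
first-class value distinct from 0.0 and from an error — because a
validation set with, say, no defect-free fields genuinely cannot estimate
the specificity of defect detection, and that fact belongs in the report.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats as _scipy_stats

from .hpa import SeverityGrade

__all__ = [
    "UNDEFINED",
    "Undefined",
    "ConfusionMatrix",
    "BinaryMetrics",
    "DurationSummary",
    "TTestResult",
    "confusion_matrix",
    "binary_metrics",
    "cohen_kappa",
    "welch_t",
    "pooled_t",
    "validation_report",
    "format_report",
    "read_label_manifest",
    "read_durations",
]

GRADE_CLASSES = tuple(g.label for g in SeverityGrade)
DEFECT_CLASSES = ("mild", "moderate", "severe")


class Undefined:
    """Singleton marker for a metric with an empty denominator."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:
        return "UNDEFINED"


UNDEFINED = Undefined()


def _ratio(num: float, den: float) -> "float | Undefined":
    return UNDEFINED if den == 0 else num / den


def metric_to_json(value: "float | Undefined") -> "float | str":
    return "undefined" if value is UNDEFINED else value


# ---------------------------------------------------------------------------
# Confusion matrix
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConfusionMatrix:
    """Truth-by-predicted count table; rows are truth, columns predicted."""

    classes: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=int)
        object.__setattr__(self, "counts", counts)
        k = len(self.classes)
        if counts.shape != (k, k):
            raise ValueError(f"counts must be {k}x{k}, got {counts.shape}")
        if (counts < 0).any():
            raise ValueError("counts must be non-negative")
        if counts.sum() == 0:
            raise ValueError("confusion matrix must contain at least one observation")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def accuracy(self) -> float:
        """Multi-class accuracy: the diagonal proportion."""
        return float(np.trace(self.counts)) / self.total

    def is_diagonal(self) -> bool:
        return bool(np.all(self.counts == np.diag(np.diag(self.counts))))

    def to_json(self) -> dict:
        return {"classes": list(self.classes), "counts": self.counts.tolist()}


def confusion_matrix(
    truth: Sequence[str], predicted: Sequence[str], classes: Sequence[str] = GRADE_CLASSES
) -> ConfusionMatrix:
    """Tally truth-vs-predicted labels into a square count table."""
    if len(truth) != len(predicted):
        raise ValueError(f"label lists differ in length: {len(truth)} vs {len(predicted)}")
    if not truth:
        raise ValueError("label lists must be non-empty")
    index = {c: i for i, c in enumerate(classes)}
    counts = np.zeros((len(classes), len(classes)), dtype=int)
    for t, p in zip(truth, predicted):
        if t not in index or p not in index:
            raise ValueError(f"label pair ({t!r}, {p!r}) outside classes {classes}")
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(tuple(classes), counts)


# ---------------------------------------------------------------------------
# Binary collapse metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BinaryMetrics:
    """Sensitivity, specificity, accuracy and F1 of a positive-vs-rest
    collapse, with the underlying 2x2 counts."""

    sensitivity: "float | Undefined"
    specificity: "float | Undefined"
    accuracy: "float | Undefined"
    f1: "float | Undefined"
    tp: int
    fp: int
    fn: int
    tn: int

    def to_json(self) -> dict:
        return {
            "sensitivity": metric_to_json(self.sensitivity),
            "specificity": metric_to_json(self.specificity),
            "accuracy": metric_to_json(self.accuracy),
            "f1": metric_to_json(self.f1),
            "tp": self.tp,
            "fp": self.fp,
            "fn": self.fn,
            "tn": self.tn,
        }


def binary_metrics(cm: ConfusionMatrix, positive_classes: Iterable[str]) -> BinaryMetrics:
    """Collapse a multi-class table to positive-vs-rest and score it.

    ``sensitivity = TP/(TP+FN)``, ``specificity = TN/(TN+FP)``,
    ``f1 = 2TP/(2TP+FP+FN)``; a zero denominator yields :data:`UNDEFINED`.
    The collapse preserves the total observation count.
    """
    positive = set(positive_classes)
    if not positive or not positive < set(cm.classes):
        raise ValueError(
            f"positive classes {sorted(positive)} must be a non-empty proper subset of {cm.classes}"
        )
    pos = np.array([c in positive for c in cm.classes])
    tp = int(cm.counts[np.ix_(pos, pos)].sum())
    fn = int(cm.counts[np.ix_(pos, ~pos)].sum())
    fp = int(cm.counts[np.ix_(~pos, pos)].sum())
    tn = int(cm.counts[np.ix_(~pos, ~pos)].sum())
    return BinaryMetrics(
        sensitivity=_ratio(tp, tp + fn),
        specificity=_ratio(tn, tn + fp),
        accuracy=_ratio(tp + tn, tp + fp + fn + tn),
        f1=_ratio(2 * tp, 2 * tp + fp + fn),
        tp=tp, fp=fp, fn=fn, tn=tn,
    )


# ---------------------------------------------------------------------------
# Cohen's kappa
# ---------------------------------------------------------------------------

def cohen_kappa(cm: ConfusionMatrix) -> "float | Undefined":
    """Unweighted Cohen's kappa: (p_o - p_e) / (1 - p_e).

    p_o is the observed agreement (diagonal proportion); p_e the chance
    agreement implied by the row and column margins.  Returns
    :data:`UNDEFINED` for degenerate tables where p_e = 1 (both raters
    confined to a single class), since chance correction is impossible.
    """
    n = cm.total
    p_o = cm.accuracy()
    rows = cm.counts.sum(axis=1) / n
    cols = cm.counts.sum(axis=0) / n
    p_e = float(rows @ cols)
    if math.isclose(p_e, 1.0, abs_tol=1e-12):
        return UNDEFINED
    return (p_o - p_e) / (1.0 - p_e)


# ---------------------------------------------------------------------------
# Duration comparison (t-test from summary statistics)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DurationSummary:
    """Mean +- SD of appraisal durations (seconds) over n assessments."""

    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("standard deviation must be non-negative")
        if self.n < 2:
            raise ValueError("at least two observations are required")


@dataclass(frozen=True)
class TTestResult:
    t: "float | Undefined"
    df: "float | Undefined"
    p: "float | Undefined"
    form: str

    def to_json(self) -> dict:
        return {
            "t": metric_to_json(self.t),
            "df": metric_to_json(self.df),
            "p": metric_to_json(self.p),
            "form": self.form,
        }


def welch_t(a: DurationSummary, b: DurationSummary) -> TTestResult:
    """Welch's unequal-variance two-sample t from summary statistics.

    t = (mean_a - mean_b) / sqrt(sd_a^2/n_a + sd_b^2/n_b), with
    Welch-Satterthwaite degrees of freedom and a two-sided p value.  With
    equal group sizes the statistic coincides with the pooled form (the
    degrees of freedom do not).  Returns UNDEFINED components when both
    SDs are zero.
    """
    va, vb = a.sd**2 / a.n, b.sd**2 / b.n
    se2 = va + vb
    if se2 == 0:
        return TTestResult(UNDEFINED, UNDEFINED, UNDEFINED, form="welch")
    t = (a.mean - b.mean) / math.sqrt(se2)
    df = se2**2 / (va**2 / (a.n - 1) + vb**2 / (b.n - 1))
    p = 2.0 * float(_scipy_stats.t.sf(abs(t), df))
    return TTestResult(t=t, df=df, p=p, form="welch")


def pooled_t(a: DurationSummary, b: DurationSummary) -> TTestResult:
    """Student's pooled-variance two-sample t from summary statistics."""
    df = a.n + b.n - 2
    sp2 = ((a.n - 1) * a.sd**2 + (b.n - 1) * b.sd**2) / df
    se2 = sp2 * (1 / a.n + 1 / b.n)
    if se2 == 0:
        return TTestResult(UNDEFINED, UNDEFINED, UNDEFINED, form="pooled")
    t = (a.mean - b.mean) / math.sqrt(se2)
    p = 2.0 * float(_scipy_stats.t.sf(abs(t), df))
    return TTestResult(t=t, df=float(df), p=p, form="pooled")


# ---------------------------------------------------------------------------
# Report assembly
# ---------------------------------------------------------------------------

def validation_report(
    truth: Sequence[str],
    predicted: Sequence[str],
    classes: Sequence[str] = GRADE_CLASSES,
    durations: "dict[str, DurationSummary] | None" = None,
) -> dict:
    """Full validation arithmetic as a JSON-serialisable report.

    Binary collapses are computed for "any defect" (mild or worse positive)
    and "severe defect" (severe positive).  When two duration summaries are
    supplied, a Welch comparison of the two methods is included.
    """
    cm = confusion_matrix(truth, predicted, classes)
    report = {
        "schema": "hpagrade.validation_report.v1",
        "n": cm.total,
        "confusion_matrix": cm.to_json(),
        "kappa": metric_to_json(cohen_kappa(cm)),
        "accuracy": cm.accuracy(),
        "any_defect": binary_metrics(cm, [c for c in DEFECT_CLASSES if c in classes]).to_json(),
        "severe_defect": binary_metrics(cm, ["severe"]).to_json(),
    }
    if durations:
        if len(durations) != 2:
            raise ValueError("duration comparison requires exactly two methods")
        (name_a, a), (name_b, b) = sorted(durations.items())
        report["durations"] = {
            "methods": {
                name_a: {"mean": a.mean, "sd": a.sd, "n": a.n},
                name_b: {"mean": b.mean, "sd": b.sd, "n": b.n},
            },
            "welch": welch_t(a, b).to_json(),
            "pooled": pooled_t(a, b).to_json(),
        }
    return report


def _pct(value: "float | Undefined") -> str:
    return "undefined" if value is UNDEFINED else f"{100 * value:.1f}%"


def format_report(report: dict) -> str:
    """Human-readable summary of a validation report."""
    lines = [
        f"Validation on {report['n']} fields.",
        f"Overall accuracy: {_pct(report['accuracy'])}; agreement kappa = "
        + ("undefined" if report["kappa"] == "undefined" else f"{report['kappa']:.2f}")
        + ".",
    ]
    any_d, sev = report["any_defect"], report["severe_defect"]
    lines.append(
        "Any defect: sensitivity "
        f"{_pct_json(any_d['sensitivity'])}, specificity {_pct_json(any_d['specificity'])}."
    )
    lines.append(
        "Severe defect: sensitivity "
        f"{_pct_json(sev['sensitivity'])}, specificity {_pct_json(sev['specificity'])}, "
        f"F1 {_pct_json(sev['f1'])}."
    )
    if "durations" in report:
        w = report["durations"]["welch"]
        methods = report["durations"]["methods"]
        named = ", ".join(
            f"{name}: {m['mean']:.1f} +- {m['sd']:.1f} s (n={m['n']})" for name, m in methods.items()
        )
        lines.append(f"Appraisal durations — {named}.")
        if w["t"] != "undefined":
            lines.append(f"Welch t = {w['t']:.2f}, df = {w['df']:.1f}, p = {w['p']:.3f}.")
    return "\n".join(lines)


def _pct_json(value: "float | str") -> str:
    return "undefined" if value == "undefined" else f"{100 * value:.1f}%"


# ---------------------------------------------------------------------------
# CSV interfaces
# ---------------------------------------------------------------------------

def read_label_manifest(path) -> tuple[list[str], list[str]]:
    """Read a (record_id, truth_grade, predicted_grade) CSV."""
    truth, predicted = [], []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        needed = {"record_id", "truth_grade", "predicted_grade"}
        if not needed <= set(reader.fieldnames or ()):
            raise ValueError(f"label manifest needs columns {sorted(needed)}, got {reader.fieldnames}")
        for row in reader:
            truth.append(row["truth_grade"].strip().lower())
            predicted.append(row["predicted_grade"].strip().lower())
    if not truth:
        raise ValueError("label manifest is empty")
    return truth, predicted


def read_durations(path) -> dict[str, DurationSummary]:
    """Read a (record_id, method, seconds) CSV into per-method summaries."""
    by_method: dict[str, list[float]] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        needed = {"record_id", "method", "seconds"}
        if not needed <= set(reader.fieldnames or ()):
            raise ValueError(f"durations CSV needs columns {sorted(needed)}, got {reader.fieldnames}")
        for row in reader:
            by_method.setdefault(row["method"].strip(), []).append(float(row["seconds"]))
    return {
        method: DurationSummary(
            mean=float(np.mean(vals)), sd=float(np.std(vals, ddof=1)), n=len(vals)
        )
        for method, vals in by_method.items()
    }
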