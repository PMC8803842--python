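"""Agreement statistics between manual and automated scoring.

Frame-level (or trial-level) manual and automated binary calls are
cross-tabulated into a 2x2 confusion matrix from which accuracy with an
exact (Clopper-Pearson) binomial confidence interval, sensitivity and
specificity are derived. Following the convention of R's caret package
(whose first factor level, "0", is the positive class), the *absent /
not-retrieved* label is treated as positive by default: sensitivity is the
correct-call rate on manual-0 frames and specificity on manual-1 frames.
The convention is recorded in every report because silently assuming
label 1 as positive swaps the two rates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy import stats


class EvaluateError(ValueError):
    pass


@dataclass
class ConfusionCounts:
    """2x2 agreement counts: a = manual 0 & predicted 0, b = manual 1 &
    predicted 0, c = manual 0 & predicted 1, d = manual 1 & predicted 1."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for v in (self.a, self.b, self.c, self.d):
            if v < 0:
                raise EvaluateError("confusion counts must be non-negative")
        if self.n < 1:
            raise EvaluateError("empty confusion matrix")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass
class MetricReport:
    accuracy: float
    ci_level: float
    ci_low: float
    ci_high: float
    sensitivity: float
    specificity: float
    positive_label: int

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "ci_level": self.ci_level,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "positive_label": self.positive_label,
        }


def confusion_counts(manual, predicted) -> ConfusionCounts:
    """Cross-tabulate equal-length binary manual and predicted vectors."""
    m = np.asarray(manual)
    p = np.asarray(predicted)
    if m.shape != p.shape:
        raise EvaluateError(f"length mismatch: manual {m.size}, predicted {p.size}")
    if not (np.isin(m, (0, 1)).all() and np.isin(p, (0, 1)).all()):
        raise EvaluateError("vectors must be binary 0/1")
    return ConfusionCounts(
        a=int(np.sum((m == 0) & (p == 0))),
        b=int(np.sum((m == 1) & (p == 0))),
        c=int(np.sum((m == 0) & (p == 1))),
        d=int(np.sum((m == 1) & (p == 1))),
    )


def _rate(num: int, den: int) -> float:
    return math.nan if den == 0 else num / den


def classification_report(cm: ConfusionCounts, positive_label: int = 0,
                          level: float = 0.95) -> MetricReport:
    """Accuracy (with exact CI), sensitivity and specificity from a 2x2 matrix.

    With ``positive_label=0`` sensitivity is a/(a+c) and specificity
    d/(b+d); with ``positive_label=1`` the two definitions swap. Rates for
    an empty class are reported as NaN. Values are stored at full
    precision; rounding is presentation only.
    """
    if positive_label not in (0, 1):
        raise EvaluateError("positive_label must be 0 or 1")
    acc = (cm.a + cm.d) / cm.n
    lo, hi = clopper_pearson(cm.a + cm.d, cm.n, level)
    sens0 = _rate(cm.a, cm.a + cm.c)
    spec0 = _rate(cm.d, cm.b + cm.d)
    if positive_label == 0:
        sens, spec = sens0, spec0
    else:
        sens, spec = spec0, sens0
    return MetricReport(acc, level, lo, hi, sens, spec, positive_label)


def clopper_pearson(successes: int, n: int, level: float = 0.95) -> Tuple[float, float]:
    """Exact binomial confidence interval (beta-quantile form).

    The lower bound is 0 when successes = 0 and the upper bound 1 when
    successes = n; otherwise the endpoints invert the binomial tail
    probabilities exactly.
    """
    if n < 1 or not 0 <= successes <= n:
        raise EvaluateError(f"invalid counts: {successes} successes of {n}")
    if not 0 < level < 1:
        raise EvaluateError("confidence level must lie in (0, 1)")
    alpha = 1.0 - level
    lo = 0.0 if successes == 0 else float(stats.beta.ppf(alpha / 2, successes, n - successes + 1))
    hi = 1.0 if successes == n else float(stats.beta.ppf(1 - alpha / 2, successes + 1, n - successes))
    return lo, hi


def pearson_correlation(x, y) -> float:
    """Product-moment correlation between two equal-length vectors."""
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape or xa.size < 3:
        raise EvaluateError("need equal-length vectors of length >= 3")
    if np.std(xa) == 0 or np.std(ya) == 0:
        raise EvaluateError("zero variance input")
    return float(stats.pearsonr(xa, ya).statistic)


def format_report(cm: ConfusionCounts, report: MetricReport) -> str:
    """Human-readable text table for a confusion matrix and its metrics."""
    lines = [
        "              predicted 0   predicted 1",
        f"manual 0    {cm.a:12d}  {cm.c:12d}",
        f"manual 1    {cm.b:12d}  {cm.d:12d}",
        "",
        f"positive label : {report.positive_label}",
        f"accuracy       : {report.accuracy * 100:.1f}% "
        f"({report.ci_level * 100:.0f}% CI {report.ci_low * 100:.1f}, {report.ci_high * 100:.1f})",
        f"sensitivity    : {report.sensitivity * 100:.1f}%",
        f"specificity    : {report.specificity * 100:.1f}%",
    ]
    return "\n".join(lines)
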