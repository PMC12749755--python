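"""Diagnostic-performance evaluation of severity thresholds.

Confusion matrices against the ascending-aorta reference, sensitivity and
specificity with Wilson (or exact) confidence intervals, likelihood ratios
with log-method intervals, Bland-Altman agreement and ROC/AUC.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "ConfusionMatrix",
    "DiagnosticSummary",
    "BlandAltman",
    "RocCurve",
    "confusion_and_summary",
    "bland_altman",
    "roc_auc",
]

_Z95 = 1.959963984540054


@dataclass
class ConfusionMatrix:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def as_text(self) -> str:
        """Plain-text 2x2 table (reference rows, prediction columns)."""
        return (
            "            pred+   pred-\n"
            f"ref+   {self.tp:8d}{self.fn:8d}\n"
            f"ref-   {self.fp:8d}{self.tn:8d}"
        )


@dataclass
class DiagnosticSummary:
    """Sensitivity/specificity in percent, likelihood ratios as ratios.

    Ratios that involve a division by zero are reported as ``inf`` (PLR)
    or ``0``/``nan`` with ``*_defined = False`` — no silent continuity
    correction unless ``haldane`` was requested.
    """

    sensitivity: float
    sensitivity_ci: tuple[float, float]
    specificity: float
    specificity_ci: tuple[float, float]
    plr: float
    plr_ci: tuple[float, float]
    plr_defined: bool
    nlr: float
    nlr_ci: tuple[float, float]
    nlr_defined: bool
    ci_method: str = "wilson"


@dataclass
class BlandAltman:
    """Agreement between paired measurements, differences ``d = x - y``."""

    bias: float
    loa_low: float
    loa_high: float
    sd_diff: float
    n: int

    def __post_init__(self) -> None:
        if not self.loa_low <= self.bias <= self.loa_high:
            raise ValueError("limits of agreement must bracket the bias")


@dataclass
class RocCurve:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.auc <= 1.0:
            raise ValueError("AUC must lie in [0, 1]")


def _proportion_ci(count: int, nobs: int, method: str) -> tuple[float, float]:
    if nobs == 0:
        return (float("nan"), float("nan"))
    method_map = {"wilson": "wilson", "exact": "beta"}
    lo, hi = proportion_confint(count, nobs, alpha=0.05, method=method_map[method])
    return (100.0 * float(lo), 100.0 * float(hi))


def _lr_log_ci(lr: float, se_log: float) -> tuple[float, float]:
    if not math.isfinite(lr) or lr <= 0 or not math.isfinite(se_log):
        return (float("nan"), float("nan"))
    log_lr = math.log(lr)
    return (math.exp(log_lr - _Z95 * se_log), math.exp(log_lr + _Z95 * se_log))


def confusion_and_summary(
    predicted: np.ndarray,
    reference: np.ndarray,
    haldane: bool = False,
    ci_method: str = "wilson",
) -> tuple[ConfusionMatrix, DiagnosticSummary]:
    """Score boolean predictions against a boolean reference.

    Sensitivity/specificity are reported in percent with Wilson score
    intervals by default (``ci_method='exact'`` for Clopper-Pearson);
    likelihood-ratio intervals use the log method.  When a ratio's
    denominator is zero it is flagged undefined unless ``haldane`` adds
    0.5 to every cell first.
    """
    predicted = np.asarray(predicted, dtype=bool)
    reference = np.asarray(reference, dtype=bool)
    if predicted.shape != reference.shape or predicted.ndim != 1:
        raise ValueError("predicted and reference must be equal-length 1-D vectors")
    if predicted.size == 0:
        raise ValueError("empty input")
    if ci_method not in ("wilson", "exact"):
        raise ValueError(f"unknown ci_method {ci_method!r}")

    tp = int(np.sum(predicted & reference))
    fp = int(np.sum(predicted & ~reference))
    fn = int(np.sum(~predicted & reference))
    tn = int(np.sum(~predicted & ~reference))
    cm = ConfusionMatrix(tp=tp, fp=fp, fn=fn, tn=tn)

    a, b, c, d = (tp, fp, fn, tn)
    if haldane:
        a, b, c, d = (a + 0.5, b + 0.5, c + 0.5, d + 0.5)

    pos, neg = a + c, b + d
    sens = a / pos if pos else float("nan")
    spec = d / neg if neg else float("nan")
    sens_ci = _proportion_ci(tp, tp + fn, ci_method)
    spec_ci = _proportion_ci(tn, tn + fp, ci_method)

    plr_defined = spec < 1.0 and pos > 0 and neg > 0
    nlr_defined = spec > 0.0 and pos > 0 and neg > 0
    plr = sens / (1.0 - spec) if plr_defined else float("inf")
    nlr = (1.0 - sens) / spec if nlr_defined else float("nan")

    # Log-method standard errors (Simel et al. form); undefined with empty cells.
    if plr_defined and a > 0 and b > 0:
        se_plr = math.sqrt(1 / a - 1 / pos + 1 / b - 1 / neg)
        plr_ci = _lr_log_ci(plr, se_plr)
    else:
        plr_ci = (float("nan"), float("nan"))
    if nlr_defined and c > 0 and d > 0:
        se_nlr = math.sqrt(1 / c - 1 / pos + 1 / d - 1 / neg)
        nlr_ci = _lr_log_ci(nlr, se_nlr)
    else:
        nlr_ci = (float("nan"), float("nan"))

    summary = DiagnosticSummary(
        sensitivity=100.0 * sens,
        sensitivity_ci=sens_ci,
        specificity=100.0 * spec,
        specificity_ci=spec_ci,
        plr=plr,
        plr_ci=plr_ci,
        plr_defined=plr_defined,
        nlr=nlr,
        nlr_ci=nlr_ci,
        nlr_defined=nlr_defined,
        ci_method=ci_method,
    )
    return cm, summary


def bland_altman(x: np.ndarray, y: np.ndarray) -> BlandAltman:
    """Bland-Altman agreement on paired values, differences ``x - y``.

    Bias is the mean difference; limits of agreement are
    ``bias +/- 1.96 * SD`` of the differences (n-1 denominator).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D arrays")
    if x.size < 2:
        raise ValueError("Bland-Altman requires at least 2 pairs")
    d = x - y
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltman(
        bias=bias,
        loa_low=bias - 1.96 * sd,
        loa_high=bias + 1.96 * sd,
        sd_diff=sd,
        n=x.size,
    )


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> RocCurve:
    """ROC curve and AUC for a continuous score against boolean labels.

    All observed score values are swept as strict-'>' thresholds; AUC is
    the trapezoidal area, which with this sweep handles ties by rank
    midpoint (equivalent to the normalized Mann-Whitney statistic).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1-D arrays")
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")

    thresholds = np.concatenate(([np.inf], np.unique(scores)[::-1], [-np.inf]))
    tpr = np.empty(thresholds.size)
    fpr = np.empty(thresholds.size)
    for i, thr in enumerate(thresholds):
        pred = scores > thr
        tpr[i] = np.sum(pred & labels) / n_pos
        fpr[i] = np.sum(pred & ~labels) / n_neg
    auc = float(np.trapezoid(tpr, fpr))
    return RocCurve(fpr=fpr, tpr=tpr, thresholds=thresholds, auc=auc)
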