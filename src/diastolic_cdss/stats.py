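"""Agreement and diagnostic-performance statistics, from first principles.

These are the quantities used to validate a rule-based reader against an
expert reference: 2x2 confusion-matrix metrics, Cohen's kappa, the
two-way random-effects single-measure absolute-agreement intraclass
correlation ICC(2,1), ROC AUC via the Mann-Whitney U identity (midrank tie
handling, Hanley-McNeil normal-approximation CI), and the simple
concordance rate of primary classifications.

Degenerate inputs yield ``nan`` with an explanatory warning rather than a
silent zero: an undefined proportion (empty margin), kappa with expected
agreement 1, or ICC with no between-subject variance are reported as
undefined.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy.stats import norm, rankdata


class DegenerateInputWarning(UserWarning):
    pass


def _undefined(message: str) -> float:
    warnings.warn(message, DegenerateInputWarning, stacklevel=3)
    return math.nan


@dataclass(frozen=True)
class ConfusionMetrics:
    tp: int
    fp: int
    fn: int
    tn: int
    sensitivity: float  # %
    specificity: float  # %
    ppv: float  # %
    npv: float  # %


def confusion_metrics(pred: Sequence[int], truth: Sequence[int]) -> ConfusionMetrics:
    """Standard 2x2 metrics, in percent.  Division-by-zero cells are
    reported as ``nan`` (undefined), not 0."""
    pred = np.asarray(pred).astype(int)
    truth = np.asarray(truth).astype(int)
    if pred.shape != truth.shape:
        raise ValueError("pred and truth must have equal length")
    tp = int(np.sum((pred == 1) & (truth == 1)))
    fp = int(np.sum((pred == 1) & (truth == 0)))
    fn = int(np.sum((pred == 0) & (truth == 1)))
    tn = int(np.sum((pred == 0) & (truth == 0)))

    def pct(num: int, den: int, name: str) -> float:
        if den == 0:
            return _undefined(f"{name} undefined: empty denominator")
        return num / den * 100.0

    return ConfusionMetrics(
        tp=tp, fp=fp, fn=fn, tn=tn,
        sensitivity=pct(tp, tp + fn, "sensitivity"),
        specificity=pct(tn, tn + fp, "specificity"),
        ppv=pct(tp, tp + fp, "PPV"),
        npv=pct(tn, tn + fn, "NPV"))


def cohens_kappa(labels_a: Sequence, labels_b: Sequence) -> float:
    """Chance-corrected categorical agreement,
    kappa = (p_o - p_e) / (1 - p_e), with marginal-product expected
    agreement.  Invariant to label renaming."""
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape:
        raise ValueError("label vectors must have equal length")
    n = a.size
    if n == 0:
        return _undefined("kappa undefined on empty input")
    categories = np.unique(np.concatenate([a, b]))
    p_o = float(np.mean(a == b))
    p_e = 0.0
    for c in categories:
        p_e += float(np.mean(a == c)) * float(np.mean(b == c))
    if p_e == 1.0:
        return _undefined("kappa undefined: expected agreement is 1 "
                          "(degenerate marginals)")
    return (p_o - p_e) / (1.0 - p_e)


@dataclass(frozen=True)
class ICCResult:
    icc: float
    ms_rows: float  # between-subject mean square
    ms_cols: float  # between-rater mean square
    ms_error: float
    n_subjects: int
    n_raters: int


def icc_two_way(ratings: np.ndarray) -> ICCResult:
    """ICC(2,1): two-way random effects, absolute agreement, single
    measure, from the two-way ANOVA mean squares of a complete
    subjects x raters matrix."""
    x = np.asarray(ratings, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("ratings must be a subjects x raters matrix with "
                         ">=2 subjects and >=2 raters")
    if np.isnan(x).any():
        raise ValueError("ratings matrix must have no missing cells")
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)

    ss_rows = k * float(np.sum((row_means - grand) ** 2))
    ss_cols = n * float(np.sum((col_means - grand) ** 2))
    ss_total = float(np.sum((x - grand) ** 2))
    ss_error = ss_total - ss_rows - ss_cols

    ms_rows = ss_rows / (n - 1)
    ms_cols = ss_cols / (k - 1)
    ms_error = ss_error / ((n - 1) * (k - 1))

    denom = (ms_rows + (k - 1) * ms_error + k * (ms_cols - ms_error) / n)
    if math.isclose(ss_rows, 0.0, abs_tol=1e-12):
        warnings.warn("ICC reported as 0: zero between-subject variance",
                      DegenerateInputWarning, stacklevel=2)
        icc = 0.0
    elif denom == 0:
        icc = _undefined("ICC undefined: zero total variance")
    else:
        icc = (ms_rows - ms_error) / denom
    return ICCResult(icc=icc, ms_rows=ms_rows, ms_cols=ms_cols,
                     ms_error=ms_error, n_subjects=n, n_raters=k)


def roc_auc(
    scores: Sequence[float], truth: Sequence[int], alpha: float = 0.05
) -> Tuple[float, Tuple[float, float]]:
    """AUC by the Mann-Whitney U identity with midrank tie handling, and a
    Hanley-McNeil normal-approximation confidence interval.

    Higher scores must indicate the positive class.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(truth).astype(int)
    if s.shape != y.shape:
        raise ValueError("scores and truth must have equal length")
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")

    ranks = rankdata(s)  # midranks
    rank_sum_pos = float(np.sum(ranks[y == 1]))
    u = rank_sum_pos - n_pos * (n_pos + 1) / 2.0
    auc = u / (n_pos * n_neg)

    # Hanley & McNeil variance approximation
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc**2 / (1.0 + auc)
    var = (auc * (1 - auc)
           + (n_pos - 1) * (q1 - auc**2)
           + (n_neg - 1) * (q2 - auc**2)) / (n_pos * n_neg)
    se = math.sqrt(max(var, 0.0))
    z = float(norm.ppf(1.0 - alpha / 2.0))
    ci = (max(0.0, auc - z * se), min(1.0, auc + z * se))
    return auc, ci


def concordance(pred: Sequence, reference: Sequence) -> float:
    """Percent of studies whose primary classification matches."""
    p = np.asarray(pred)
    r = np.asarray(reference)
    if p.shape != r.shape:
        raise ValueError("prediction and reference must have equal length")
    if p.size == 0:
        return _undefined("concordance undefined on empty input")
    return float(np.mean(p == r)) * 100.0


def classify_hfpef(report_or_conclusion) -> int:
    """Binary HFpEF-likely classification from a conclusion or report:
    positive iff the HFpEF statement is present."""
    labels = getattr(report_or_conclusion, "labels", [])
    return int("HFpEF likely" in labels)


def primary_statement(report_or_conclusion) -> Optional[str]:
    stmts = getattr(report_or_conclusion, "statements", None)
    if stmts is None:
        stmts = getattr(report_or_conclusion, "conclusions", [])
    return stmts[0] if stmts else None
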