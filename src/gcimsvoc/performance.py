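"""ROC analysis, AUC inference and operating-point statistics.

All metrics are computed from pooled out-of-fold class probabilities.  The
AUC is the Mann–Whitney U statistic normalised by n_pos·n_neg (ties count
1/2); its 95% confidence interval uses the DeLong structural-component
variance estimate with a normal interval clipped to [0, 1]; the significance
of discrimination is the two-sided rank-sum test applied to the
probabilities between the two classes, which tests exactly AUC = 1/2.  The
reporting cutoff maximises Youden's J = sensitivity + specificity − 1 over
the observed probabilities, ties broken toward the lower cutoff, with the
prediction rule "probability ≥ cutoff → positive".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.metrics import roc_curve

from .selection import ranksum_pvalue

__all__ = ["PerformanceSummary", "roc_points", "auc", "auc_ci",
           "auc_pvalue", "operating_point", "summarize"]


@dataclass
class PerformanceSummary:
    """The per-comparison reporting row: AUC (CI), p, and cutoff metrics."""

    auc: float
    ci_low: float
    ci_high: float
    p_value: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    cutoff: float
    positive_class: str
    tp: int
    fp: int
    tn: int
    fn: int
    n_pos: int
    n_neg: int
    ci_degenerate: bool = False

    def to_dict(self) -> dict:
        return {
            "positive_class": self.positive_class,
            "n_pos": self.n_pos, "n_neg": self.n_neg,
            "auc": self.auc, "ci_low": self.ci_low, "ci_high": self.ci_high,
            "p_value": self.p_value,
            "p_rendered": render_pvalue(self.p_value),
            "cutoff": self.cutoff,
            "sensitivity": self.sensitivity, "specificity": self.specificity,
            "ppv": self.ppv, "npv": self.npv,
            "tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
            "ci_degenerate": self.ci_degenerate,
        }


def render_pvalue(p: float) -> str:
    """Report full precision but render tiny values as '<0.001'."""
    return "<0.001" if p < 0.001 else f"{p:.3f}"


def _validate(probs, y):
    probs = np.asarray(probs, dtype=float)
    y = np.asarray(y).astype(bool)
    if probs.size != y.size:
        raise ValueError("probs and labels differ in length")
    if y.all() or not y.any():
        raise ValueError("both classes must be present")
    return probs, y


def roc_points(probs, y) -> np.ndarray:
    """Ordered (FPR, TPR) pairs over all distinct thresholds.

    Starts at (0, 0), ends at (1, 1); monotone non-decreasing in both
    coordinates.
    """
    probs, y = _validate(probs, y)
    fpr, tpr, _ = roc_curve(y.astype(int), probs, drop_intermediate=False)
    return np.column_stack([fpr, tpr])


def auc(probs, y) -> float:
    """Probability that a positive outranks a negative (ties = 1/2)."""
    probs, y = _validate(probs, y)
    n_pos = int(y.sum())
    n_neg = y.size - n_pos
    ranks = stats.rankdata(probs)
    u = ranks[y].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def _delong_variance(probs: np.ndarray, y: np.ndarray) -> float:
    """DeLong variance of the AUC via placement values (midranks)."""
    pos = probs[y]
    neg = probs[~y]
    m, n = pos.size, neg.size
    # V10[i] = fraction of negatives below pos[i] (ties 1/2); V01 analogous
    v10 = np.array([(np.sum(p > neg) + 0.5 * np.sum(p == neg)) / n
                    for p in pos])
    v01 = np.array([(np.sum(pos > q) + 0.5 * np.sum(pos == q)) / m
                    for q in neg])
    s10 = np.var(v10, ddof=1) if m > 1 else 0.0
    s01 = np.var(v01, ddof=1) if n > 1 else 0.0
    return s10 / m + s01 / n


def auc_ci(probs, y, level: float = 0.95):
    """DeLong normal interval for the AUC, clipped to [0, 1].

    Returns ``(low, high, degenerate)``; ``degenerate`` flags a zero
    variance estimate (perfect or null separation), where the interval
    collapses to the point estimate.
    """
    probs, y = _validate(probs, y)
    if y.sum() < 2 or (~y).sum() < 2:
        raise ValueError("need at least two samples per class")
    a = auc(probs, y)
    var = _delong_variance(probs, y)
    if var <= 0:
        return a, a, True
    z = stats.norm.ppf(0.5 + level / 2.0)
    half = z * np.sqrt(var)
    return max(a - half, 0.0), min(a + half, 1.0), False


def auc_pvalue(probs, y) -> float:
    """Two-sided p for AUC ≠ 1/2: rank-sum test between the two classes'
    probabilities (the U-statistic identity makes the two hypotheses one).
    """
    probs, y = _validate(probs, y)
    return ranksum_pvalue(probs[y], probs[~y])


def _confusion(probs, y, cutoff):
    pred = probs >= cutoff
    tp = int(np.sum(pred & y))
    fp = int(np.sum(pred & ~y))
    tn = int(np.sum(~pred & ~y))
    fn = int(np.sum(~pred & y))
    return tp, fp, tn, fn


def _safe_div(a, b):
    return a / b if b else float("nan")


def operating_point(probs, y) -> dict:
    """Cutoff metrics at the Youden-optimal threshold.

    Candidate cutoffs are the observed probabilities; J = sens + spec − 1 is
    maximised and ties go to the lower cutoff.  PPV/NPV are NaN when no
    positive/negative call is made.
    """
    probs, y = _validate(probs, y)
    best = None
    for cutoff in np.unique(probs):          # ascending → lower wins ties
        tp, fp, tn, fn = _confusion(probs, y, cutoff)
        sens = tp / (tp + fn)
        spec = tn / (tn + fp)
        j = sens + spec - 1.0
        if best is None or j > best["j"] + 1e-12:
            best = {"j": j, "cutoff": float(cutoff), "tp": tp, "fp": fp,
                    "tn": tn, "fn": fn, "sensitivity": sens,
                    "specificity": spec,
                    "ppv": _safe_div(tp, tp + fp),
                    "npv": _safe_div(tn, tn + fn)}
    del best["j"]
    return best


def summarize(probs, labels, positive_class: str) -> PerformanceSummary:
    """Full reporting row from probabilities and group labels."""
    labels = np.asarray(labels)
    y = labels == positive_class
    probs, y = _validate(probs, y)
    a = auc(probs, y)
    low, high, degenerate = auc_ci(probs, y)
    op = operating_point(probs, y)
    return PerformanceSummary(
        auc=a, ci_low=low, ci_high=high, p_value=auc_pvalue(probs, y),
        sensitivity=op["sensitivity"], specificity=op["specificity"],
        ppv=op["ppv"], npv=op["npv"], cutoff=op["cutoff"],
        positive_class=positive_class,
        tp=op["tp"], fp=op["fp"], tn=op["tn"], fn=op["fn"],
        n_pos=int(y.sum()), n_neg=int((~y).sum()),
        ci_degenerate=degenerate,
    )
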