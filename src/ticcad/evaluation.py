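"""Cohort-level diagnostics: ROC analysis and rule-based malignancy calling.

The AUC is computed as the Mann–Whitney concordance probability with tie
correction, its standard error with the DeLong structural-components
estimator, and the operating point by maximizing Youden's J
(sensitivity + specificity − 100) over all observed scores, with the
criterion direction chosen so the reported AUC is at least 0.5 (as ROC
software conventionally reports, e.g. "> c" vs "<= c" criteria).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import FormatError

BENIGN = "benign"
MALIGNANT = "malignant"


@dataclass
class LabeledScores:
    """Per-case scores with benign/malignant truth labels; NaNs are dropped."""

    scores: np.ndarray
    labels: np.ndarray
    n_dropped: int = 0

    @classmethod
    def from_arrays(cls, scores, labels) -> "LabeledScores":
        scores = np.asarray(scores, dtype=float)
        labels = np.asarray(labels, dtype=object)
        if scores.shape != labels.shape:
            raise FormatError("scores and labels must have equal length")
        bad = set(labels) - {BENIGN, MALIGNANT}
        if bad:
            raise FormatError(f"unknown labels: {sorted(map(str, bad))}")
        keep = np.isfinite(scores)
        out = cls(scores=scores[keep], labels=labels[keep], n_dropped=int((~keep).sum()))
        if out.pos.size < 1 or out.neg.size < 1:
            raise FormatError("need at least one case per class after NaN removal")
        return out

    @property
    def pos(self) -> np.ndarray:
        """Malignant-case scores."""
        return self.scores[self.labels == MALIGNANT]

    @property
    def neg(self) -> np.ndarray:
        """Benign-case scores."""
        return self.scores[self.labels == BENIGN]


@dataclass
class ConfusionMetrics:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def sensitivity(self) -> float:
        return 100.0 * self.tp / (self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return 100.0 * self.tn / (self.tn + self.fp)

    @property
    def accuracy(self) -> float:
        return 100.0 * (self.tp + self.tn) / self.n

    @property
    def youden_j(self) -> float:
        return self.sensitivity + self.specificity - 100.0


@dataclass
class RocResult:
    """ROC summary: AUC with DeLong SE/CI plus the Youden-optimal criterion.

    ``direction`` is ``"gt"`` (malignant iff score > cutoff) or ``"le"``
    (malignant iff score <= cutoff); sensitivity/specificity/accuracy are
    percentages at that criterion.
    """

    auc: float
    se: float
    ci95: tuple[float, float]
    direction: str
    cutoff: float
    sensitivity: float
    specificity: float
    accuracy: float
    n_pos: int
    n_neg: int
    n_dropped: int = 0


def auc(ls: LabeledScores, positive_high: bool = True) -> float:
    """Mann–Whitney AUC: (concordant + 0.5·tied pairs) / (n_pos·n_neg)."""
    pos, neg = ls.pos, ls.neg
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    r_pos = ranks[: len(pos)].sum()
    a = (r_pos - len(pos) * (len(pos) + 1) / 2.0) / (len(pos) * len(neg))
    return float(a if positive_high else 1.0 - a)


def _delong_components(pos: np.ndarray, neg: np.ndarray):
    psi = (pos[:, None] > neg[None, :]).astype(float)
    psi += 0.5 * (pos[:, None] == neg[None, :])
    return psi.mean(axis=1), psi.mean(axis=0), psi.mean()


def auc_se(ls: LabeledScores) -> float:
    """DeLong structural-components standard error of the AUC."""
    pos, neg = ls.pos, ls.neg
    if len(pos) < 3 or len(neg) < 3:
        raise FormatError("DeLong SE needs at least 3 cases per class")
    v10, v01, _ = _delong_components(pos, neg)
    var = v10.var(ddof=1) / len(pos) + v01.var(ddof=1) / len(neg)
    return float(math.sqrt(max(var, 0.0)))


def optimal_cutoff(ls: LabeledScores) -> RocResult:
    """Youden-optimal operating point with data-driven criterion direction.

    If the raw AUC (high scores = malignant) is below 0.5 the criterion is
    flipped to "<= c" and the complementary AUC reported.  Candidate cutoffs
    are the distinct observed scores; J ties are broken by higher
    sensitivity, then by smaller ``|c|``.
    """
    raw = auc(ls, positive_high=True)
    direction = "gt" if raw >= 0.5 else "le"
    reported_auc = raw if raw >= 0.5 else 1.0 - raw
    se = auc_se(ls) if min(len(ls.pos), len(ls.neg)) >= 3 else math.nan
    candidates = np.unique(ls.scores)
    best = None
    for c in candidates:
        if direction == "gt":
            calls = ls.scores > c
        else:
            calls = ls.scores <= c
        cm = confusion_metrics(
            np.where(calls, MALIGNANT, BENIGN), ls.labels
        )
        key = (cm.youden_j, cm.sensitivity, -abs(c))
        if best is None or key > best[0]:
            best = (key, c, cm)
    _, cutoff, cm = best
    lo = max(0.0, reported_auc - 1.96 * se) if np.isfinite(se) else math.nan
    hi = min(1.0, reported_auc + 1.96 * se) if np.isfinite(se) else math.nan
    return RocResult(
        auc=reported_auc,
        se=se,
        ci95=(lo, hi),
        direction=direction,
        cutoff=float(cutoff),
        sensitivity=cm.sensitivity,
        specificity=cm.specificity,
        accuracy=cm.accuracy,
        n_pos=len(ls.pos),
        n_neg=len(ls.neg),
        n_dropped=ls.n_dropped,
    )


def malignancy_from_type(tic_type: str | None) -> str | None:
    """Curve-type rule: plateau/washout (II, III) called malignant, I benign."""
    if tic_type is None:
        return None
    if tic_type in ("II", "III"):
        return MALIGNANT
    if tic_type == "I":
        return BENIGN
    raise FormatError(f"unknown TIC type {tic_type!r}")


def confusion_metrics(calls, truth) -> ConfusionMetrics:
    calls = np.asarray(calls, dtype=object)
    truth = np.asarray(truth, dtype=object)
    if calls.shape != truth.shape:
        raise FormatError("calls and truth must have equal length")
    if not ((truth == BENIGN).any() and (truth == MALIGNANT).any()):
        raise FormatError("both truth classes must be present")
    tp = int(((calls == MALIGNANT) & (truth == MALIGNANT)).sum())
    fp = int(((calls == MALIGNANT) & (truth == BENIGN)).sum())
    tn = int(((calls == BENIGN) & (truth == BENIGN)).sum())
    fn = int(((calls == BENIGN) & (truth == MALIGNANT)).sum())
    return ConfusionMetrics(tp=tp, fp=fp, tn=tn, fn=fn)


def composition_summary(category_counts) -> pd.DataFrame:
    """Percent composition of a cohort from (label, count) pairs."""
    labels = [lab for lab, _ in category_counts]
    counts = np.asarray([c for _, c in category_counts], dtype=float)
    if np.any(counts < 0):
        raise FormatError("counts must be non-negative")
    total = counts.sum()
    if total <= 0:
        raise FormatError("total count must be positive")
    return pd.DataFrame(
        {"label": labels, "count": counts.astype(int), "percent": 100.0 * counts / total}
    )


def dice_coefficient(a: np.ndarray, b: np.ndarray) -> float:
    """Overlap 2|A∩B| / (|A|+|B|) between two binary masks."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return math.nan
    return 2.0 * float((a & b).sum()) / float(denom)


def roc_row(param: str, pathway: str, r: RocResult) -> dict:
    """Flatten a RocResult for CSV reporting."""
    return {
        "param": param,
        "pathway": pathway,
        "auc": r.auc,
        "se": r.se,
        "ci_lo": r.ci95[0],
        "ci_hi": r.ci95[1],
        "direction": r.direction,
        "cutoff": r.cutoff,
        "sensitivity": round(r.sensitivity, 2),
        "specificity": round(r.specificity, 2),
        "accuracy": round(r.accuracy, 2),
        "n_pos": r.n_pos,
        "n_neg": r.n_neg,
        "n_dropped": r.n_dropped,
    }
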