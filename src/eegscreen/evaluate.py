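"""Subject aggregation (majority vote) and every reported performance metric.

All metrics are computed at full precision; percentage rounding (2 d.p.)
happens only in the report helpers.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import ConfigurationError, GROUPS


@dataclass
class ConfusionMatrix3:
    """K x K actual-vs-predicted counts (rows actual) in fixed class order."""

    counts: np.ndarray
    classes: tuple[str, ...] = GROUPS
    level: str = "subject"

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        k = len(self.classes)
        if self.counts.shape != (k, k):
            raise ConfigurationError("counts shape must match class count")
        if np.any(self.counts < 0) or self.counts.sum() == 0:
            raise ConfigurationError("counts must be non-negative, total > 0")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class KappaScore:
    kappa: float
    observed_agreement: float
    chance_agreement: float


@dataclass
class BinaryMetrics:
    """Se/Sp/Acc/PPV/NPV (percent) of a one-vs-all collapse.

    Ratios with a zero denominator are NaN and listed in `undefined`.
    """

    comparison: str
    positive_classes: tuple[str, ...]
    se: float
    sp: float
    acc: float
    ppv: float
    npv: float
    undefined: list[str] = field(default_factory=list)

    def rounded(self) -> dict[str, float]:
        return {k: round(getattr(self, k), 2)
                for k in ("se", "sp", "acc", "ppv", "npv")}


def majority_vote(trial_labels, posteriors: pd.DataFrame | None = None) -> str:
    """Most frequent trial label of one subject.

    Ties are broken by the highest mean posterior over the tied classes when
    posteriors are given (a warning is logged), else by canonical class order.
    """
    labels = list(trial_labels)
    if not labels:
        raise ValueError("subject has no trials")
    counts: dict[str, int] = {}
    for lab in labels:
        counts[lab] = counts.get(lab, 0) + 1
    top = max(counts.values())
    tied = [c for c, n in counts.items() if n == top]
    if len(tied) == 1:
        return tied[0]
    if posteriors is not None:
        means = posteriors[tied].mean(axis=0)
        winner = str(means.idxmax())
    else:
        order = [g for g in GROUPS if g in tied] + sorted(set(tied) - set(GROUPS))
        winner = order[0]
    warnings.warn(f"majority-vote tie between {sorted(tied)}; chose {winner}")
    return winner


def subject_votes(trials: pd.DataFrame, label_col: str = "predicted",
                  posterior_cols: tuple[str, ...] | None = None) -> pd.DataFrame:
    """Collapse a per-trial prediction table to one row per subject."""
    rows = []
    for sid, grp in trials.groupby("subject_id", sort=False):
        post = grp[list(posterior_cols)] if posterior_cols else None
        rows.append({"subject_id": sid, "group": grp["group"].iloc[0],
                     "predicted": majority_vote(grp[label_col], post)})
    return pd.DataFrame(rows)


def confusion_matrix3(actual, predicted, level: str = "subject",
                      classes: tuple[str, ...] | None = None) -> ConfusionMatrix3:
    """Counts[i, j] = #(actual = class_i, predicted = class_j)."""
    actual = np.asarray(actual, dtype=object)
    predicted = np.asarray(predicted, dtype=object)
    if actual.shape != predicted.shape:
        raise ValueError("actual and predicted must have equal length")
    classes = tuple(classes) if classes is not None else GROUPS
    index = {c: i for i, c in enumerate(classes)}
    unknown = set(actual) | set(predicted) - set(classes)
    unknown -= set(classes)
    if unknown:
        raise ConfigurationError(f"unknown label(s): {sorted(unknown)}")
    k = len(classes)
    counts = np.zeros((k, k), dtype=int)
    for a, p in zip(actual, predicted):
        counts[index[a], index[p]] += 1
    return ConfusionMatrix3(counts=counts, classes=classes, level=level)


def cohens_kappa(cm: ConfusionMatrix3) -> KappaScore:
    """Chance-corrected agreement from the confusion matrix marginals."""
    n = cm.total
    p_o = np.trace(cm.counts) / n
    p_e = float(cm.counts.sum(axis=1) @ cm.counts.sum(axis=0)) / n ** 2
    if p_e >= 1.0:
        raise ConfigurationError("chance agreement is 1: kappa undefined")
    return KappaScore(kappa=(p_o - p_e) / (1.0 - p_e),
                      observed_agreement=float(p_o),
                      chance_agreement=float(p_e))


def overall_accuracy(cm: ConfusionMatrix3) -> float:
    """Percentage of correctly classified units (trace / total)."""
    return 100.0 * float(np.trace(cm.counts)) / cm.total


_COMPARISONS = {
    # comparison -> positive classes.  "HC_vs_all": positive = impaired.
    "HC_vs_all": ("MCI", "AD"),
    "AD_vs_all": ("AD",),
}


def one_vs_all_metrics(cm: ConfusionMatrix3, comparison: str) -> BinaryMetrics:
    """Collapse the 3x3 matrix to 2x2 and report Se/Sp/Acc/PPV/NPV (%)."""
    if comparison not in _COMPARISONS:
        raise ConfigurationError(
            f"comparison must be one of {sorted(_COMPARISONS)}")
    positive = _COMPARISONS[comparison]
    pos = np.array([c in positive for c in cm.classes])
    c = cm.counts
    tp = int(c[np.ix_(pos, pos)].sum())
    fn = int(c[np.ix_(pos, ~pos)].sum())
    fp = int(c[np.ix_(~pos, pos)].sum())
    tn = int(c[np.ix_(~pos, ~pos)].sum())
    assert tp + fn + fp + tn == cm.total  # collapse conserves totals

    undefined: list[str] = []

    def ratio(num: int, den: int, name: str) -> float:
        if den == 0:
            undefined.append(name)
            return math.nan
        return 100.0 * num / den

    return BinaryMetrics(
        comparison=comparison, positive_classes=positive,
        se=ratio(tp, tp + fn, "se"), sp=ratio(tn, tn + fp, "sp"),
        acc=ratio(tp + tn, cm.total, "acc"),
        ppv=ratio(tp, tp + fp, "ppv"), npv=ratio(tn, tn + fn, "npv"),
        undefined=undefined)


def model_report(cm_trial: ConfusionMatrix3 | None,
                 cm_subject: ConfusionMatrix3) -> dict:
    """All reported statistics of one model as a JSON-ready dict."""
    kappa = cohens_kappa(cm_subject)
    report = {
        "subject_confusion": cm_subject.counts.tolist(),
        "overall_accuracy": round(overall_accuracy(cm_subject), 2),
        "kappa": round(kappa.kappa, 4),
        "one_vs_all": {comp: one_vs_all_metrics(cm_subject, comp).rounded()
                       for comp in _COMPARISONS},
    }
    if cm_trial is not None:
        report["trial_confusion"] = cm_trial.counts.tolist()
        report["trial_overall_accuracy"] = round(overall_accuracy(cm_trial), 2)
        report["trial_kappa"] = round(cohens_kappa(cm_trial).kappa, 4)
    return report
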