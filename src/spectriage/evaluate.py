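"""Diagnostic-performance statistics.

Confusion counts, sensitivity/specificity, ROC curves by threshold sweep with
trapezoidal AUC (identical to the Mann-Whitney pair probability with ties
counted 1/2), prevalence-adjusted PPV/NPV via Bayes' rule, subtype detection
tables, PPV fold-improvement ratios, and permutation feature importance over
wavenumber bins.

Reported percentages are rounded half-away-from-zero to one decimal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .consensus import ConsensusRule, patient_predictions
from .preprocess import FeatureMatrix
from .pls import PlsModel
from .simulate import PatientRecord


def round_half_away(x: float, decimals: int = 1) -> float:
    """Round half away from zero (the convention of printed percentages)."""
    factor = 10.0 ** decimals
    return float(np.sign(x) * np.floor(abs(x) * factor + 0.5) / factor)


def as_percent(fraction: float, decimals: int = 1) -> float:
    """Fraction -> percentage rounded half-away-from-zero."""
    return round_half_away(100.0 * fraction, decimals)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be >= 0")

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp)


@dataclass(frozen=True)
class OperatingPoint:
    threshold: float
    sensitivity: float
    specificity: float


@dataclass(frozen=True)
class RocResult:
    points: list[OperatingPoint]   # sorted by threshold
    auc: float


def _binary(labels) -> np.ndarray:
    labels = np.asarray(labels)
    if labels.dtype.kind in "UO":
        known = np.isin(labels, ("positive", "negative"))
        if not np.all(known):
            raise ValueError("labels must be 'positive'/'negative'")
        return (labels == "positive").astype(int)
    return labels.astype(int)


def confusion(calls, labels) -> ConfusionCounts:
    """Tally patient-level calls against true labels."""
    c = _binary(calls)
    y = _binary(labels)
    if c.size != y.size:
        raise ValueError("calls and labels lengths differ")
    return ConfusionCounts(
        tp=int(np.sum((c == 1) & (y == 1))),
        fp=int(np.sum((c == 1) & (y == 0))),
        tn=int(np.sum((c == 0) & (y == 0))),
        fn=int(np.sum((c == 0) & (y == 1))))


def roc_curve(scores, labels) -> RocResult:
    """ROC by sweeping the call threshold over every distinct score (and +inf).

    A sample is called positive iff score >= threshold. The AUC is the
    trapezoidal area over (1 - specificity, sensitivity), which equals the
    Mann-Whitney probability P(score_pos > score_neg) + 1/2 P(equal).
    """
    s = np.asarray(scores, dtype=float)
    y = _binary(labels)
    n_pos = int(y.sum())
    n_neg = int(y.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present for a ROC curve")
    thresholds = np.concatenate([np.unique(s), [np.inf]])
    points = []
    for t in thresholds:
        calls = s >= t
        sens = float(np.sum(calls & (y == 1))) / n_pos
        spec = float(np.sum(~calls & (y == 0))) / n_neg
        points.append(OperatingPoint(float(t), sens, spec))
    fpr = np.array([1.0 - p.specificity for p in points])
    tpr = np.array([p.sensitivity for p in points])
    order = np.lexsort((tpr, fpr))  # ties in FPR must keep TPR ascending
    auc = float(np.trapezoid(tpr[order], fpr[order]))
    return RocResult(points=points, auc=auc)


def ppv(sensitivity: float, specificity: float, prevalence: float) -> float:
    """Positive predictive value: sens*prev / (sens*prev + (1-spec)(1-prev))."""
    _check_unit_interval(sensitivity, specificity, prevalence)
    num = sensitivity * prevalence
    den = num + (1.0 - specificity) * (1.0 - prevalence)
    if den == 0:
        raise ZeroDivisionError("PPV undefined: no positive calls expected")
    return num / den


def npv(sensitivity: float, specificity: float, prevalence: float) -> float:
    """Negative predictive value: spec(1-prev) / (spec(1-prev) + (1-sens)prev)."""
    _check_unit_interval(sensitivity, specificity, prevalence)
    num = specificity * (1.0 - prevalence)
    den = num + (1.0 - sensitivity) * prevalence
    if den == 0:
        raise ZeroDivisionError("NPV undefined: no negative calls expected")
    return num / den


def _check_unit_interval(*values: float) -> None:
    for v in values:
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"value {v} outside [0, 1]")


def fold_improvement(ppv_test: float, ppv_comparator: float) -> float:
    """Ratio of test PPV to a comparator PPV."""
    if ppv_comparator <= 0:
        raise ValueError("comparator PPV must be > 0")
    return ppv_test / ppv_comparator


@dataclass(frozen=True)
class SubtypeDetection:
    subtype: str
    actual: int
    identified: int

    @property
    def detection_rate(self) -> float:
        return 100.0 * self.identified / self.actual


def detection_table(calls, labels, subtypes) -> pd.DataFrame:
    """Per-subtype detection rates among true positives, plus a TOTAL row."""
    c = _binary(calls)
    y = _binary(labels)
    subtypes = np.asarray(subtypes, dtype=object)
    pos = y == 1
    if np.any(pd.isna(subtypes[pos])):
        raise ValueError("every positive patient must have a subtype")
    rows = []
    # preserve first-appearance order of subtypes among positives
    seen: list[str] = []
    for s in subtypes[pos]:
        if s not in seen:
            seen.append(s)
    for s in seen:
        mask = pos & (subtypes == s)
        actual = int(mask.sum())
        identified = int(np.sum(c[mask] == 1))
        rows.append({"subtype": s, "actual": actual, "identified": identified,
                     "detection_rate": round_half_away(
                         100.0 * identified / actual, 1)})
    total_actual = int(pos.sum())
    total_identified = int(np.sum(c[pos] == 1))
    rows.append({"subtype": "TOTAL", "actual": total_actual,
                 "identified": total_identified,
                 "detection_rate": round_half_away(
                     100.0 * total_identified / max(total_actual, 1), 1)})
    return pd.DataFrame(rows)


def make_bins(high_wn: float, low_wn: float, width: float) -> list[tuple[float, float]]:
    """Contiguous (high, low) wavenumber bins partitioning [low_wn, high_wn]."""
    edges = np.arange(high_wn, low_wn - 1e-9, -width)
    edges = np.append(edges, low_wn) if edges[-1] > low_wn else edges
    return [(float(edges[i]), float(edges[i + 1])) for i in range(len(edges) - 1)]


def permutation_importance(model: PlsModel,
                           records: list[PatientRecord],
                           features: FeatureMatrix,
                           threshold: float,
                           wavenumber_bins: list[tuple[float, float]],
                           rule: ConsensusRule = ConsensusRule(),
                           n_repeats: int = 5,
                           seed: int = 0) -> pd.DataFrame:
    """Permutation importance of wavenumber bins for patient-level AUC.

    For each bin, the bin's feature columns are jointly permuted across
    spectra and the drop in patient-level AUC (positive-replicate-fraction
    score) relative to the unpermuted baseline is averaged over `n_repeats`
    permutations. Bins must partition the feature range exactly.
    """
    wn = features.wavenumbers
    covered = np.zeros(wn.size, dtype=int)
    masks = []
    for i, (hi, lo) in enumerate(wavenumber_bins):
        last = i == len(wavenumber_bins) - 1
        m = (wn <= hi + 1e-9) & ((wn >= lo - 1e-9) if last else (wn > lo + 1e-9))
        masks.append(m)
        covered += m
    if not np.all(covered == 1):
        raise ValueError("wavenumber_bins must partition the feature range")

    labels = [r.label for r in records]
    base = patient_predictions(records, model, threshold, rule=rule,
                               features=features)
    base_auc = roc_curve(base["score"], labels).auc
    rng = np.random.default_rng(seed)
    rows = []
    for (hi, lo), m in zip(wavenumber_bins, masks):
        drops = []
        for _ in range(n_repeats):
            perm = rng.permutation(features.n_spectra)
            Xp = features.X.copy()
            Xp[:, m] = Xp[perm][:, m]
            fm = FeatureMatrix(
                X=Xp, wavenumbers=wn, spectrum_ids=features.spectrum_ids,
                patient_ids=features.patient_ids, labels=features.labels,
                qc_pass=features.qc_pass, qc_report=features.qc_report)
            pred = patient_predictions(records, model, threshold, rule=rule,
                                       features=fm)
            drops.append(base_auc - roc_curve(pred["score"], labels).auc)
        rows.append({"bin_high_wn": hi, "bin_low_wn": lo,
                     "importance": float(np.mean(drops))})
    return pd.DataFrame(rows)
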