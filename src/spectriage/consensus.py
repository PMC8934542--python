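"""Replicate-consensus patient calls: positive iff >= 5 of 9 replicate calls.

With the full 9-replicate design the default rule is an odd-majority vote, so
ties are impossible. Patients with fewer usable replicates (QC failures) are
handled by a short-set policy: "proportional" preserves the 5/9 operating
fraction, "strict" keeps the absolute >= 5 count. Patients with zero usable
spectra get an "indeterminate" call and are reported separately rather than
silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import constants
from .preprocess import FeatureMatrix, PreprocessConfig, preprocess_cohort
from .pls import PlsModel, predict_proba
from .simulate import PatientRecord


@dataclass(frozen=True)
class ConsensusRule:
    min_positive: int = constants.CONSENSUS_MIN_POSITIVE
    expected_replicates: int = constants.REPLICATES_PER_PATIENT
    short_set_policy: str = "proportional"   # proportional | strict

    def __post_init__(self) -> None:
        if not 1 <= self.min_positive <= self.expected_replicates:
            raise ValueError(
                "min_positive must be in [1, expected_replicates]")
        if self.short_set_policy not in ("proportional", "strict"):
            raise ValueError(
                f"unknown short_set_policy {self.short_set_policy!r}")


def consensus_call(spectrum_calls, rule: ConsensusRule = ConsensusRule()) -> str:
    """Patient-level call from replicate-level calls.

    `spectrum_calls` is a sequence of "positive"/"negative" strings or booleans.
    """
    calls = list(spectrum_calls)
    if not calls:
        raise ValueError("empty call list")
    n_pos = sum(1 for c in calls
                if (c == "positive" if isinstance(c, str) else bool(c)))
    n = len(calls)
    if n >= rule.expected_replicates or rule.short_set_policy == "strict":
        positive = n_pos >= rule.min_positive
    else:
        positive = (n_pos / n) >= (rule.min_positive / rule.expected_replicates)
    return "positive" if positive else "negative"


def patient_predictions(records: list[PatientRecord],
                        model: PlsModel,
                        threshold: float,
                        preprocess_cfg: PreprocessConfig = PreprocessConfig(),
                        rule: ConsensusRule = ConsensusRule(),
                        features: FeatureMatrix | None = None,
                        score_kind: str = "fraction") -> pd.DataFrame:
    """Per-patient consensus calls plus a continuous patient score.

    A replicate is called positive iff its predicted probability >= threshold.
    The patient score retained for ROC construction is, by default, the
    positive-replicate fraction at that threshold ("fraction"); alternatively
    the median per-spectrum probability ("median_prob").

    Returns a DataFrame with columns patient_id, call, score, n_replicates,
    n_positive, n_qc_failed.
    """
    if score_kind not in ("fraction", "median_prob"):
        raise ValueError(f"unknown score_kind {score_kind!r}")
    fm = features if features is not None else preprocess_cohort(
        records, preprocess_cfg)
    probs = predict_proba(model, fm.X)
    rows = []
    for rec in records:
        idx = np.flatnonzero(fm.patient_ids == rec.patient_id)
        ok = idx[fm.qc_pass[idx]]
        n_failed = int(idx.size - ok.size)
        if ok.size == 0:
            rows.append({"patient_id": rec.patient_id, "call": "indeterminate",
                         "score": np.nan, "n_replicates": 0,
                         "n_positive": 0, "n_qc_failed": n_failed})
            continue
        p = probs[ok]
        calls = p >= threshold
        call = consensus_call(list(calls), rule)
        score = (float(calls.mean()) if score_kind == "fraction"
                 else float(np.median(p)))
        rows.append({"patient_id": rec.patient_id, "call": call,
                     "score": score, "n_replicates": int(ok.size),
                     "n_positive": int(calls.sum()), "n_qc_failed": n_failed})
    return pd.DataFrame(rows)
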