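"""Population-scale triage model: expected confusion counts for a screening
population, imaging scans avoided, cost savings under UK (GBP) and US (USD)
scan-cost models, and benchmarking against symptom-based referral criteria.

Two savings modes are provided. "printed_reconciliation" (default,
savings = tn x (ct_cost + mri_cost)) is the formula singled out by
:func:`reconcile_savings_formula`, which checks a candidate set against the
published scenario figures and finds exactly one match. "half_imaging"
implements the stated assumption that half of negative-test patients still
undergo imaging: savings = (1 - negative_imaging_fraction) x (tn + fn) x
(ct_cost + mri_cost); it is kept for prospective scenario analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import constants
from .evaluate import fold_improvement, round_half_away


@dataclass(frozen=True)
class TriageScenario:
    population: int = constants.TRIAGE_POPULATION
    prevalence: float = constants.TRIAGE_PREVALENCE
    operating_point: tuple[float, float] = constants.SENSITIVITY_TUNED_POINT

    def __post_init__(self) -> None:
        if self.population <= 0:
            raise ValueError("population must be > 0")
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError("prevalence must be in (0, 1)")
        sens, spec = self.operating_point
        if not (0.0 <= sens <= 1.0 and 0.0 <= spec <= 1.0):
            raise ValueError("operating point must lie in [0, 1]^2")


@dataclass(frozen=True)
class CostModel:
    ct_cost: float
    mri_cost: float
    currency: str = "GBP"
    negative_imaging_fraction: float = constants.NEGATIVE_IMAGING_FRACTION

    def __post_init__(self) -> None:
        if self.ct_cost < 0 or self.mri_cost < 0:
            raise ValueError("scan costs must be >= 0")
        if not 0.0 <= self.negative_imaging_fraction <= 1.0:
            raise ValueError("negative_imaging_fraction must be in [0, 1]")
        if self.currency not in ("GBP", "USD"):
            raise ValueError("currency must be GBP or USD")

    @classmethod
    def uk(cls) -> "CostModel":
        ct, mri = constants.SCAN_COSTS["GBP"]
        return cls(ct_cost=ct, mri_cost=mri, currency="GBP")

    @classmethod
    def us(cls) -> "CostModel":
        ct, mri = constants.SCAN_COSTS["USD"]
        return cls(ct_cost=ct, mri_cost=mri, currency="USD")


@dataclass(frozen=True)
class TriageOutcome:
    tp: int
    fn: int
    tn: int
    fp: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.tn, self.fp) < 0:
            raise ValueError("counts must be >= 0")

    @property
    def population(self) -> int:
        return self.tp + self.fn + self.tn + self.fp


def expected_counts(scenario: TriageScenario) -> TriageOutcome:
    """Expected confusion counts for the screening population.

    tp = round(pop * prev * sens) (half away from zero), fn its complement in
    the diseased stratum; tn = round(pop * (1-prev) * spec), fp its complement
    — so the four counts always partition the population.
    """
    sens, spec = scenario.operating_point
    n_pos = scenario.population * scenario.prevalence
    n_neg = scenario.population - n_pos
    tp = int(round_half_away(n_pos * sens, 0))
    tn = int(round_half_away(n_neg * spec, 0))
    return TriageOutcome(tp=tp, fn=int(round(n_pos)) - tp,
                         tn=tn, fp=int(round(n_neg)) - tn)


def scans_avoided(outcome: TriageOutcome, mode: str = "printed_reconciliation") -> int:
    """Number of patients whose imaging is avoided under the savings mode."""
    if mode == "printed_reconciliation":
        return outcome.tn
    if mode == "half_imaging":
        return int(round_half_away(
            (1.0 - constants.NEGATIVE_IMAGING_FRACTION)
            * (outcome.tn + outcome.fn), 0))
    raise ValueError(f"unknown mode {mode!r}")


def cost_savings(outcome: TriageOutcome, cost_model: CostModel,
                 mode: str = "printed_reconciliation") -> float:
    """Imaging cost saved for the population, in the cost model's currency."""
    per_patient = cost_model.ct_cost + cost_model.mri_cost
    if mode == "printed_reconciliation":
        return outcome.tn * per_patient
    if mode == "half_imaging":
        return ((1.0 - cost_model.negative_imaging_fraction)
                * (outcome.tn + outcome.fn) * per_patient)
    raise ValueError(f"unknown mode {mode!r}")


#: candidate generative formulas for the published savings figures
_CANDIDATE_FORMULAS = {
    "tn*(ct+mri)": lambda tn, fn, ct, mri: tn * (ct + mri),
    "half*(tn+fn)*(ct+mri)": lambda tn, fn, ct, mri: 0.5 * (tn + fn) * (ct + mri),
    "(tn+fn)*(ct+mri)": lambda tn, fn, ct, mri: (tn + fn) * (ct + mri),
    "half*(tn+fn)*2*(ct+mri)": lambda tn, fn, ct, mri: 0.5 * (tn + fn) * 2 * (ct + mri),
}

#: published savings for (operating point, currency): value to reproduce
_PUBLISHED_SAVINGS = {
    (constants.SENSITIVITY_TUNED_POINT, "GBP"): 1_136_025.0,
    (constants.SENSITIVITY_TUNED_POINT, "USD"): 11_248_875.0,
    (constants.SPECIFICITY_TUNED_POINT, "GBP"): 2_272_050.0,
    (constants.SPECIFICITY_TUNED_POINT, "USD"): 22_497_750.0,
}


def reconcile_savings_formula() -> str:
    """Identify which candidate formula reproduces all published savings.

    Evaluates each candidate on the expected counts of the 10,000-patient /
    1% prevalence scenario at both operating points and both currencies;
    exactly one candidate must match all four published figures, and its name
    is returned. Raises if zero or multiple candidates survive.
    """
    matches = []
    for name, f in _CANDIDATE_FORMULAS.items():
        ok = True
        for (point, currency), target in _PUBLISHED_SAVINGS.items():
            out = expected_counts(TriageScenario(operating_point=point))
            ct, mri = constants.SCAN_COSTS[currency]
            if abs(f(out.tn, out.fn, ct, mri) - target) > 0.5:
                ok = False
                break
        if ok:
            matches.append(name)
    if len(matches) != 1:
        raise RuntimeError(
            f"savings reconciliation did not single out one formula: {matches}")
    return matches[0]


def comparator_report(test_ppv: float) -> pd.DataFrame:
    """Fold-improvement of the test's PPV over published referral benchmarks."""
    rows = []
    for name, cppv in constants.COMPARATOR_PPV.items():
        rows.append({
            "comparator": name,
            "comparator_ppv_pct": round_half_away(100.0 * cppv, 1),
            "test_ppv_pct": round_half_away(100.0 * test_ppv, 1),
            "fold_improvement": fold_improvement(test_ppv, cppv),
        })
    return pd.DataFrame(rows)


def timely_diagnosis_comparison(scenario: TriageScenario,
                                comparator_sensitivity: float) -> dict[str, int]:
    """Tumor patients diagnosed in time under the test vs a symptom comparator.

    The comparator count is round(pop * prev * comparator_sens); the test
    count is the scenario's expected true positives.
    """
    if not 0.0 <= comparator_sensitivity <= 1.0:
        raise ValueError("comparator sensitivity must be in [0, 1]")
    n_pos = scenario.population * scenario.prevalence
    return {
        "test": expected_counts(scenario).tp,
        "comparator": int(round_half_away(n_pos * comparator_sensitivity, 0)),
    }
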