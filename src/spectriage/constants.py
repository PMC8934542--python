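"""Study-design constants and published reference values used across the package.

Everything here is an *input* to the pipeline: the replicate design of the
assay, the validation-cohort composition, the reference operating points of the
sensitivity- and specificity-tuned algorithms, imaging costs, and published
symptom-based referral benchmarks used for comparator reporting.
"""

from __future__ import annotations

# ---------------------------------------------------------------- assay design
WELLS_PER_PATIENT = 3          # serum deposited on three sample wells
SPECTRA_PER_WELL = 3           # three acquisitions per well
REPLICATES_PER_PATIENT = WELLS_PER_PATIENT * SPECTRA_PER_WELL  # = 9

CONSENSUS_MIN_POSITIVE = 5     # patient positive iff >= 5 of 9 replicate calls

SPECTRAL_RESOLUTION_CM1 = 4.0  # instrument resolution
DATA_SPACING_CM1 = 1.0         # wavenumber grid spacing

# ------------------------------------------------------- model-selection design
N_OUTER_SPLITS = 51            # repeated train-test splits
N_INNER_FOLDS = 5              # inner CV folds for hyperparameter/threshold tuning

# ------------------------------------------------------------ validation cohort
COHORT_SIZE = 603
COHORT_POSITIVES = 47
COHORT_PREVALENCE = 0.078

#: tumor-type composition of the 47 positives in the validation cohort
SUBTYPE_COUNTS: dict[str, int] = {
    "GBM": 20,
    "Metastatic": 12,
    "Meningioma": 10,
    "Lymphoma": 2,
    "Low grade glioma": 2,
    "Medulloblastoma": 1,
}

#: proportions among positives (sum to 1)
SUBTYPE_MIX: dict[str, float] = {
    k: v / COHORT_POSITIVES for k, v in SUBTYPE_COUNTS.items()
}

# ------------------------------------------------------ reference operating points
#: (sensitivity, specificity) of the sensitivity-tuned algorithm
SENSITIVITY_TUNED_POINT = (0.96, 0.45)
#: (sensitivity, specificity) of the specificity-tuned algorithm
SPECIFICITY_TUNED_POINT = (0.47, 0.90)

# ------------------------------------------------------------- triage scenario
TRIAGE_POPULATION = 10_000
TRIAGE_PREVALENCE = 0.01

#: per-scan imaging costs by currency: (CT, MRI)
SCAN_COSTS = {
    "GBP": (90.0, 165.0),      # NHS tariffs: CT ~£90, MRI ~£165
    "USD": (1200.0, 1325.0),   # US national averages: CT ~$1200, MRI ~$1325
}
#: fraction of negative-test patients assumed to still undergo imaging
NEGATIVE_IMAGING_FRACTION = 0.5

# -------------------------------------------- symptom-based referral comparators
#: published PPVs of symptom-based referral criteria for suspected brain tumor
COMPARATOR_PPV = {
    "NICE 'symptoms related to CNS'": 0.029,     # NICE 2005 referral guidance
    "Kernick red-flag symptoms": 0.028,          # Kernick risk-flag criteria
    "Headache alone": 0.001,
    "Symptom combination (6-month)": 0.072,      # highest published symptom PPV
}
#: sensitivity of headache alone as a referral trigger
HEADACHE_ALONE_SENSITIVITY = 0.142
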