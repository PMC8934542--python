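import warnings

import pytest
from hypothesis import HealthCheck, settings

import spectriage as sp
from spectriage.simulate import NoiseModel

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")

# the PLS zero-variance-feature warning is by design (rubberband cut edges)
warnings.filterwarnings(
    "ignore", message="dropping .* zero-variance feature")


@pytest.fixture(scope="session")
def small_cohort():
    """60-patient cohort with a clear disease effect, full replicate design."""
    cfg = sp.CohortConfig(
        n_patients=60, prevalence=0.3,
        subtype_mix={"GBM": 0.5, "Meningioma": 0.5},
        effect=sp.DiseaseEffect(band_index=1, amplitude_shift=0.15,
                                per_patient_sd=0.01),
        seed=42)
    return cfg, sp.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def quiet_cohort():
    """Deterministic cohort: all noise sources off, strong single-band effect."""
    cfg = sp.CohortConfig(
        n_patients=10, prevalence=0.5, subtype_mix={"GBM": 1.0},
        effect=sp.DiseaseEffect(band_index=1, amplitude_shift=0.1,
                                per_patient_sd=0.0),
        noise=NoiseModel.silent(), seed=7)
    return cfg, sp.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def small_features(small_cohort):
    _, records = small_cohort
    return sp.preprocess_cohort(records, sp.PreprocessConfig())


def random_classification_problem(rng, n=20, p=10):
    X = rng.normal(size=(n, p))
    y = rng.integers(0, 2, size=n)
    while y.sum() in (0, n):
        y = rng.integers(0, 2, size=n)
    return X, y
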