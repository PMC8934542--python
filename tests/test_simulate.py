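"""Simulator: cohort structure, determinism, noise hierarchy, signal dose-response."""

import numpy as np
import pytest

import spectriage as sp
from spectriage.simulate import (ConfigurationError, NoiseModel,
                                 largest_remainder_apportionment, with_effect)


def test_cohort_structure_matches_study_composition():
    """Default config: 603 patients, 47 positives, Table-style subtype counts,
    nine replicates each."""
    cfg = sp.CohortConfig(seed=1, n_patients=603)
    records = sp.simulate_cohort(cfg)
    assert len(records) == 603
    positives = [r for r in records if r.label == "positive"]
    assert len(positives) == 47
    counts = {}
    for r in positives:
        counts[r.subtype] = counts.get(r.subtype, 0) + 1
    assert counts == {"GBM": 20, "Metastatic": 12, "Meningioma": 10,
                      "Lymphoma": 2, "Low grade glioma": 2,
                      "Medulloblastoma": 1}
    assert all(len(r.spectra) == 9 for r in records)
    assert all(r.subtype == "non-cancer" for r in records
               if r.label == "negative")


def test_determinism_bit_identical(small_cohort):
    cfg, records = small_cohort
    again = sp.simulate_cohort(cfg)
    for a, b in zip(records, again):
        assert a.patient_id == b.patient_id and a.label == b.label
        for s, t in zip(a.spectra, b.spectra):
            np.testing.assert_array_equal(s.absorbance, t.absorbance)


@pytest.mark.parametrize("n,prev,expected", [(603, 0.078, 47), (10, 0.0, 0),
                                             (100, 0.5, 50), (7, 0.5, 4)])
def test_positive_count_exactness(n, prev, expected):
    cfg = sp.CohortConfig(n_patients=n, prevalence=prev,
                          subtype_mix={"GBM": 1.0}, seed=0)
    records = sp.simulate_cohort(cfg)
    assert sum(r.label == "positive" for r in records) == expected


def test_zero_noise_single_band_shift_is_exact():
    """With all noise off, every positive exceeds every negative at the band
    center by exactly the amplitude shift."""
    cfg = sp.CohortConfig(
        n_patients=6, prevalence=0.5, subtype_mix={"GBM": 1.0},
        bands=[sp.BandModel(center=1650.0, width=25.0, amplitude=0.8)],
        effect=sp.DiseaseEffect(band_index=0, amplitude_shift=0.1,
                                per_patient_sd=0.0),
        noise=NoiseModel.silent(), seed=3)
    records = sp.simulate_cohort(cfg)
    i_center = int(np.argmin(np.abs(cfg.grid.wavenumbers - 1650.0)))
    pos = [s.absorbance[i_center] for r in records if r.label == "positive"
           for s in r.spectra]
    neg = [s.absorbance[i_center] for r in records if r.label == "negative"
           for s in r.spectra]
    assert np.allclose(pos, 0.9) and np.allclose(neg, 0.8)
    assert np.allclose(np.min(pos) - np.max(neg), 0.1)


def test_variance_decomposition_tiers():
    """Only patient-level noise: the 9 replicates of a patient are identical.
    Only replicate-level white noise: well means agree to sampling error."""
    base = dict(n_patients=4, prevalence=0.0, subtype_mix={}, seed=5)
    cfg = sp.CohortConfig(noise=NoiseModel(patient_sd=0.1, well_sd=0,
                                           replicate_sd=0,
                                           baseline_coeffs_sd=(0, 0, 0),
                                           scatter_sd=0), **base)
    for r in sp.simulate_cohort(cfg):
        ref = r.spectra[0].absorbance
        for s in r.spectra[1:]:
            np.testing.assert_array_equal(s.absorbance, ref)

    cfg2 = sp.CohortConfig(
        noise=NoiseModel(patient_sd=0, well_sd=0, replicate_sd=0.01,
                         baseline_coeffs_sd=(0, 0, 0), scatter_sd=0),
        spectra_per_well=200, **base)
    rec = sp.simulate_cohort(cfg2)[0]
    means = [np.mean([s.absorbance for s in rec.spectra
                      if s.well_id == w], axis=0) for w in ("W0", "W1", "W2")]
    # well means differ only by white-noise sampling error ~ sd/sqrt(200)
    assert np.max(np.abs(means[0] - means[1])) < 5 * 0.01 / np.sqrt(100)


def test_auc_monotone_in_effect_size(small_cohort):
    """Downstream patient-level AUC is non-decreasing in the amplitude shift."""
    cfg, _ = small_cohort
    aucs = []
    for shift in (0.0, 0.05, 0.2):
        records = sp.simulate_cohort(with_effect(cfg, shift))
        fm = sp.preprocess_cohort(records, sp.PreprocessConfig())
        half = len(records) // 2
        tr_ids = {r.patient_id for r in records[:half]}
        tr = np.isin(fm.patient_ids, list(tr_ids))
        mdl = sp.fit_pls(fm.X[tr], (fm.labels[tr] == "positive").astype(int), 4)
        scores = []
        labels = []
        for r in records[half:]:
            rows = np.flatnonzero(fm.patient_ids == r.patient_id)
            scores.append(float(np.median(sp.predict_proba(mdl, fm.X[rows]))))
            labels.append(r.label)
        aucs.append(sp.roc_curve(scores, labels).auc)
    assert aucs[0] < 0.75                      # no signal: near chance
    assert aucs[2] > aucs[0] and aucs[2] > 0.9  # strong signal dominates
    assert aucs[1] <= aucs[2] + 0.05           # monotone within MC tolerance


def test_cohort_summary_consistent(small_cohort):
    _, records = small_cohort
    table = sp.cohort_summary(records)
    total = int(table.loc[table.group == "total", "count"].iloc[0])
    assert total == len(records)
    # brute-force recount oracle
    by_label = {}
    by_subtype = {}
    for r in records:
        by_label[r.label] = by_label.get(r.label, 0) + 1
        by_subtype[r.subtype] = by_subtype.get(r.subtype, 0) + 1
    for _, row in table[table.group == "label"].iterrows():
        assert by_label[row["name"]] == row["count"]
    for _, row in table[table.group == "subtype"].iterrows():
        assert by_subtype[row["name"]] == row["count"]
    assert table[table.group == "label"]["count"].sum() == total


def test_largest_remainder_apportionment():
    np.testing.assert_array_equal(
        largest_remainder_apportionment(np.array([20, 12, 10, 2, 2, 1]) / 47, 47),
        [20, 12, 10, 2, 2, 1])
    counts = largest_remainder_apportionment(np.array([1 / 3, 1 / 3, 1 / 3]), 10)
    assert counts.sum() == 10 and sorted(counts) == [3, 3, 4]


def test_invalid_configs_rejected():
    with pytest.raises(ConfigurationError):
        sp.CohortConfig(subtype_mix={"GBM": 0.7})  # does not sum to 1
    with pytest.raises(ConfigurationError):
        sp.CohortConfig(prevalence=1.5)
    with pytest.raises(ConfigurationError):
        sp.CohortConfig(grid=sp.WavenumberGrid(1800, 1000, 50.0),
                        bands=[sp.BandModel(1650, 10.0, 0.5)])  # too coarse
    with pytest.raises(ConfigurationError):
        sp.WavenumberGrid(1000, 1800, 1.0)  # ascending
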