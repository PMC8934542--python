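"""Model/Results interface tying the pipeline together.

:class:`SpectralTriageModel` is built from a cohort of patient records (or
spectra + metadata files); ``fit()`` runs the nested-CV selection protocol
and returns a :class:`SpectralTriageResults` carrying the tuned classifier,
the selected threshold and component count, per-split CV diagnostics, and
methods for prediction, evaluation, feature importance, triage projection
and plotting.
"""

from __future__ import annotations

from dataclasses import asdict

import numpy as np
import pandas as pd

from . import io as sio
from .consensus import ConsensusRule, patient_predictions
from .evaluate import (RocResult, as_percent, detection_table, npv,
                       permutation_importance, ppv, roc_curve)
from .preprocess import FeatureMatrix, PreprocessConfig, preprocess_cohort
from .pls import PlsModel
from .simulate import PatientRecord
from .triage import CostModel, TriageScenario, cost_savings, expected_counts
from .tuning import TunedModel, TuningConfig, nested_cv


class SpectralTriageModel:
    """Per-spectrum PLS-DA + replicate-consensus triage model for a cohort.

    Parameters
    ----------
    records : list of PatientRecord
        Labeled training cohort (each patient with its replicate spectra).
    preprocess, tuning, rule :
        Configuration of the preprocessing pipeline, the nested-CV selection
        protocol, and the patient-level consensus rule.
    """

    def __init__(self, records: list[PatientRecord],
                 preprocess: PreprocessConfig | None = None,
                 tuning: TuningConfig | None = None,
                 rule: ConsensusRule | None = None):
        self.records = records
        self.preprocess_cfg = preprocess or PreprocessConfig()
        self.tuning_cfg = tuning or TuningConfig()
        self.rule = rule or ConsensusRule()
        self._features: FeatureMatrix | None = None

    @classmethod
    def from_files(cls, spectra_path, metadata_path, **kwargs
                   ) -> "SpectralTriageModel":
        """Build a model from a spectra CSV matrix and a metadata TSV."""
        records = sio.read_spectra(spectra_path)
        sio.join_metadata(records, sio.read_metadata(metadata_path))
        return cls(records, **kwargs)

    @property
    def features(self) -> FeatureMatrix:
        """Preprocessed feature matrix of the training cohort (cached)."""
        if self._features is None:
            self._features = preprocess_cohort(self.records, self.preprocess_cfg)
        return self._features

    def fit(self) -> "SpectralTriageResults":
        tuned = nested_cv(self.records, self.preprocess_cfg, self.tuning_cfg,
                          self.rule, features=self.features)
        return SpectralTriageResults(self, tuned)


class SpectralTriageResults:
    """Fitted-pipeline results: tuned classifier, threshold and diagnostics."""

    def __init__(self, model: SpectralTriageModel, tuned: TunedModel):
        self.model = model
        self.tuned = tuned

    # ------------------------------------------------------------- accessors
    @property
    def pls(self) -> PlsModel:
        return self.tuned.model

    @property
    def threshold(self) -> float:
        return self.tuned.threshold

    @property
    def n_components(self) -> int:
        return self.tuned.chosen_n_components

    @property
    def cv_performance(self) -> pd.DataFrame:
        """Per-outer-split selections and outer-test metrics."""
        return self.tuned.cv_performance

    # ------------------------------------------------------------ prediction
    def predict(self, records: list[PatientRecord] | None = None,
                features: FeatureMatrix | None = None) -> pd.DataFrame:
        """Per-patient consensus calls and positive-replicate-fraction scores."""
        if records is None:
            records = self.model.records
            features = features or self.model.features
        return patient_predictions(
            records, self.pls, self.threshold,
            preprocess_cfg=self.model.preprocess_cfg, rule=self.model.rule,
            features=features)

    def roc(self, records: list[PatientRecord] | None = None) -> RocResult:
        """Patient-level ROC over the positive-replicate-fraction score."""
        records = records or self.model.records
        pred = self.predict(records)
        ok = pred["call"] != "indeterminate"
        labels = [r.label for r, keep in zip(records, ok) if keep]
        return roc_curve(pred.loc[ok, "score"], labels)

    # ------------------------------------------------------------ evaluation
    def evaluation_summary(self, prevalence: float | None = None) -> dict:
        """Mean outer-split metrics plus predictive values at `prevalence`.

        Sensitivity/specificity are the means over outer-test splits (the
        generalization estimate); prevalence defaults to the cohort's.
        """
        rep = self.cv_performance
        sens = float(rep["test_sensitivity"].mean())
        spec = float(rep["test_specificity"].mean())
        auc = float(rep["test_auc"].mean())
        if prevalence is None:
            labels = [r.label for r in self.model.records]
            prevalence = labels.count("positive") / len(labels)
        return {
            "sensitivity": sens, "specificity": spec, "auc": auc,
            "prevalence": prevalence,
            "ppv": ppv(sens, spec, prevalence),
            "npv": npv(sens, spec, prevalence),
            "threshold": self.threshold,
            "n_components": self.n_components,
        }

    def detection_rates(self, records: list[PatientRecord] | None = None
                        ) -> pd.DataFrame:
        """Detection-rate table by tumor subtype (plus TOTAL)."""
        records = records or self.model.records
        pred = self.predict(records).set_index("patient_id")
        calls = [1 if pred.loc[r.patient_id, "call"] == "positive" else 0
                 for r in records]
        return detection_table(
            calls, [r.label for r in records], [r.subtype for r in records])

    def importance(self, wavenumber_bins, n_repeats: int = 5,
                   seed: int = 0) -> pd.DataFrame:
        """Permutation importance of wavenumber bins for patient-level AUC."""
        return permutation_importance(
            self.pls, self.model.records, self.model.features, self.threshold,
            wavenumber_bins, rule=self.model.rule, n_repeats=n_repeats,
            seed=seed)

    # --------------------------------------------------------------- triage
    def triage(self, population: int = 10_000, prevalence: float = 0.01,
               cost_model: CostModel | None = None) -> dict:
        """Project the fitted operating point onto a screening population."""
        summ = self.evaluation_summary()
        scenario = TriageScenario(
            population=population, prevalence=prevalence,
            operating_point=(summ["sensitivity"], summ["specificity"]))
        outcome = expected_counts(scenario)
        cm = cost_model or CostModel.uk()
        return {**asdict(outcome),
                "savings": cost_savings(outcome, cm),
                "currency": cm.currency}

    # -------------------------------------------------------------- reports
    def summary(self) -> str:
        """Human-readable fit summary."""
        s = self.evaluation_summary()
        rep = self.cv_performance
        lines = [
            "Spectral triage model — nested-CV summary",
            "=" * 45,
            f"patients: {len(self.model.records)}   "
            f"spectra: {self.model.features.n_spectra}   "
            f"features: {self.model.features.X.shape[1]}",
            f"outer splits: {len(rep)}   inner folds: "
            f"{self.tuned.tuning_cfg.n_inner_folds}   "
            f"mode: {self.tuned.tuning_cfg.tuning_mode} "
            f"(level {self.tuned.tuning_cfg.constraint_level})",
            f"selected components: {self.n_components}   "
            f"probability threshold: {self.threshold:.2f}",
            "-" * 45,
            f"mean outer-test sensitivity: {as_percent(s['sensitivity'])}%",
            f"mean outer-test specificity: {as_percent(s['specificity'])}%",
            f"mean outer-test AUC:         {s['auc']:.3f}",
            f"PPV at prevalence {as_percent(s['prevalence'])}%: "
            f"{as_percent(s['ppv'])}%",
            f"NPV at prevalence {as_percent(s['prevalence'])}%: "
            f"{as_percent(s['npv'])}%",
        ]
        return "\n".join(lines)

    def plot_roc(self, records: list[PatientRecord] | None = None, ax=None):
        """Plot the patient-level ROC curve; returns the matplotlib Axes."""
        import matplotlib.pyplot as plt

        roc = self.roc(records)
        if ax is None:
            _, ax = plt.subplots(figsize=(4.5, 4.5))
        fpr = [1 - p.specificity for p in roc.points]
        tpr = [p.sensitivity for p in roc.points]
        order = np.argsort(fpr)
        ax.plot(np.asarray(fpr)[order], np.asarray(tpr)[order],
                marker="o", ms=3, label=f"AUC = {roc.auc:.2f}")
        ax.plot([0, 1], [0, 1], ls="--", c="gray", lw=0.8)
        ax.set_xlabel("1 - specificity")
        ax.set_ylabel("sensitivity")
        ax.legend(loc="lower right")
        return ax

    # -------------------------------------------------------------- archive
    def save(self, path) -> None:
        """Serialize the tuned model (arrays + scalars) as a versioned archive."""
        t = self.tuned
        payload = {
            "pls": {
                "n_components": t.model.n_components,
                "x_mean": t.model.x_mean, "x_scale": t.model.x_scale,
                "y_mean": t.model.y_mean, "weights": t.model.weights,
                "loadings": t.model.loadings, "y_loadings": t.model.y_loadings,
                "coefficients_path": t.model.coefficients_path,
                "link_intercept": t.model.link_intercept,
                "link_slope": t.model.link_slope,
            },
            "threshold": t.threshold,
            "chosen_n_components": t.chosen_n_components,
            "preprocess": asdict(t.preprocess_cfg),
            "rule": asdict(t.rule),
        }
        sio.save_model_archive(payload, path)


def load_results_payload(path) -> tuple[PlsModel, float, PreprocessConfig,
                                        ConsensusRule]:
    """Load a tuned-model archive into usable objects."""
    p = sio.load_model_archive(path)
    pls = PlsModel(**{k: (v if not isinstance(v, list) else np.array(v))
                      for k, v in p["pls"].items()})
    pre = p["preprocess"]
    pre["cut_range"] = tuple(pre["cut_range"])
    return (pls, float(p["threshold"]),
            PreprocessConfig(**pre), ConsensusRule(**p["rule"]))
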