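"""Model selection: nested cross-validation of the PLS component count and the
probability threshold, repeated over many stratified train-test splits.

Protocol: for each of `n_outer_splits` outer splits (default 51), an inner
`n_inner_folds`-fold CV (default 5) on the outer-train patients produces
out-of-fold per-spectrum probabilities for every candidate component count;
the probability threshold is then selected at the *patient* level (after
replicate consensus) under the chosen tuning mode. Outer-test performance is
recorded per split. The final model uses the modally selected component count
(ties toward fewer components), re-selects the threshold by one more CV pass
over the full cohort, and refits on all training spectra.

All splitting is at the patient level: a patient's 9 replicate spectra never
straddle a split (replicate-leakage guard, asserted structurally).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold, StratifiedShuffleSplit

from . import constants
from .consensus import ConsensusRule
from .evaluate import roc_curve
from .pls import PlsModel, fit_logistic_link, fit_pls, predict_proba
from .preprocess import FeatureMatrix, PreprocessConfig, preprocess_cohort
from .simulate import PatientRecord

_MODES = ("sensitivity_tuned", "specificity_tuned", "youden")


def default_threshold_grid() -> np.ndarray:
    """0.01-step grid over (0.01, 0.99) — finer than any reported operating point."""
    return np.round(np.arange(0.01, 0.995, 0.01), 2)


@dataclass(frozen=True)
class TuningConfig:
    n_outer_splits: int = constants.N_OUTER_SPLITS
    outer_test_fraction: float = 1.0 / 3.0
    n_inner_folds: int = constants.N_INNER_FOLDS
    hyperparameter_grid: tuple[int, ...] = (2, 4, 8, 12)
    threshold_grid: tuple[float, ...] = field(
        default_factory=lambda: tuple(default_threshold_grid()))
    tuning_mode: str = "sensitivity_tuned"
    constraint_level: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_outer_splits < 1:
            raise ValueError("n_outer_splits must be >= 1")
        if self.n_inner_folds < 2:
            raise ValueError("n_inner_folds must be >= 2")
        if not 0.0 < self.constraint_level <= 1.0:
            raise ValueError("constraint_level must be in (0, 1]")
        if self.tuning_mode not in _MODES:
            raise ValueError(f"tuning_mode must be one of {_MODES}")
        if not self.hyperparameter_grid:
            raise ValueError("hyperparameter_grid is empty")


@dataclass(frozen=True)
class ThresholdSelection:
    threshold: float
    sensitivity: float
    specificity: float
    feasible: bool   # False when no grid threshold met the constraint


def _patient_metrics(patient_probs, labels, grid: np.ndarray,
                     rule: ConsensusRule) -> tuple[np.ndarray, np.ndarray]:
    """Patient-level (sensitivity, specificity) per grid threshold.

    `patient_probs` is a sequence of per-patient replicate-probability arrays;
    a replicate is called positive iff prob >= threshold, then the consensus
    rule yields the patient call.
    """
    y = np.asarray([1 if l in (1, "positive", True) else 0 for l in labels])
    if y.sum() == 0 or y.sum() == y.size:
        raise ValueError("both classes must be present")
    calls = np.zeros((len(patient_probs), grid.size), dtype=bool)
    for i, p in enumerate(patient_probs):
        p = np.asarray(p, dtype=float)
        cnt = (p[:, None] >= grid[None, :]).sum(axis=0)
        if p.size >= rule.expected_replicates or rule.short_set_policy == "strict":
            calls[i] = cnt >= rule.min_positive
        else:
            calls[i] = cnt / p.size >= rule.min_positive / rule.expected_replicates
    sens = calls[y == 1].mean(axis=0)
    spec = (~calls[y == 0]).mean(axis=0)
    return sens, spec


def select_threshold(patient_probs, labels,
                     mode: str = "sensitivity_tuned",
                     constraint_level: float = 0.9,
                     grid=None,
                     rule: ConsensusRule = ConsensusRule()) -> ThresholdSelection:
    """Pick the probability threshold from a grid under the tuning mode.

    sensitivity_tuned: among grid thresholds with patient-level sensitivity >=
    `constraint_level`, return the one maximizing specificity.
    specificity_tuned: symmetric. youden: maximize sens + spec - 1.
    Ties are broken toward the larger threshold (the higher specificity
    margin). If no threshold satisfies the constraint, the one maximizing the
    constrained metric is returned with ``feasible=False``.
    """
    if mode not in _MODES:
        raise ValueError(f"mode must be one of {_MODES}")
    grid = np.asarray(default_threshold_grid() if grid is None else grid,
                      dtype=float)
    sens, spec = _patient_metrics(patient_probs, labels, grid, rule)

    def argbest(primary: np.ndarray, secondary: np.ndarray,
                mask: np.ndarray) -> int:
        # lexicographic (primary, secondary, threshold), restricted to mask
        idx = np.flatnonzero(mask)
        key = np.lexsort((grid[idx], secondary[idx], primary[idx]))
        return int(idx[key[-1]])

    all_mask = np.ones(grid.size, dtype=bool)
    if mode == "youden":
        j = sens + spec - 1.0
        best = argbest(j, spec, all_mask)
        feasible = True
    elif mode == "sensitivity_tuned":
        feas = sens >= constraint_level
        feasible = bool(feas.any())
        best = (argbest(spec, sens, feas) if feasible
                else argbest(sens, spec, all_mask))
    else:  # specificity_tuned
        feas = spec >= constraint_level
        feasible = bool(feas.any())
        best = (argbest(sens, spec, feas) if feasible
                else argbest(spec, sens, all_mask))
    return ThresholdSelection(float(grid[best]), float(sens[best]),
                              float(spec[best]), feasible)


def _objective(sel: ThresholdSelection, mode: str) -> float:
    if mode == "sensitivity_tuned":
        return sel.specificity if sel.feasible else sel.sensitivity - 1.0
    if mode == "specificity_tuned":
        return sel.sensitivity if sel.feasible else sel.specificity - 1.0
    return sel.sensitivity + sel.specificity - 1.0


@dataclass
class TunedModel:
    """Final fitted classifier plus the selected operating configuration."""

    model: PlsModel
    threshold: float
    chosen_n_components: int
    cv_performance: pd.DataFrame = field(repr=False)
    preprocess_cfg: PreprocessConfig = field(default_factory=PreprocessConfig)
    rule: ConsensusRule = field(default_factory=ConsensusRule)
    tuning_cfg: TuningConfig = field(default_factory=TuningConfig)


class SplitError(RuntimeError):
    """A usable stratified split could not be drawn."""


def _stratified_split(pids: np.ndarray, y: np.ndarray, test_fraction: float,
                      seed: int, max_attempts: int = 10):
    """Patient-level stratified split guaranteed to keep both classes on
    both sides; redraws from successive streams on failure."""
    for attempt in range(max_attempts):
        sss = StratifiedShuffleSplit(n_splits=1, test_size=test_fraction,
                                     random_state=(seed + attempt) % (2**31))
        tr, te = next(sss.split(pids.reshape(-1, 1), y))
        if len(set(y[tr])) == 2 and len(set(y[te])) == 2:
            return tr, te
    raise SplitError("could not draw a two-class stratified split")


def _kfold(y: np.ndarray, n_folds: int, seed: int, max_attempts: int = 10):
    for attempt in range(max_attempts):
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True,
                              random_state=(seed + attempt) % (2**31))
        folds = list(skf.split(np.zeros_like(y), y))
        if all(len(set(y[tr])) == 2 and len(set(y[va])) == 2
               for tr, va in folds):
            return folds
    raise SplitError("could not draw two-class stratified folds")


def _cv_patient_probs(fm: FeatureMatrix, rows_by_patient: list[np.ndarray],
                      patient_idx: np.ndarray, y_pat: np.ndarray,
                      k_grid: tuple[int, ...], n_folds: int, seed: int):
    """Out-of-fold per-spectrum probabilities for every component count.

    Fits one NIPALS model per fold at max(k_grid); sub-models for smaller k
    are exact truncations, so the component grid costs one fit per fold.
    Returns {k: list of per-patient probability arrays} aligned with
    `patient_idx`.
    """
    kmax = max(k_grid)
    oof = {k: np.full(fm.n_spectra, np.nan) for k in k_grid}
    folds = _kfold(y_pat, n_folds, seed)
    for tr, va in folds:
        tr_rows = np.concatenate([rows_by_patient[patient_idx[i]] for i in tr])
        va_rows = np.concatenate([rows_by_patient[patient_idx[i]] for i in va])
        ytr = (fm.labels[tr_rows] == "positive").astype(int)
        mdl = fit_pls(fm.X[tr_rows], ytr, kmax, fit_link=False)
        for k in k_grid:
            s_tr = mdl.latent_score(fm.X[tr_rows], k=k)
            b0, b1 = fit_logistic_link(s_tr, ytr)
            s_va = mdl.latent_score(fm.X[va_rows], k=k)
            z = b0 + b1 * s_va
            oof[k][va_rows] = np.clip(1.0 / (1.0 + np.exp(-z)), 1e-12, 1 - 1e-12)
    out = {}
    for k in k_grid:
        out[k] = [oof[k][rows_by_patient[patient_idx[i]]]
                  for i in range(patient_idx.size)]
    return out


def nested_cv(records: list[PatientRecord],
              preprocess_cfg: PreprocessConfig = PreprocessConfig(),
              tuning_cfg: TuningConfig = TuningConfig(),
              rule: ConsensusRule = ConsensusRule(),
              features: FeatureMatrix | None = None) -> TunedModel:
    """Run the full nested-CV selection protocol and refit the final model."""
    cfg = tuning_cfg
    fm = features if features is not None else preprocess_cohort(
        records, preprocess_cfg)
    pids = np.array([r.patient_id for r in records])
    y_pat = np.array([1 if r.label == "positive" else 0 for r in records])
    if len(set(y_pat)) != 2:
        raise ValueError("cohort must contain both classes")
    # per-patient QC-passing spectrum rows
    rows_by_patient = []
    for pid in pids:
        idx = np.flatnonzero((fm.patient_ids == pid) & fm.qc_pass)
        rows_by_patient.append(idx)
    usable = np.array([r.size > 0 for r in rows_by_patient])
    grid = np.asarray(cfg.threshold_grid, dtype=float)
    k_grid = tuple(sorted(cfg.hyperparameter_grid))

    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))
    split_seeds = rng.integers(0, 2**31 - 1, size=cfg.n_outer_splits + 1)

    report_rows = []
    for s in range(cfg.n_outer_splits):
        pidx = np.flatnonzero(usable)
        tr, te = _stratified_split(pids[pidx], y_pat[pidx],
                                   cfg.outer_test_fraction, int(split_seeds[s]))
        tr_pat, te_pat = pidx[tr], pidx[te]
        assert not set(tr_pat) & set(te_pat)  # replicate-leakage guard

        probs_by_k = _cv_patient_probs(
            fm, rows_by_patient, tr_pat, y_pat[tr_pat], k_grid,
            cfg.n_inner_folds, int(split_seeds[s]))
        best_k, best_sel, best_obj = None, None, -np.inf
        for k in k_grid:
            sel = select_threshold(probs_by_k[k], y_pat[tr_pat],
                                   cfg.tuning_mode, cfg.constraint_level,
                                   grid, rule)
            obj = _objective(sel, cfg.tuning_mode)
            if obj > best_obj + 1e-12:  # ties -> smaller k (ascending sweep)
                best_k, best_sel, best_obj = k, sel, obj

        # outer-test evaluation at the selected (k, threshold)
        tr_rows = np.concatenate([rows_by_patient[i] for i in tr_pat])
        mdl = fit_pls(fm.X[tr_rows],
                      (fm.labels[tr_rows] == "positive").astype(int),
                      best_k)
        te_probs = [predict_proba(mdl, fm.X[rows_by_patient[i]])
                    for i in te_pat]
        sens_t, spec_t = _patient_metrics(
            te_probs, y_pat[te_pat], np.array([best_sel.threshold]), rule)
        frac = [float(np.mean(p >= best_sel.threshold)) for p in te_probs]
        auc = roc_curve(frac, y_pat[te_pat]).auc
        report_rows.append({
            "split": s, "n_components": best_k,
            "threshold": best_sel.threshold, "feasible": best_sel.feasible,
            "train_sensitivity": best_sel.sensitivity,
            "train_specificity": best_sel.specificity,
            "test_sensitivity": float(sens_t[0]),
            "test_specificity": float(spec_t[0]),
            "test_auc": auc,
        })
    report = pd.DataFrame(report_rows)

    # modal component count, ties toward fewer components
    counts = Counter(report["n_components"])
    top = max(counts.values())
    final_k = min(k for k, c in counts.items() if c == top)

    # threshold re-selected on the full training cohort by one CV pass
    all_pat = np.flatnonzero(usable)
    probs_final = _cv_patient_probs(
        fm, rows_by_patient, all_pat, y_pat[all_pat], (final_k,),
        cfg.n_inner_folds, int(split_seeds[-1]))[final_k]
    final_sel = select_threshold(probs_final, y_pat[all_pat],
                                 cfg.tuning_mode, cfg.constraint_level,
                                 grid, rule)
    all_rows = np.concatenate([rows_by_patient[i] for i in all_pat])
    final_model = fit_pls(fm.X[all_rows],
                          (fm.labels[all_rows] == "positive").astype(int),
                          final_k)
    return TunedModel(model=final_model, threshold=final_sel.threshold,
                      chosen_n_components=final_k, cv_performance=report,
                      preprocess_cfg=preprocess_cfg, rule=rule,
                      tuning_cfg=cfg)
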