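"""Spectral preprocessing: cut -> baseline-correct -> normalize, plus QC.

The commercial assay's preprocessing is undisclosed, so this module makes the
pipeline explicit and configurable. Defaults follow standard dried-serum FTIR
practice: cut to the fingerprint region (1800-1000 cm^-1), rubberband
(lower convex hull) baseline correction, Euclidean vector normalization.
QC-failed spectra are flagged, never silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simulate import PatientRecord, Spectrum


@dataclass(frozen=True)
class PreprocessConfig:
    cut_range: tuple[float, float] = (1800.0, 1000.0)  # (high_wn, low_wn)
    baseline: str = "rubberband"     # none | polynomial | rubberband
    baseline_degree: int = 2         # used by polynomial baseline, in {0,1,2}
    normalization: str = "vector"    # none | vector | min-max
    qc_min_signal: float = 1e-6      # minimum peak-to-peak absorbance

    def __post_init__(self) -> None:
        hi, lo = self.cut_range
        if hi <= lo:
            raise ValueError("cut_range must be (high_wn, low_wn) with high > low")
        if self.baseline not in ("none", "polynomial", "rubberband"):
            raise ValueError(f"unknown baseline method {self.baseline!r}")
        if self.baseline == "polynomial" and self.baseline_degree not in (0, 1, 2):
            raise ValueError("polynomial baseline degree must be in {0, 1, 2}")
        if self.normalization not in ("none", "vector", "min-max"):
            raise ValueError(f"unknown normalization {self.normalization!r}")


@dataclass
class FeatureVector:
    """Preprocessed spectrum with its QC verdict attached."""

    values: np.ndarray
    wavenumbers: np.ndarray
    qc_pass: bool
    qc_reason: str = ""


@dataclass
class FeatureMatrix:
    """Stacked per-spectrum feature vectors with row-aligned identity arrays."""

    X: np.ndarray                 # (n_spectra, n_features)
    wavenumbers: np.ndarray       # descending, length n_features
    spectrum_ids: np.ndarray
    patient_ids: np.ndarray
    labels: np.ndarray            # per-spectrum patient label
    qc_pass: np.ndarray           # bool per row
    qc_report: pd.DataFrame = field(repr=False, default=None)

    @property
    def n_spectra(self) -> int:
        return self.X.shape[0]


def rubberband_baseline(y: np.ndarray) -> np.ndarray:
    """Lower convex hull baseline (Andrew's monotone chain on the index axis).

    The returned baseline touches the spectrum at the hull support points, so
    the corrected spectrum is exactly zero there and >= 0 between them only if
    the signal is convex-bounded; negatives between supports are possible for
    noisy data and are left as-is.
    """
    n = y.size
    if n < 3:
        return np.minimum.accumulate(y) * 0 + y.min()
    x = np.arange(n)
    # monotone chain, lower hull only
    hull: list[int] = []
    for i in range(n):
        while len(hull) >= 2:
            a, b = hull[-2], hull[-1]
            # cross product of (b-a) x (i-b); pop while not a right turn
            if (x[b] - x[a]) * (y[i] - y[a]) - (y[b] - y[a]) * (x[i] - x[a]) <= 0:
                hull.pop()
            else:
                break
        hull.append(i)
    return np.interp(x, x[hull], y[hull])


def polynomial_baseline(y: np.ndarray, degree: int,
                        n_iter: int = 40, tol: float = 1e-8) -> np.ndarray:
    """Iterative restricted polynomial baseline (modpoly-style).

    Repeatedly fits a degree-`degree` polynomial and clips the spectrum to the
    fit, so absorption peaks are progressively excluded and the fit converges
    to the underlying smooth baseline.
    """
    x = np.linspace(-1.0, 1.0, y.size)
    work = y.astype(float).copy()
    fit = np.zeros_like(work)
    for _ in range(n_iter):
        coeffs = np.polynomial.polynomial.polyfit(x, work, degree)
        new_fit = np.polynomial.polynomial.polyval(x, coeffs)
        clipped = np.minimum(work, new_fit)
        if np.max(np.abs(new_fit - fit)) < tol:
            fit = new_fit
            break
        work, fit = clipped, new_fit
    return fit


def _cut_mask(wavenumbers: np.ndarray, cut_range: tuple[float, float]) -> np.ndarray:
    hi, lo = cut_range
    if hi > wavenumbers.max() + 1e-9 or lo < wavenumbers.min() - 1e-9:
        raise ValueError(
            f"cut_range {cut_range} outside grid "
            f"[{wavenumbers.min()}, {wavenumbers.max()}]")
    return (wavenumbers <= hi + 1e-9) & (wavenumbers >= lo - 1e-9)


def preprocess_spectrum(s: Spectrum, cfg: PreprocessConfig) -> FeatureVector:
    """Cut -> baseline-correct -> normalize, in that fixed order.

    A spectrum whose cut-region peak-to-peak amplitude falls below
    ``cfg.qc_min_signal`` (after baseline correction) is QC-flagged and
    returned unnormalized to avoid a division blow-up.
    """
    mask = _cut_mask(s.wavenumbers, cfg.cut_range)
    wn = s.wavenumbers[mask]
    y = s.absorbance[mask].astype(float)

    if cfg.baseline == "rubberband":
        y = y - rubberband_baseline(y)
    elif cfg.baseline == "polynomial":
        y = y - polynomial_baseline(y, cfg.baseline_degree)

    ptp = float(np.ptp(y)) if y.size else 0.0
    if not np.all(np.isfinite(y)):
        return FeatureVector(y, wn, qc_pass=False, qc_reason="non-finite values")
    if ptp < cfg.qc_min_signal:
        return FeatureVector(y, wn, qc_pass=False,
                             qc_reason=f"peak-to-peak {ptp:.3g} below QC floor")

    if cfg.normalization == "vector":
        y = y / np.linalg.norm(y)
    elif cfg.normalization == "min-max":
        y = (y - y.min()) / ptp
    return FeatureVector(y, wn, qc_pass=True)


def preprocess_cohort(records: list[PatientRecord],
                      cfg: PreprocessConfig) -> FeatureMatrix:
    """Preprocess every spectrum of a cohort into one feature matrix.

    Row order follows the record/spectrum order, so per-spectrum outputs are
    independent of which other spectra are present. QC failures are flagged
    in the matrix and itemized in ``qc_report``; more than 50% failures is a
    hard error (the configuration, not the data, is then suspect).
    """
    rows, sids, pids, labels, qc, reasons = [], [], [], [], [], []
    wn = None
    for rec in records:
        for s in rec.spectra:
            fv = preprocess_spectrum(s, cfg)
            if wn is None:
                wn = fv.wavenumbers
            elif fv.wavenumbers.shape != wn.shape or not np.allclose(
                    fv.wavenumbers, wn):
                raise ValueError(
                    f"spectrum {s.spectrum_id!r} on a different grid")
            rows.append(fv.values)
            sids.append(s.spectrum_id)
            pids.append(rec.patient_id)
            labels.append(rec.label)
            qc.append(fv.qc_pass)
            reasons.append(fv.qc_reason)
    if not rows:
        raise ValueError("cohort contains no spectra")
    qc_arr = np.array(qc)
    n_fail = int((~qc_arr).sum())
    if n_fail > 0.5 * len(rows):
        raise ValueError(
            f"{n_fail}/{len(rows)} spectra failed QC; preprocessing "
            "configuration suspect")
    report = pd.DataFrame(
        {"spectrum_id": sids, "patient_id": pids,
         "qc_pass": qc, "qc_reason": reasons})
    return FeatureMatrix(
        X=np.vstack(rows), wavenumbers=wn,
        spectrum_ids=np.array(sids), patient_ids=np.array(pids),
        labels=np.array(labels), qc_pass=qc_arr, qc_report=report)
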