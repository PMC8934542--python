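"""Synthetic serum-FTIR cohort generator.

Real spectra for this assay are proprietary, so the pipeline is exercised on
synthetic cohorts that reproduce the *structure* of the study data: each
patient contributes 3 sample wells x 3 acquisitions = 9 replicate absorbance
spectra on a shared 1 cm^-1 wavenumber grid, with binary tumor labels and a
tumor-subtype mix matching the validation cohort (603 patients, 47 tumors).

The generative model is a sum of Gaussian absorption bands whose amplitudes
carry a three-tier noise hierarchy (patient, well, replicate), plus a disease
effect that shifts one band's amplitude in positive patients, a low-order
polynomial baseline, a global multiplicative scatter factor, and white noise.
Band positions default to canonical serum features (amide I ~1650, amide II
~1550, carbohydrate ~1080 cm^-1 ...); they are neutral placeholders, not a
claim about the true discriminatory regions of any real assay.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import constants


class ConfigurationError(ValueError):
    """Raised when a simulator configuration violates its invariants."""


@dataclass(frozen=True)
class WavenumberGrid:
    """Shared spectral axis, stored high-to-low (descending convention).

    Parameters
    ----------
    start_wn, end_wn : float
        First (highest) and last (lowest) wavenumber in cm^-1.
    spacing : float
        Step between adjacent points in cm^-1.
    """

    start_wn: float = 4000.0
    end_wn: float = 450.0
    spacing: float = constants.DATA_SPACING_CM1

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise ConfigurationError("grid spacing must be > 0")
        if self.start_wn <= self.end_wn:
            raise ConfigurationError("grid must be descending: start_wn > end_wn")
        if self.n_points < 2:
            raise ConfigurationError("grid must contain at least 2 points")

    @property
    def n_points(self) -> int:
        return int(np.floor((self.start_wn - self.end_wn) / self.spacing)) + 1

    @property
    def wavenumbers(self) -> np.ndarray:
        """Descending wavenumber axis in cm^-1."""
        return self.start_wn - self.spacing * np.arange(self.n_points)

    def contains(self, wn: float) -> bool:
        return self.wavenumbers[-1] <= wn <= self.start_wn


@dataclass(frozen=True)
class BandModel:
    """One Gaussian absorption band: exp(-(wn-center)^2 / (2 width^2)) * amplitude."""

    center: float
    width: float   # Gaussian sigma, cm^-1
    amplitude: float  # absorbance units

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ConfigurationError("band width must be > 0")
        if self.amplitude < 0:
            raise ConfigurationError("band amplitude must be >= 0")


@dataclass(frozen=True)
class DiseaseEffect:
    """Additive amplitude shift on one band in the disease class.

    Each positive patient receives shift ~ Normal(amplitude_shift, per_patient_sd),
    constant across that patient's 9 replicates — the simplest hierarchy under
    which replicate-consensus voting is meaningful.
    """

    band_index: int = 1           # defaults to the amide I band (see default_bands)
    amplitude_shift: float = 0.05
    per_patient_sd: float = 0.02

    def __post_init__(self) -> None:
        if self.per_patient_sd < 0:
            raise ConfigurationError("per_patient_sd must be >= 0")


@dataclass(frozen=True)
class NoiseModel:
    """Three-tier noise hierarchy plus baseline drift and multiplicative scatter.

    patient_sd / well_sd are SDs of multiplicative band-amplitude factors
    (factor = 1 + eps, truncated positive); replicate_sd is additive white
    noise per spectral point; baseline_coeffs_sd are SDs of Legendre-style
    polynomial coefficients (degree <= 2) on the normalized axis; scatter_sd
    is the SD of a global multiplicative factor (1 + eps).
    """

    patient_sd: float = 0.05
    well_sd: float = 0.02
    replicate_sd: float = 0.002
    baseline_coeffs_sd: tuple[float, ...] = (0.01, 0.005, 0.002)
    scatter_sd: float = 0.03

    def __post_init__(self) -> None:
        sds = (self.patient_sd, self.well_sd, self.replicate_sd,
               self.scatter_sd, *self.baseline_coeffs_sd)
        if any(s < 0 for s in sds):
            raise ConfigurationError("all noise SDs must be >= 0")
        if len(self.baseline_coeffs_sd) > 3:
            raise ConfigurationError("baseline polynomial degree must be <= 2")

    @classmethod
    def silent(cls) -> "NoiseModel":
        """All noise sources off (deterministic limit)."""
        return cls(0.0, 0.0, 0.0, (0.0, 0.0, 0.0), 0.0)


def default_bands() -> list[BandModel]:
    """Canonical dried-serum mid-IR features (placeholder positions)."""
    return [
        BandModel(center=3300.0, width=80.0, amplitude=0.45),  # amide A (N-H/O-H)
        BandModel(center=1650.0, width=25.0, amplitude=0.80),  # amide I
        BandModel(center=1550.0, width=22.0, amplitude=0.55),  # amide II
        BandModel(center=1400.0, width=20.0, amplitude=0.25),  # COO-/CH bend
        BandModel(center=1240.0, width=25.0, amplitude=0.15),  # amide III / PO2-
        BandModel(center=1080.0, width=25.0, amplitude=0.20),  # carbohydrate C-O
    ]


@dataclass(frozen=True)
class CohortConfig:
    """Full specification of a synthetic cohort."""

    n_patients: int = constants.COHORT_SIZE
    prevalence: float = constants.COHORT_PREVALENCE
    subtype_mix: dict[str, float] = field(
        default_factory=lambda: dict(constants.SUBTYPE_MIX))
    wells_per_patient: int = constants.WELLS_PER_PATIENT
    spectra_per_well: int = constants.SPECTRA_PER_WELL
    grid: WavenumberGrid = field(default_factory=WavenumberGrid)
    bands: list[BandModel] = field(default_factory=default_bands)
    effect: DiseaseEffect = field(default_factory=DiseaseEffect)
    noise: NoiseModel = field(default_factory=NoiseModel)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients <= 0:
            raise ConfigurationError("n_patients must be positive")
        if not 0.0 <= self.prevalence <= 1.0:
            raise ConfigurationError("prevalence must be in [0, 1]")
        if self.subtype_mix:
            total = sum(self.subtype_mix.values())
            if abs(total - 1.0) > 1e-9:
                raise ConfigurationError(
                    f"subtype_mix proportions sum to {total}, expected 1")
            if any(p < 0 for p in self.subtype_mix.values()):
                raise ConfigurationError("subtype proportions must be >= 0")
        if self.wells_per_patient < 1 or self.spectra_per_well < 1:
            raise ConfigurationError("replicate design counts must be >= 1")
        for b in self.bands:
            if not self.grid.contains(b.center):
                raise ConfigurationError(
                    f"band center {b.center} outside grid range")
            if b.width < self.grid.spacing:
                raise ConfigurationError(
                    f"grid too coarse for band width {b.width}")
        if self.bands and not 0 <= self.effect.band_index < len(self.bands):
            raise ConfigurationError("effect.band_index out of range")

    @property
    def replicates_per_patient(self) -> int:
        return self.wells_per_patient * self.spectra_per_well


@dataclass(frozen=True)
class Spectrum:
    """One absorbance spectrum tied to patient/well/replicate identity."""

    spectrum_id: str
    patient_id: str
    well_id: str
    replicate_id: str
    wavenumbers: np.ndarray   # descending, cm^-1
    absorbance: np.ndarray    # AU, same length

    def __post_init__(self) -> None:
        if self.wavenumbers.shape != self.absorbance.shape:
            raise ValueError("wavenumbers and absorbance must align")


@dataclass
class PatientRecord:
    """A patient's label, subtype and full replicate spectrum set."""

    patient_id: str
    label: str                 # "positive" | "negative" | "unknown"
    subtype: str               # tumor subtype or "non-cancer"
    spectra: list[Spectrum]


def largest_remainder_apportionment(proportions: np.ndarray, total: int) -> np.ndarray:
    """Integer counts summing to `total` closest to proportions * total.

    Floors each quota, then distributes the leftover units to the largest
    fractional remainders (ties broken by lower index, i.e. input order).
    """
    quotas = np.asarray(proportions, dtype=float) * total
    counts = np.floor(quotas).astype(int)
    remainder = total - counts.sum()
    if remainder > 0:
        # stable sort => ties resolved toward earlier entries
        order = np.argsort(-(quotas - counts), kind="stable")
        counts[order[:remainder]] += 1
    return counts


def _patient_rng(seed: int, index: int) -> np.random.Generator:
    # counter-based stream split: patient content independent of generation order
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(index,)))


def simulate_cohort(config: CohortConfig) -> list[PatientRecord]:
    """Draw a full synthetic cohort.

    Returns exactly ``config.n_patients`` records; the number of positives is
    ``round(n_patients * prevalence)`` (half away from zero) and subtypes are
    apportioned among positives by largest remainder, then assigned to
    randomly chosen positive patients. Bit-identical under a fixed seed.
    """
    n = config.n_patients
    n_pos = int(np.floor(n * config.prevalence + 0.5))
    master = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(2**31,)))

    labels = np.array(["negative"] * n, dtype=object)
    pos_idx = master.choice(n, size=n_pos, replace=False)
    labels[pos_idx] = "positive"

    subtypes = np.array(["non-cancer"] * n, dtype=object)
    if n_pos and config.subtype_mix:
        names = list(config.subtype_mix)
        counts = largest_remainder_apportionment(
            np.array([config.subtype_mix[k] for k in names]), n_pos)
        pool = np.repeat(names, counts)
        master.shuffle(pool)
        subtypes[pos_idx] = pool
    elif n_pos:
        subtypes[pos_idx] = "positive"

    wn = config.grid.wavenumbers
    # unit-amplitude band profiles, shape (n_bands, n_points)
    profiles = np.stack([
        np.exp(-0.5 * ((wn - b.center) / b.width) ** 2) for b in config.bands
    ]) if config.bands else np.zeros((0, wn.size))
    base_amps = np.array([b.amplitude for b in config.bands])
    x = np.linspace(-1.0, 1.0, wn.size)
    basis = np.vstack([x**d for d in range(len(config.noise.baseline_coeffs_sd))])

    width = len(str(n - 1)) if n > 1 else 1
    records: list[PatientRecord] = []
    for i in range(n):
        rng = _patient_rng(config.seed, i)
        pid = f"P{i:0{width}d}"
        amps = base_amps * np.clip(
            1.0 + rng.normal(0.0, config.noise.patient_sd, base_amps.shape),
            1e-6, None)
        if labels[i] == "positive" and config.bands:
            shift = config.effect.amplitude_shift
            if config.effect.per_patient_sd > 0:
                shift = shift + rng.normal(0.0, config.effect.per_patient_sd)
            amps = amps.copy()
            amps[config.effect.band_index] = max(
                amps[config.effect.band_index] + shift, 0.0)

        spectra: list[Spectrum] = []
        for w in range(config.wells_per_patient):
            well_factor = np.clip(
                1.0 + rng.normal(0.0, config.noise.well_sd), 1e-6, None)
            pure = (amps * well_factor) @ profiles
            for r in range(config.spectra_per_well):
                coeffs = rng.normal(
                    0.0, config.noise.baseline_coeffs_sd, size=basis.shape[0])
                scatter = np.clip(
                    1.0 + rng.normal(0.0, config.noise.scatter_sd), 1e-6, None)
                noise = (rng.normal(0.0, config.noise.replicate_sd, wn.size)
                         if config.noise.replicate_sd > 0 else 0.0)
                absorb = pure * scatter + coeffs @ basis + noise
                spectra.append(Spectrum(
                    spectrum_id=f"{pid}-W{w}-R{r}",
                    patient_id=pid, well_id=f"W{w}", replicate_id=f"R{r}",
                    wavenumbers=wn, absorbance=absorb))
        records.append(PatientRecord(
            patient_id=pid, label=str(labels[i]),
            subtype=str(subtypes[i]), spectra=spectra))
    return records


def cohort_summary(records: list[PatientRecord]) -> pd.DataFrame:
    """Counts by label and subtype; the 'total' row sums to the cohort size."""
    if not records:
        raise ValueError("cohort is empty")
    df = pd.DataFrame(
        {"label": [r.label for r in records],
         "subtype": [r.subtype for r in records]})
    rows = [{"group": "total", "name": "all", "count": len(df)}]
    for lab, cnt in df["label"].value_counts().sort_index().items():
        rows.append({"group": "label", "name": lab, "count": int(cnt)})
    for sub, cnt in df["subtype"].value_counts().sort_index().items():
        rows.append({"group": "subtype", "name": sub, "count": int(cnt)})
    return pd.DataFrame(rows)


def strong_effect_config(seed: int = 0, **overrides) -> CohortConfig:
    """Study-sized cohort with a strong single-band disease effect.

    Used for pipeline validation: the effect is large relative to patient-level
    biological variability, so a well-behaved pipeline should recover it with
    patient-level AUC well above 0.9 and peak feature importance at the band.
    The injected band is the spectrally isolated carbohydrate feature
    (~1080 cm^-1): under vector normalization a shift on an overlapping band
    (e.g. amide I next to amide II) shows up strongest in the overlap region,
    which would make center recovery ambiguous by construction.
    """
    kw = dict(effect=DiseaseEffect(band_index=5, amplitude_shift=0.12,
                                   per_patient_sd=0.01),
              seed=seed)
    kw.update(overrides)
    return CohortConfig(**kw)


def null_effect_config(seed: int = 0, **overrides) -> CohortConfig:
    """Study-sized cohort with zero disease effect (negative control)."""
    kw = dict(effect=DiseaseEffect(band_index=1, amplitude_shift=0.0,
                                   per_patient_sd=0.0),
              seed=seed)
    kw.update(overrides)
    return CohortConfig(**kw)


def with_effect(config: CohortConfig, amplitude_shift: float) -> CohortConfig:
    """Copy of `config` with a different disease amplitude shift."""
    return replace(config, effect=replace(config.effect,
                                          amplitude_shift=amplitude_shift))
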