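"""Plain-text I/O: spectra CSV matrix, patient-metadata TSV, model archives,
and a read-only JCAMP-DX importer.

The canonical exchange format is a CSV matrix — header row of descending
wavenumbers preceded by the four identity columns, one row per spectrum —
plus a tab-separated metadata table keyed by patient_id. Absorbance values
are serialized at 6 significant digits, below the simulated noise floor.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import PatientRecord, Spectrum

ID_COLUMNS = ("spectrum_id", "patient_id", "well_id", "replicate_id")
_PRECISION = "%.6g"


class SpectraFormatError(ValueError):
    """Malformed spectra matrix file; message carries the offending location."""


def write_spectra(records: list[PatientRecord], path: str | Path) -> None:
    """Write a cohort as a CSV spectra matrix.

    Rows are ordered by (patient_id, well_id, replicate_id) so output is
    deterministic regardless of in-memory ordering. All spectra must share
    one wavenumber grid. An empty cohort yields a header-only file with the
    identity columns alone.
    """
    path = Path(path)
    spectra = [s for r in records for s in r.spectra]
    spectra.sort(key=lambda s: (s.patient_id, s.well_id, s.replicate_id))
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        if not spectra:
            writer.writerow(ID_COLUMNS)
            return
        wn = spectra[0].wavenumbers
        for s in spectra[1:]:
            if s.wavenumbers.shape != wn.shape or not np.allclose(
                    s.wavenumbers, wn):
                raise SpectraFormatError(
                    f"spectrum {s.spectrum_id!r} is on a different grid")
        writer.writerow(list(ID_COLUMNS) + [_PRECISION % v for v in wn])
        for s in spectra:
            writer.writerow(
                [s.spectrum_id, s.patient_id, s.well_id, s.replicate_id]
                + [_PRECISION % v for v in s.absorbance])


def read_spectra(path: str | Path) -> list[PatientRecord]:
    """Read a CSV spectra matrix into patient records (labels "unknown").

    The grid is inferred from the header; rows are grouped by patient_id in
    file order. Ragged rows, non-monotone headers, non-finite absorbances and
    duplicate spectrum_ids raise :class:`SpectraFormatError` naming the line.
    """
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise SpectraFormatError(f"{path}: empty file") from None
        if tuple(header[:4]) != ID_COLUMNS:
            raise SpectraFormatError(
                f"{path}: line 1: header must start with {ID_COLUMNS}")
        try:
            wn = np.array([float(v) for v in header[4:]])
        except ValueError as exc:
            raise SpectraFormatError(f"{path}: line 1: bad wavenumber: {exc}")
        if wn.size >= 2:
            diffs = np.diff(wn)
            if not (np.all(diffs < 0) or np.all(diffs > 0)):
                raise SpectraFormatError(
                    f"{path}: line 1: wavenumbers not strictly monotone")

        seen: set[str] = set()
        by_patient: dict[str, list[Spectrum]] = {}
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(header):
                raise SpectraFormatError(
                    f"{path}: line {lineno}: expected {len(header)} fields, "
                    f"got {len(row)}")
            sid, pid, wid, rid = row[:4]
            if not (sid and pid and wid and rid):
                raise SpectraFormatError(
                    f"{path}: line {lineno}: empty identifier field")
            if sid in seen:
                raise SpectraFormatError(
                    f"{path}: line {lineno}: duplicate spectrum_id {sid!r}")
            seen.add(sid)
            try:
                absorb = np.array([float(v) for v in row[4:]])
            except ValueError as exc:
                raise SpectraFormatError(
                    f"{path}: line {lineno}: bad absorbance: {exc}")
            if not np.all(np.isfinite(absorb)):
                raise SpectraFormatError(
                    f"{path}: line {lineno}: non-finite absorbance")
            by_patient.setdefault(pid, []).append(Spectrum(
                spectrum_id=sid, patient_id=pid, well_id=wid,
                replicate_id=rid, wavenumbers=wn, absorbance=absorb))
    return [PatientRecord(patient_id=pid, label="unknown",
                          subtype="unknown", spectra=specs)
            for pid, specs in by_patient.items()]


def write_metadata(records: list[PatientRecord], path: str | Path) -> None:
    """Write the patient metadata table (TSV: patient_id, label, subtype)."""
    df = pd.DataFrame(
        {"patient_id": [r.patient_id for r in records],
         "label": [r.label for r in records],
         "subtype": [r.subtype for r in records]}
    ).sort_values("patient_id")
    df.to_csv(path, sep="\t", index=False)


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read the metadata TSV; validates unique patient_ids and known labels."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"patient_id", "label"}
    missing = required - set(df.columns)
    if missing:
        raise SpectraFormatError(f"{path}: missing columns {sorted(missing)}")
    if df["patient_id"].duplicated().any():
        dup = df.loc[df["patient_id"].duplicated(), "patient_id"].iloc[0]
        raise SpectraFormatError(f"{path}: duplicate patient_id {dup!r}")
    bad = set(df["label"]) - {"positive", "negative", "unknown"}
    if bad:
        raise SpectraFormatError(f"{path}: unknown labels {sorted(bad)}")
    return df


def join_metadata(records: list[PatientRecord],
                  metadata: pd.DataFrame) -> list[PatientRecord]:
    """Attach labels/subtypes to records in place; every patient must resolve."""
    meta = metadata.set_index("patient_id")
    for r in records:
        if r.patient_id not in meta.index:
            raise SpectraFormatError(
                f"patient {r.patient_id!r} missing from metadata")
        r.label = str(meta.loc[r.patient_id, "label"])
        if "subtype" in meta.columns:
            r.subtype = str(meta.loc[r.patient_id, "subtype"])
    return records


# --------------------------------------------------------------- model archive

ARCHIVE_VERSION = 1


def save_model_archive(payload: dict, path: str | Path) -> None:
    """Serialize a model payload (arrays become nested lists) as versioned JSON."""

    def convert(obj):
        if isinstance(obj, np.ndarray):
            return {"__ndarray__": obj.tolist()}
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, dict):
            return {k: convert(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [convert(v) for v in obj]
        return obj

    doc = {"format_version": ARCHIVE_VERSION, "payload": convert(payload)}
    Path(path).write_text(json.dumps(doc, indent=1))


def load_model_archive(path: str | Path) -> dict:
    doc = json.loads(Path(path).read_text())
    if doc.get("format_version") != ARCHIVE_VERSION:
        raise SpectraFormatError(
            f"{path}: unsupported archive version {doc.get('format_version')}")

    def restore(obj):
        if isinstance(obj, dict):
            if set(obj) == {"__ndarray__"}:
                return np.array(obj["__ndarray__"])
            return {k: restore(v) for k, v in obj.items()}
        if isinstance(obj, list):
            return [restore(v) for v in obj]
        return obj

    return restore(doc["payload"])


# ------------------------------------------------------------------- JCAMP-DX

def read_jcampdx(path: str | Path,
                 target_grid: np.ndarray | None = None) -> Spectrum:
    """Read a single-block JCAMP-DX file (AFFN ``XYDATA=(X++(Y..Y))``).

    Returns a :class:`Spectrum`; if `target_grid` is given the trace is
    resampled onto it by linear interpolation. Multi-block files and
    compressed (SQZ/DIF/DUP) ordinate forms are unsupported and raise
    :class:`SpectraFormatError`.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    meta: dict[str, str] = {}
    xs: list[float] = []
    ys: list[float] = []
    in_data = False
    n_titles = 0
    for line in lines:
        line = line.strip()
        if not line:
            continue
        if line.startswith("##"):
            key, _, value = line[2:].partition("=")
            key = key.strip().upper()
            value = value.strip()
            if key == "TITLE":
                n_titles += 1
                if n_titles > 1:
                    raise SpectraFormatError(
                        f"{path}: multi-block JCAMP-DX unsupported")
            if key == "XYDATA":
                if "(X++(Y..Y))" not in value.replace(" ", ""):
                    raise SpectraFormatError(
                        f"{path}: only XYDATA=(X++(Y..Y)) supported")
                in_data = True
                continue
            if key == "END":
                in_data = False
            meta[key] = value
            continue
        if in_data:
            tokens = line.replace(",", " ").split()
            try:
                values = [float(t) for t in tokens]
            except ValueError:
                raise SpectraFormatError(
                    f"{path}: compressed ordinate forms unsupported "
                    f"(offending line: {line[:40]!r})") from None
            if len(values) < 2:
                raise SpectraFormatError(f"{path}: short XYDATA line")
            xs.append(values[0])
            ys.extend(values[1:])
    if not ys:
        raise SpectraFormatError(f"{path}: empty XYDATA block")

    xfactor = float(meta.get("XFACTOR", 1.0))
    yfactor = float(meta.get("YFACTOR", 1.0))
    firstx = xs[0] * xfactor
    lastx = float(meta.get("LASTX", xs[-1])) * (1.0 if "LASTX" in meta else xfactor)
    x = np.linspace(firstx, lastx, len(ys))
    y = np.array(ys) * yfactor

    if target_grid is not None:
        # np.interp needs ascending abscissa
        order = np.argsort(x)
        y = np.interp(target_grid[::-1] if target_grid[0] > target_grid[-1]
                      else target_grid, x[order], y[order])
        if target_grid[0] > target_grid[-1]:
            y = y[::-1]
        x = np.asarray(target_grid, dtype=float)

    title = meta.get("TITLE", path.stem)
    return Spectrum(spectrum_id=title, patient_id=title, well_id="W0",
                    replicate_id="R0", wavenumbers=x, absorbance=y)
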