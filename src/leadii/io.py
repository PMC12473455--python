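"""Dataset layout: per-record 12-lead CSVs, the diagnostics table, and the rhythm taxonomy.

The on-disk layout mirrors the large-scale 12-lead arrhythmia database
distributed through PhysioNet: each subject is one CSV of 5000 samples x 12
leads recorded at 500 Hz, and a single diagnostics table keyed by ``FileName``
carries the rhythm annotation, demographics and the GE-MUSE waveform
measurements.  Only lead II is used downstream; the other columns are kept so
that real data loads unchanged.
"""

from __future__ import annotations

import dataclasses
import math
from collections import Counter
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FS",
    "N_SAMPLES",
    "LEAD_NAMES",
    "MUSE_ATTRIBUTES",
    "RHYTHM_CODES",
    "ECGRecord",
    "DiagnosticsRow",
    "RhythmScheme",
    "MalformedRecordError",
    "SchemaError",
    "UnmappedLabelError",
    "get_scheme",
    "load_record",
    "write_record",
    "select_lead",
    "load_diagnostics",
    "write_diagnostics",
    "apply_rhythm_scheme",
    "class_counts",
]

FS = 500
N_SAMPLES = 5000
LEAD_NAMES = ("I", "II", "III", "aVR", "aVL", "aVF", "V1", "V2", "V3", "V4", "V5", "V6")

#: canonical attribute name -> column name in the diagnostics CSV
MUSE_ATTRIBUTES = {
    "ventricular_rate": "VentricularRate",
    "atrial_rate": "AtrialRate",
    "qrs_duration": "QRSDuration",
    "qt_interval": "QTInterval",
    "qt_corrected": "QTCorrected",
    "r_axis": "RAxis",
    "t_axis": "TAxis",
    "qrs_count": "QRSCount",
    "q_onset": "QOnset",
    "q_offset": "QOffset",
    "t_offset": "TOffset",
}

#: the eleven annotated rhythm codes and their four-group assignment
RHYTHM_GROUPS = {
    "AFIB": "AFIB",  # atrial fibrillation
    "AF": "AFIB",    # atrial flutter
    "SB": "SB",      # sinus bradycardia
    "SA": "SR",      # sinus arrhythmia
    "SR": "SR",      # sinus rhythm
    "ST": "GSVT",    # sinus tachycardia
    "SVT": "GSVT",   # supraventricular tachycardia
    "AT": "GSVT",    # atrial tachycardia
    "AVNRT": "GSVT",
    "SAAWR": "GSVT",
    "AVRT": "GSVT",
}
RHYTHM_CODES = tuple(RHYTHM_GROUPS)

#: codes too small for statistical use (< 20 subjects in the source database)
UNDERREPRESENTED = frozenset({"AVNRT", "SAAWR", "AVRT"})


class MalformedRecordError(ValueError):
    """A per-record CSV violates the 5000 x 12 numeric contract."""


class SchemaError(ValueError):
    """The diagnostics table lacks a mandatory column."""


class UnmappedLabelError(KeyError):
    """A rhythm code is neither mapped nor excluded by the active scheme."""


@dataclasses.dataclass(frozen=True)
class ECGRecord:
    """One subject's 12-lead signal matrix (millivolts) at 500 Hz."""

    record_id: str
    signal: np.ndarray
    fs: int = FS
    lead_names: tuple = LEAD_NAMES

    def __post_init__(self):
        sig = np.asarray(self.signal, dtype=float)
        if sig.shape != (N_SAMPLES, len(self.lead_names)):
            raise MalformedRecordError(
                f"record {self.record_id!r}: expected shape "
                f"({N_SAMPLES}, {len(self.lead_names)}), got {sig.shape}"
            )
        if not np.all(np.isfinite(sig)):
            raise MalformedRecordError(f"record {self.record_id!r}: non-finite samples")
        object.__setattr__(self, "signal", sig)


@dataclasses.dataclass(frozen=True)
class DiagnosticsRow:
    """Per-subject metadata: rhythm annotation, demographics, MUSE measurements.

    Missing numeric attributes are stored as ``nan`` (never silently as 0).
    """

    record_id: str
    rhythm: str
    age: float
    sex: str
    muse: Mapping[str, float]

    def __post_init__(self):
        if self.rhythm not in RHYTHM_GROUPS:
            raise SchemaError(
                f"record {self.record_id!r}: unknown rhythm code {self.rhythm!r}"
            )
        missing = set(MUSE_ATTRIBUTES) - set(self.muse)
        if missing:
            raise SchemaError(
                f"record {self.record_id!r}: missing MUSE attributes {sorted(missing)}"
            )


@dataclasses.dataclass(frozen=True)
class RhythmScheme:
    """A label scheme: map rhythm codes to class labels, or exclude them."""

    name: str
    mapping: Mapping[str, str]
    excluded: frozenset = frozenset()

    def label(self, rhythm: str) -> str:
        try:
            return self.mapping[rhythm]
        except KeyError:
            raise UnmappedLabelError(
                f"rhythm {rhythm!r} is neither mapped nor excluded by scheme "
                f"{self.name!r}"
            ) from None

    @property
    def classes(self) -> tuple:
        return tuple(dict.fromkeys(self.mapping.values()))


ELEVEN_CLASS = RhythmScheme("eleven", {c: c for c in RHYTHM_CODES})
EIGHT_CLASS = RhythmScheme(
    "eight",
    {c: c for c in RHYTHM_CODES if c not in UNDERREPRESENTED},
    excluded=UNDERREPRESENTED,
)
FOUR_CLASS = RhythmScheme("four", dict(RHYTHM_GROUPS))

_SCHEMES = {s.name: s for s in (ELEVEN_CLASS, EIGHT_CLASS, FOUR_CLASS)}


def get_scheme(name: str) -> RhythmScheme:
    try:
        return _SCHEMES[name]
    except KeyError:
        raise KeyError(
            f"unknown scheme {name!r}; valid schemes: {sorted(_SCHEMES)}"
        ) from None


def load_record(path) -> ECGRecord:
    """Read one per-record CSV (header of 12 lead names, 5000 numeric rows)."""
    path = Path(path)
    frame = pd.read_csv(path, float_precision="round_trip")
    if frame.shape != (N_SAMPLES, len(LEAD_NAMES)):
        raise MalformedRecordError(
            f"{path.name}: expected {N_SAMPLES} rows x {len(LEAD_NAMES)} columns, "
            f"got {frame.shape[0]} rows x {frame.shape[1]} columns"
        )
    numeric = frame.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & frame.notna()
    if bad.to_numpy().any():
        row = int(np.argwhere(bad.to_numpy())[0, 0])
        raise MalformedRecordError(f"{path.name}: non-numeric cell at data row {row}")
    if numeric.isna().to_numpy().any():
        row = int(np.argwhere(numeric.isna().to_numpy())[0, 0])
        raise MalformedRecordError(f"{path.name}: empty cell at data row {row}")
    return ECGRecord(record_id=path.stem, signal=numeric.to_numpy(dtype=float))


def write_record(record: ECGRecord, directory) -> Path:
    """Write a record back to ``<directory>/<record_id>.csv`` (round-trip exact)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    out = directory / f"{record.record_id}.csv"
    pd.DataFrame(record.signal, columns=list(record.lead_names)).to_csv(out, index=False)
    return out


def _normalize_lead(name: str, valid: Sequence[str]) -> str:
    """Case-insensitive lead lookup; 'DII' style synonyms accepted for limb leads."""
    lookup = {v.upper(): v for v in valid}
    key = name.strip().upper()
    if key in lookup:
        return lookup[key]
    # 'DII' / 'D2' dialects for the bipolar limb leads
    if key.startswith("D"):
        rest = key[1:]
        roman = {"1": "I", "2": "II", "3": "III"}.get(rest, rest)
        if roman in lookup:
            return lookup[roman]
    raise KeyError(f"unknown lead {name!r}; valid leads: {list(valid)}")


def select_lead(record: ECGRecord, lead: str = "II") -> np.ndarray:
    """Return a 1-D copy of the requested lead column (default lead II)."""
    resolved = _normalize_lead(lead, record.lead_names)
    col = record.lead_names.index(resolved)
    return record.signal[:, col].copy()


_MANDATORY = ["FileName", "Rhythm", "Age", "Gender", *MUSE_ATTRIBUTES.values()]


def load_diagnostics(path) -> list[DiagnosticsRow]:
    """Read the diagnostics table; one :class:`DiagnosticsRow` per subject."""
    frame = pd.read_csv(path)
    missing = [c for c in _MANDATORY if c not in frame.columns]
    if missing:
        raise SchemaError(f"diagnostics table lacks mandatory column(s): {missing}")
    rows = []
    for _, rec in frame.iterrows():
        muse = {
            key: float(pd.to_numeric(rec[col], errors="coerce"))
            for key, col in MUSE_ATTRIBUTES.items()
        }
        age = float(pd.to_numeric(rec["Age"], errors="coerce"))
        rows.append(
            DiagnosticsRow(
                record_id=str(rec["FileName"]),
                rhythm=str(rec["Rhythm"]),
                age=age,
                sex=str(rec["Gender"]).strip().lower(),
                muse=muse,
            )
        )
    return rows


def write_diagnostics(rows: Iterable[DiagnosticsRow], path) -> Path:
    """Write diagnostics rows in the on-disk column layout."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    out = []
    for r in rows:
        rec = {"FileName": r.record_id, "Rhythm": r.rhythm, "Age": r.age,
               "Gender": r.sex.capitalize()}
        rec.update({col: r.muse[key] for key, col in MUSE_ATTRIBUTES.items()})
        out.append(rec)
    pd.DataFrame(out, columns=_MANDATORY).to_csv(path, index=False)
    return path


def apply_rhythm_scheme(rows, scheme):
    """Drop excluded rhythms, map the rest to class labels (order preserved).

    Parameters
    ----------
    rows : sequence of DiagnosticsRow
    scheme : RhythmScheme

    Returns
    -------
    (kept_rows, labels) : tuple of list
    """
    kept, labels = [], []
    for row in rows:
        if row.rhythm in scheme.excluded:
            continue
        labels.append(scheme.label(row.rhythm))
        kept.append(row)
    return kept, labels


def class_counts(labels) -> dict:
    """Count members per class; zero-member classes are absent."""
    return dict(Counter(labels))


def _check_muse_sanity(row: DiagnosticsRow) -> list[str]:
    """Soft sanity checks on MUSE metadata: positive rates, onset <= offset."""
    problems = []
    for key in ("ventricular_rate", "atrial_rate"):
        v = row.muse[key]
        if not math.isnan(v) and v <= 0:
            problems.append(f"{key} = {v} is not positive")
    q_on, q_off = row.muse["q_onset"], row.muse["q_offset"]
    if not (math.isnan(q_on) or math.isnan(q_off)) and q_on > q_off:
        problems.append(f"q_onset {q_on} exceeds q_offset {q_off}")
    return problems
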