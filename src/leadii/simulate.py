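"""Synthetic lead-II cohort generator.

Emulates 10-s, 500-Hz single-lead ECGs for the eleven annotated rhythm
classes so that every downstream stage (denoising, feature bank, selection,
separability, classification) is testable without the PhysioNet download.

A beat is a sum of five Gaussian kernels (P, Q, R, S, T); beats are placed at
times whose RR intervals are i.i.d. lognormal with a class-conditional mean
heart rate and coefficient of variation.  Atrial fibrillation suppresses the
P wave and adds a 4-9 Hz fibrillatory baseline; atrial flutter adds a
300/min sawtooth.  Noise is additive: baseline-wander sinusoid, 50 Hz
powerline tone and white broadband noise.  Each record carries a matching
diagnostics row whose MUSE-style attributes are derived from the generator's
ground truth (ventricular rate = 60 / mean RR, QRS count = beats placed,
QT interval from template geometry).

The class parameter table is an invented fixture: it reproduces the defining
rhythm semantics (bradycardic SB, tachycardic GSVT members, irregular
AFIB RR) but makes no claim to match any real cohort's distributions.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import (
    FS,
    LEAD_NAMES,
    MUSE_ATTRIBUTES,
    N_SAMPLES,
    DiagnosticsRow,
    ECGRecord,
)

__all__ = [
    "Wave",
    "BeatTemplate",
    "RhythmModel",
    "NoiseSpec",
    "InfeasibleModelError",
    "DEFAULT_TEMPLATE",
    "RHYTHM_MODELS",
    "DEFAULT_NOISE",
    "ZERO_NOISE",
    "clean_beat_train",
    "generate_record",
    "inject_noise",
    "generate_cohort",
    "generate_feature_table",
]

DURATION_S = N_SAMPLES / FS  # 10 s


class InfeasibleModelError(ValueError):
    """Heart rate so high that QRS complexes would overlap."""


@dataclasses.dataclass(frozen=True)
class Wave:
    """One Gaussian kernel: amplitude (mV), centre offset from R (s), width (s)."""

    amplitude: float
    center: float
    width: float

    def __post_init__(self):
        if self.width <= 0:
            raise ValueError(f"wave width must be > 0, got {self.width}")


@dataclasses.dataclass(frozen=True)
class BeatTemplate:
    """Five-wave Gaussian beat morphology; R must dominate P and T."""

    p: Wave = Wave(0.15, -0.20, 0.025)
    q: Wave = Wave(-0.10, -0.04, 0.010)
    r: Wave = Wave(1.00, 0.00, 0.012)
    s: Wave = Wave(-0.20, 0.04, 0.012)
    t: Wave = Wave(0.30, 0.28, 0.060)

    def __post_init__(self):
        if not (abs(self.r.amplitude) > abs(self.p.amplitude)
                and abs(self.r.amplitude) > abs(self.t.amplitude)):
            raise ValueError("R amplitude must dominate P and T")

    @property
    def qrs_support(self) -> float:
        """Width in seconds of the QRS envelope (Q onset to S offset)."""
        return (self.s.center + 2 * self.s.width) - (self.q.center - 2 * self.q.width)


@dataclasses.dataclass(frozen=True)
class RhythmModel:
    """Class-conditional rhythm dynamics."""

    label: str
    hr_mean: float  # BPM
    hr_sd: float    # between-subject SD, BPM
    rr_cv: float    # within-record RR coefficient of variation
    p_wave: bool = True
    fibrillatory: bool = False
    fib_band: tuple = (4.0, 9.0)  # Hz
    flutter: bool = False
    flutter_rate: float = 300.0   # waves per minute


#: invented class parameter table (documented fixture, see module docstring)
RHYTHM_MODELS: Mapping[str, RhythmModel] = {
    "SB": RhythmModel("SB", 50, 5, 0.03),
    "SR": RhythmModel("SR", 75, 8, 0.05),
    "SA": RhythmModel("SA", 70, 8, 0.12),
    "ST": RhythmModel("ST", 120, 15, 0.03),
    "SVT": RhythmModel("SVT", 180, 20, 0.02, p_wave=False),
    "AT": RhythmModel("AT", 140, 15, 0.04),
    "AFIB": RhythmModel("AFIB", 110, 20, 0.25, p_wave=False, fibrillatory=True),
    "AF": RhythmModel("AF", 110, 15, 0.05, p_wave=False, flutter=True),
    "AVNRT": RhythmModel("AVNRT", 170, 20, 0.02, p_wave=False),
    "SAAWR": RhythmModel("SAAWR", 90, 15, 0.10),
    "AVRT": RhythmModel("AVRT", 175, 20, 0.02, p_wave=False),
}


@dataclasses.dataclass(frozen=True)
class NoiseSpec:
    """Additive noise mixture amplitudes (mV)."""

    wander_amplitude: float = 0.10
    wander_freq: float = 0.25  # Hz, below the 0.5 Hz filter edge
    powerline_amplitude: float = 0.03  # at 50 Hz
    broadband_sd: float = 0.03
    seed: int = 0

    def __post_init__(self):
        if min(self.wander_amplitude, self.powerline_amplitude,
               self.broadband_sd) < 0:
            raise ValueError("noise amplitudes must be >= 0")


DEFAULT_TEMPLATE = BeatTemplate()
DEFAULT_NOISE = NoiseSpec()
ZERO_NOISE = NoiseSpec(0.0, 0.25, 0.0, 0.0)

#: projection of the lead-II trace onto the other 11 columns (plumbing only)
_LEAD_SCALES = (0.55, 1.0, 0.45, -0.75, 0.2, 0.7, -0.3, 0.25, 0.6, 0.9, 1.1, 1.05)


def inject_noise(signal, noise: NoiseSpec, rng=None) -> np.ndarray:
    """Add wander sinusoid + 50 Hz tone + white noise; length preserved."""
    x = np.asarray(signal, dtype=float)
    rng = np.random.default_rng(noise.seed) if rng is None else rng
    t = np.arange(x.size) / FS
    out = x.copy()
    if noise.wander_amplitude > 0:
        phase = rng.uniform(0, 2 * np.pi)
        out += noise.wander_amplitude * np.sin(2 * np.pi * noise.wander_freq * t + phase)
    if noise.powerline_amplitude > 0:
        phase = rng.uniform(0, 2 * np.pi)
        out += noise.powerline_amplitude * np.sin(2 * np.pi * 50.0 * t + phase)
    if noise.broadband_sd > 0:
        out += rng.normal(0.0, noise.broadband_sd, size=x.size)
    return out


def _beat_times(model: RhythmModel, rng) -> tuple[np.ndarray, np.ndarray]:
    """Place beats over 10 s; RR i.i.d. lognormal(mean 60/HR, CV rr_cv)."""
    hr = float(np.clip(rng.normal(model.hr_mean, model.hr_sd), 25.0, 280.0))
    mean_rr = 60.0 / hr
    cv = max(model.rr_cv, 1e-6)
    sigma2 = np.log(1.0 + cv ** 2)
    mu = np.log(mean_rr) - sigma2 / 2.0
    # enough intervals to cover 10 s with margin
    n_draw = int(np.ceil(DURATION_S / mean_rr * 3)) + 10
    rr = rng.lognormal(mu, np.sqrt(sigma2), size=n_draw)
    times = rng.uniform(0.05, 0.95) * mean_rr + np.concatenate(([0.0], np.cumsum(rr)))
    times = times[times < DURATION_S]
    used_rr = rr[: max(times.size - 1, 0)]
    return times, used_rr


def clean_beat_train(model: RhythmModel, template: BeatTemplate, rng) -> tuple:
    """Noise-free lead-II trace plus (beat_times, rr_intervals, compression)."""
    times, rr = _beat_times(model, rng)
    mean_rr = float(np.mean(rr)) if rr.size else 60.0 / model.hr_mean
    if mean_rr < template.qrs_support:
        raise InfeasibleModelError(
            f"{model.label}: mean RR {mean_rr:.3f} s shorter than QRS support "
            f"{template.qrs_support:.3f} s"
        )
    # compress the beat at fast rates so P/T of adjacent beats stay ordered
    compress = min(1.0, mean_rr / 0.8)
    t = np.arange(N_SAMPLES) / FS
    x = np.zeros(N_SAMPLES)
    waves = [template.q, template.r, template.s, template.t]
    if model.p_wave:
        waves.append(template.p)
    for tb in times:
        for w in waves:
            c = tb + w.center * compress
            width = w.width * (compress if w is template.t else 1.0)
            x += w.amplitude * np.exp(-0.5 * ((t - c) / width) ** 2)
    if model.fibrillatory:
        lo, hi = model.fib_band
        for f in rng.uniform(lo, hi, size=3):
            x += 0.06 * np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))
    if model.flutter:
        f = model.flutter_rate / 60.0
        phase = rng.uniform(0, 1)
        x += 0.15 * (2 * ((f * t + phase) % 1.0) - 1.0)  # sawtooth
    return x, times, rr, compress


def generate_record(
    model: RhythmModel,
    template: BeatTemplate = DEFAULT_TEMPLATE,
    noise: NoiseSpec = DEFAULT_NOISE,
    seed=0,
    record_id: str | None = None,
) -> tuple[ECGRecord, DiagnosticsRow]:
    """One synthetic subject: 12-column record + ground-truth diagnostics."""
    rng = np.random.default_rng(seed)
    x, times, rr, compress = clean_beat_train(model, template, rng)
    lead2 = inject_noise(x, noise, rng)
    signal = np.outer(lead2, np.ones(len(LEAD_NAMES))) * np.array(_LEAD_SCALES)

    mean_rr = float(np.mean(rr)) if rr.size else 60.0 / model.hr_mean
    vrate = 60.0 / mean_rr
    if model.flutter:
        arate = model.flutter_rate
    elif model.fibrillatory:
        arate = float(rng.uniform(300.0, 450.0))
    else:
        arate = vrate
    q_on = (template.q.center - 2 * template.q.width) * compress
    q_off = (template.s.center + 2 * template.s.width) * compress
    t_off = (template.t.center + 2 * template.t.width) * compress
    qrs_ms = (q_off - q_on) * 1000.0
    qt_ms = (t_off - q_on) * 1000.0
    diag = DiagnosticsRow(
        record_id=record_id or f"SYN_{model.label}_{int(rng.integers(10**7)):07d}",
        rhythm=model.label,
        age=float(round(float(np.clip(rng.normal(64, 15), 18, 95)))),
        sex="male" if rng.random() < 0.55 else "female",
        muse={
            "ventricular_rate": vrate,
            "atrial_rate": arate,
            "qrs_duration": qrs_ms,
            "qt_interval": qt_ms,
            "qt_corrected": qt_ms / np.sqrt(mean_rr),
            "r_axis": float(round(rng.normal(60, 25))),
            "t_axis": float(round(rng.normal(45, 25))),
            "qrs_count": float(times.size),
            "q_onset": float(np.round((0.5 + q_on) * FS)),
            "q_offset": float(np.round((0.5 + q_off) * FS)),
            "t_offset": float(np.round((0.5 + t_off) * FS)),
        },
    )
    record = ECGRecord(record_id=diag.record_id, signal=signal)
    return record, diag


def generate_cohort(
    n_per_class: int,
    classes: Sequence[str] = ("AFIB", "SB", "SR", "ST"),
    seed: int = 0,
    template: BeatTemplate = DEFAULT_TEMPLATE,
    noise: NoiseSpec = DEFAULT_NOISE,
) -> tuple[list[ECGRecord], list[DiagnosticsRow]]:
    """``n_per_class`` records for each requested rhythm code."""
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    unknown = [c for c in classes if c not in RHYTHM_MODELS]
    if unknown:
        raise KeyError(f"unknown rhythm class(es) {unknown}; "
                       f"valid: {sorted(RHYTHM_MODELS)}")
    records, diagnostics = [], []
    for ci, cls in enumerate(classes):
        model = RHYTHM_MODELS[cls]
        for i in range(n_per_class):
            child = np.random.SeedSequence(entropy=seed, spawn_key=(ci, i))
            rec, diag = generate_record(
                model, template, noise, seed=child,
                record_id=f"SYN_{cls}_{i:04d}",
            )
            records.append(rec)
            diagnostics.append(diag)
    return records, diagnostics


def generate_feature_table(
    n_per_class: int,
    effect: Mapping[str, Mapping[str, float]],
    noise_sd: float = 1.0,
    seed: int = 0,
    classes: Sequence[str] | None = None,
    n_features: int | None = None,
) -> pd.DataFrame:
    """Class-conditional Gaussian feature table for testing selection and
    classification in isolation.

    ``effect`` maps feature name -> {class -> mean shift}; classes absent from
    a feature's map get mean 0 there.  Features beyond ``effect`` (up to
    ``n_features``) are pure ``N(0, noise_sd)`` noise with zero class signal.
    Returns a DataFrame with the feature columns plus a ``label`` column.
    """
    if classes is None:
        classes = sorted({c for shifts in effect.values() for c in shifts})
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    names = list(effect)
    n_features = n_features if n_features is not None else len(names)
    i = 0
    while len(names) < n_features:
        cand = f"null{i:02d}"
        if cand not in names:
            names.append(cand)
        i += 1
    rng = np.random.default_rng(seed)
    blocks, labels = [], []
    for cls in classes:
        means = np.array([effect.get(f, {}).get(cls, 0.0) for f in names])
        blocks.append(means + rng.normal(0.0, noise_sd, size=(n_per_class, len(names))))
        labels.extend([cls] * n_per_class)
    table = pd.DataFrame(np.vstack(blocks), columns=names)
    table["label"] = labels
    return table
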