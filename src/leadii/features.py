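"""The lead-II feature bank: 10 time-domain, 8 spectral and 7 nonlinear
descriptors, plus assembly of the 38-column subject x feature table.

Signal descriptors are computed on the denoised lead-II trace.  Spectral
descriptors come from a Hamming-windowed 2048-point averaged periodogram
restricted to the 0.5-50 Hz analysis band.  The nonlinear group covers
long-range dependence (rescaled-range Hurst exponent, DFA scaling exponent),
autocorrelation mass (LAC) and an entropy family (wavelet, spectral,
approximate and fuzzy entropy).

Features that are undefined on degenerate input (constant signals, all-zero
spectra) are returned as ``nan`` together with a ``DegenerateSignalWarning``;
imputation is deferred to model training so the raw table stays faithful.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings

import numpy as np
import pandas as pd
import pywt
from scipy import signal as sps

from . import io as lio
from .denoise import FilterSpec, NLMParams, denoise_pipeline

__all__ = [
    "PowerSpectrum",
    "DegenerateSignalWarning",
    "TIME_FEATURES",
    "SPECTRAL_FEATURES",
    "NONLINEAR_FEATURES",
    "SIGNAL_FEATURES",
    "METADATA_FEATURES",
    "FEATURE_SUBSETS",
    "extract_time_features",
    "power_spectrum",
    "extract_spectral_features",
    "hurst_rs",
    "dfa_alpha",
    "lac",
    "approximate_entropy",
    "fuzzy_entropy",
    "wavelet_entropy",
    "spectral_entropy",
    "entropy_features",
    "signal_features",
    "assemble_feature_table",
]

log = logging.getLogger(__name__)


class DegenerateSignalWarning(UserWarning):
    """A feature was undefined on this input and stored as missing."""


TIME_FEATURES = ("AR", "PPA", "MA", "MSI", "SignInt", "RMS1", "RMS2", "MS", "MdS", "SNEO")
SPECTRAL_FEATURES = ("AMSA", "CF", "PF", "ENRG", "SFM", "CP", "MP", "PSA")
NONLINEAR_FEATURES = ("Hu", "ScE", "LAC", "WE", "SpeEnt", "ApEn", "FuzzyEn")
SIGNAL_FEATURES = TIME_FEATURES + SPECTRAL_FEATURES + NONLINEAR_FEATURES

METADATA_FEATURES = ("age", "gender") + tuple(lio.MUSE_ATTRIBUTES)

GENERAL4 = ("age", "gender", "ventricular_rate", "atrial_rate")

FEATURE_SUBSETS = {
    "general4": GENERAL4,
    "morph13": METADATA_FEATURES,
    "ours29": GENERAL4 + SIGNAL_FEATURES,
    "all38": METADATA_FEATURES + SIGNAL_FEATURES,
}


# ---------------------------------------------------------------------------
# time domain
# ---------------------------------------------------------------------------

def extract_time_features(x, fs: float) -> dict:
    """Ten time-domain descriptors of a single-lead trace.

    AR: global amplitude range (max - min).
    PPA: mean of per-1-s-window amplitude ranges.
    MA: mean absolute amplitude.
    MSI: median absolute stepping increment |x[n+1] - x[n]| (also the median
        successive increment of the identity-lag Poincare plot, up to sqrt(2)).
    SignInt: integral of |x| (sum / fs).
    RMS1: full-signal root mean square.
    RMS2: mean of per-2-s-window RMS values.
    MS: mean absolute slope (mean |diff| * fs).
    MdS: median signed slope (median diff * fs).
    SNEO: mean of the Bartlett-smoothed Teager energy x[n]^2 - x[n-1] x[n+1].
    """
    x = np.asarray(x, dtype=float)
    if x.size < 100:
        raise ValueError(f"need at least 100 samples, got {x.size}")
    d = np.diff(x)
    ar = float(np.max(x) - np.min(x))
    if ar == 0.0:
        warnings.warn("constant signal: amplitude features degenerate",
                      DegenerateSignalWarning, stacklevel=2)

    def windowed(seconds, fn):
        w = int(round(seconds * fs))
        n_win = max(1, x.size // w)
        return float(np.mean([fn(x[i * w : (i + 1) * w]) for i in range(n_win)]))

    psi = x[1:-1] ** 2 - x[:-2] * x[2:]
    win = np.bartlett(7)
    win /= win.sum()
    sneo = float(np.mean(np.convolve(psi, win, mode="same")))
    return {
        "AR": ar,
        "PPA": windowed(1.0, np.ptp),
        "MA": float(np.mean(np.abs(x))),
        "MSI": float(np.median(np.abs(d))),
        "SignInt": float(np.sum(np.abs(x)) / fs),
        "RMS1": float(np.sqrt(np.mean(x ** 2))),
        "RMS2": windowed(2.0, lambda w: np.sqrt(np.mean(w ** 2))),
        "MS": float(np.mean(np.abs(d)) * fs),
        "MdS": float(np.median(d) * fs),
        "SNEO": sneo,
    }


# ---------------------------------------------------------------------------
# spectral
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class PowerSpectrum:
    """Averaged modified periodogram (2048-point Hamming segments, 50% overlap)."""

    freqs: np.ndarray
    amplitude: np.ndarray
    power: np.ndarray
    band: tuple = (0.5, 50.0)
    nfft: int = 2048
    window: str = "hamming"
    zero_padded: bool = False

    def band_mask(self) -> np.ndarray:
        lo, hi = self.band
        return (self.freqs >= lo) & (self.freqs <= hi)


def power_spectrum(x, fs: float, band=(0.5, 50.0), nfft: int = 2048) -> PowerSpectrum:
    """Welch spectrum with Hamming window; inputs shorter than one segment are
    zero-padded (flagged on the result)."""
    x = np.asarray(x, dtype=float)
    padded = x.size < nfft
    if padded:
        x = np.pad(x, (0, nfft - x.size))
    freqs, pxx = sps.welch(
        x, fs=fs, window="hamming", nperseg=nfft, noverlap=nfft // 2,
        nfft=nfft, scaling="spectrum", detrend=False,
    )
    return PowerSpectrum(
        freqs=freqs, amplitude=np.sqrt(pxx), power=pxx,
        band=tuple(band), nfft=nfft, zero_padded=padded,
    )


def extract_spectral_features(ps: PowerSpectrum) -> dict:
    """Eight band-limited spectral descriptors.

    AMSA: amplitude spectrum area, sum of |X(f)| * f over the band.
    CF: power-weighted centroid frequency.  PF: peak-power frequency.
    ENRG: total band power.  SFM: geometric / arithmetic mean power ratio.
    CP: power at the bin nearest CF.  MP: maximum bin power.
    PSA: mean band power (ENRG / number of band bins).
    """
    mask = ps.band_mask()
    if mask.sum() < 8:
        raise ValueError("analysis band contains fewer than 8 bins")
    f = ps.freqs[mask]
    p = ps.power[mask]
    a = ps.amplitude[mask]
    total = float(p.sum())
    if total == 0.0:
        warnings.warn("all-zero band power: spectral features stored as missing",
                      DegenerateSignalWarning, stacklevel=2)
        return {k: np.nan for k in SPECTRAL_FEATURES}
    cf = float((f * p).sum() / total)
    with np.errstate(divide="ignore"):
        log_p = np.log(p, out=np.full_like(p, -np.inf), where=p > 0)
    sfm = float(np.exp(log_p.mean()) / p.mean()) if np.all(p > 0) else 0.0
    return {
        "AMSA": float((a * f).sum()),
        "CF": cf,
        "PF": float(f[np.argmax(p)]),
        "ENRG": total,
        "SFM": sfm,
        "CP": float(p[np.argmin(np.abs(f - cf))]),
        "MP": float(p.max()),
        "PSA": total / p.size,
    }


# ---------------------------------------------------------------------------
# nonlinear / long-range dependence
# ---------------------------------------------------------------------------

def hurst_rs(x) -> float:
    """Rescaled-range Hurst exponent.

    The mean R/S statistic over non-overlapping windows of dyadic sizes
    16 ... N/4 is divided by its white-noise expectation (Anis-Lloyd-Peters
    small-sample formula); the exponent is 0.5 plus the slope of the corrected
    log R/S against log window size.  This removes the well-known upward bias
    of the plain R/S slope at these window sizes, so uncorrelated noise maps
    to ~0.5 and a random walk to ~1.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 256:
        raise ValueError(f"need at least 256 samples, got {x.size}")
    if np.ptp(x) == 0.0:
        warnings.warn("constant signal: Hurst exponent undefined",
                      DegenerateSignalWarning, stacklevel=2)
        return np.nan
    sizes = []
    n = 16
    while n <= x.size // 4:
        sizes.append(n)
        n *= 2
    log_rs, log_n = [], []
    for n in sizes:
        m = x.size // n
        segs = x[: m * n].reshape(m, n)
        mean = segs.mean(axis=1, keepdims=True)
        z = np.cumsum(segs - mean, axis=1)
        r = z.max(axis=1) - z.min(axis=1)
        s = segs.std(axis=1, ddof=1)
        ok = s > 0
        if not ok.any():
            continue
        rs = float(np.mean(r[ok] / s[ok]))
        log_rs.append(np.log(rs / _expected_rs(n)))
        log_n.append(np.log(n))
    if len(log_n) < 2:
        warnings.warn("too few usable windows: Hurst exponent undefined",
                      DegenerateSignalWarning, stacklevel=2)
        return np.nan
    slope = np.polyfit(log_n, log_rs, 1)[0]
    return float(0.5 + slope)


def _expected_rs(n: int) -> float:
    """Anis-Lloyd-Peters expectation of R/S for i.i.d. Gaussian noise."""
    i = np.arange(1, n)
    s = np.sum(np.sqrt((n - i) / i))
    if n <= 340:
        from scipy.special import gammaln
        front = np.exp(gammaln((n - 1) / 2.0) - gammaln(n / 2.0)) / np.sqrt(np.pi)
    else:
        front = 1.0 / np.sqrt(n * np.pi / 2.0)
    return float((n - 0.5) / n * front * s)


def dfa_alpha(x, box_range=(4, 64), n_boxes: int = 10) -> float:
    """First-order detrended fluctuation analysis scaling exponent.

    The mean-removed signal is integrated, split into non-overlapping boxes of
    log-spaced sizes, linearly detrended per box; the exponent is the slope of
    log F(n) against log n.  ~0.5 for uncorrelated noise, ~1.5 for Brownian
    motion.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 256:
        raise ValueError(f"need at least 256 samples, got {x.size}")
    if np.ptp(x) == 0.0:
        warnings.warn("constant signal: DFA exponent undefined",
                      DegenerateSignalWarning, stacklevel=2)
        return np.nan
    y = np.cumsum(x - x.mean())
    sizes = np.unique(np.geomspace(box_range[0], box_range[1], n_boxes).astype(int))
    log_f, log_n = [], []
    t_cache = {}
    for n in sizes:
        m = y.size // n
        if m < 2:
            continue
        boxes = y[: m * n].reshape(m, n)
        if n not in t_cache:
            t = np.arange(n, dtype=float)
            t -= t.mean()
            t_cache[n] = t
        t = t_cache[n]
        # per-box least-squares line: slope and intercept in closed form
        slope = boxes @ t / (t @ t)
        resid = boxes - boxes.mean(axis=1, keepdims=True) - slope[:, None] * t
        f = np.sqrt(np.mean(resid ** 2))
        if f > 0:
            log_f.append(np.log(f))
            log_n.append(np.log(n))
    if len(log_n) < 2:
        warnings.warn("too few usable box sizes: DFA exponent undefined",
                      DegenerateSignalWarning, stacklevel=2)
        return np.nan
    return float(np.polyfit(log_n, log_f, 1)[0])


def lac(x, max_lag: int = 50) -> float:
    """Logarithm (base 10) of the summed absolute autocorrelations at lags 1..K."""
    x = np.asarray(x, dtype=float)
    if x.size <= max_lag:
        raise ValueError(f"need more than {max_lag} samples, got {x.size}")
    z = x - x.mean()
    denom = float(z @ z)
    if denom == 0.0:
        warnings.warn("zero-variance signal: LAC undefined",
                      DegenerateSignalWarning, stacklevel=2)
        return np.nan
    rho = np.array([float(z[: -k or None] @ z[k:]) / denom
                    for k in range(1, max_lag + 1)])
    return float(np.log10(np.sum(np.abs(rho))))


# ---------------------------------------------------------------------------
# entropy family
# ---------------------------------------------------------------------------

def _chebyshev_counts(x: np.ndarray, m: int, r: float, fuzzy: bool):
    """Template match statistics for ApEn/FuzzyEn.

    Returns per-template mean similarity: hard threshold counts (including
    self-matches) for ApEn, exponential membership with self-matches excluded
    and per-template baseline removal for FuzzyEn.
    """
    n = x.size - m + 1
    templ = np.lib.stride_tricks.sliding_window_view(x, m).astype(float)
    if fuzzy:
        templ = templ - templ.mean(axis=1, keepdims=True)
    # pairwise Chebyshev distances, built dimension by dimension
    dist = np.zeros((n, n))
    for j in range(m):
        np.maximum(dist, np.abs(templ[:, j, None] - templ[None, :, j]), out=dist)
    if fuzzy:
        mu = np.exp(-((dist / r) ** 2))
        np.fill_diagonal(mu, 0.0)
        return mu.sum(axis=1) / (n - 1)
    return (dist <= r).sum(axis=1) / n


def approximate_entropy(x, m: int = 2, r: float | None = None) -> float:
    """Approximate entropy ApEn(m, r); ``r`` defaults to 0.2 * SD."""
    x = np.asarray(x, dtype=float)
    sd = float(np.std(x))
    if sd == 0.0:
        warnings.warn("constant signal: ApEn undefined",
                      DegenerateSignalWarning, stacklevel=2)
        return np.nan
    r = 0.2 * sd if r is None else r
    phi = []
    for mm in (m, m + 1):
        c = _chebyshev_counts(x, mm, r, fuzzy=False)
        phi.append(np.mean(np.log(c)))
    return float(phi[0] - phi[1])


def fuzzy_entropy(x, m: int = 2, r: float | None = None) -> float:
    """Fuzzy entropy with exponential membership exp(-(d/r)^2) and
    baseline-removed templates; ``r`` defaults to 0.2 * SD."""
    x = np.asarray(x, dtype=float)
    sd = float(np.std(x))
    if sd == 0.0:
        warnings.warn("constant signal: FuzzyEn undefined",
                      DegenerateSignalWarning, stacklevel=2)
        return np.nan
    r = 0.2 * sd if r is None else r
    phi = []
    for mm in (m, m + 1):
        mu = _chebyshev_counts(x, mm, r, fuzzy=True)
        phi.append(np.mean(mu))
    if phi[0] == 0.0 or phi[1] == 0.0:
        warnings.warn("no fuzzy template matches: FuzzyEn undefined",
                      DegenerateSignalWarning, stacklevel=2)
        return np.nan
    return float(np.log(phi[0]) - np.log(phi[1]))


def wavelet_entropy(x, wavelet: str = "db4", level: int = 5) -> float:
    """Shannon entropy of relative subband energies of a 5-level Daubechies-4
    decomposition, normalized to [0, 1]."""
    x = np.asarray(x, dtype=float)
    coeffs = pywt.wavedec(x, wavelet, level=level)
    energies = np.array([float(np.sum(c ** 2)) for c in coeffs])
    total = energies.sum()
    if total == 0.0:
        warnings.warn("zero-energy signal: wavelet entropy undefined",
                      DegenerateSignalWarning, stacklevel=2)
        return np.nan
    p = energies / total
    p = p[p > 0]
    return float(np.clip(-(p * np.log(p)).sum() / np.log(len(energies)), 0.0, 1.0))


def spectral_entropy(ps: PowerSpectrum) -> float:
    """Normalized Shannon entropy of the band power distribution (0 = tonal,
    1 = flat)."""
    mask = ps.band_mask()
    p = ps.power[mask]
    total = p.sum()
    if total == 0.0:
        warnings.warn("zero band power: spectral entropy undefined",
                      DegenerateSignalWarning, stacklevel=2)
        return np.nan
    q = p / total
    q = q[q > 0]
    if q.size == 1:
        return 0.0
    # clamp: the normalized entropy is exactly 1 on a flat distribution,
    # but the float sum can exceed log(N) by an ulp
    return float(np.clip(-(q * np.log(q)).sum() / np.log(p.size), 0.0, 1.0))


def entropy_features(x, ps: PowerSpectrum, fs: float = 500.0) -> dict:
    """WE, SpeEnt, ApEn and FuzzyEn.  ApEn/FuzzyEn run on the signal decimated
    to 125 Hz (anti-aliased), which keeps the quadratic template search cheap
    without discarding the sub-50-Hz content they measure."""
    x = np.asarray(x, dtype=float)
    factor = max(1, int(round(fs / 125.0)))
    xd = sps.decimate(x, factor, zero_phase=True) if factor > 1 else x
    return {
        "WE": wavelet_entropy(x),
        "SpeEnt": spectral_entropy(ps),
        "ApEn": approximate_entropy(xd),
        "FuzzyEn": fuzzy_entropy(xd),
    }


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------

def signal_features(x, fs: float, band=(0.5, 50.0)) -> dict:
    """All 25 signal descriptors of one (denoised) lead-II trace."""
    x = np.asarray(x, dtype=float)
    out = extract_time_features(x, fs)
    ps = power_spectrum(x, fs, band=band)
    out.update(extract_spectral_features(ps))
    out["Hu"] = hurst_rs(x)
    out["ScE"] = dfa_alpha(x)
    out["LAC"] = lac(x)
    out.update(entropy_features(x, ps, fs))
    return {k: out[k] for k in SIGNAL_FEATURES}


_GENDER_CODE = {"female": 0.0, "male": 1.0}


def assemble_feature_table(
    records,
    diagnostics,
    scheme: lio.RhythmScheme,
    denoise: bool = True,
    band=(0.5, 50.0),
    filter_spec: FilterSpec | None = None,
    span_seconds: float = 1.5,
    nlm_params: NLMParams | None = None,
    lead: str = "II",
) -> pd.DataFrame:
    """Build the subjects x 38 feature table with a trailing ``label`` column.

    Per subject: select lead II, optionally denoise, compute the 25 signal
    descriptors, join the 13 metadata features (age, gender coded
    female=0/male=1, 11 MUSE attributes) and attach the scheme label.  Records
    without a diagnostics row (or with a scheme-excluded rhythm) are skipped
    with a log entry.
    """
    diag_by_id = {d.record_id: d for d in diagnostics}
    rows, index = [], []
    for rec in records:
        diag = diag_by_id.get(rec.record_id)
        if diag is None:
            log.warning("record %s has no diagnostics row; skipped", rec.record_id)
            continue
        if diag.rhythm in scheme.excluded:
            log.info("record %s rhythm %s excluded by scheme %s",
                     rec.record_id, diag.rhythm, scheme.name)
            continue
        x = lio.select_lead(rec, lead)
        if denoise:
            x = denoise_pipeline(x, rec.fs, filter_spec, span_seconds, nlm_params)
        feats = signal_features(x, rec.fs, band=band)
        meta = {"age": diag.age,
                "gender": _GENDER_CODE.get(diag.sex, np.nan)}
        meta.update({k: diag.muse[k] for k in lio.MUSE_ATTRIBUTES})
        row = {**meta, **feats, "label": scheme.label(diag.rhythm)}
        rows.append(row)
        index.append(rec.record_id)
    columns = list(METADATA_FEATURES) + list(SIGNAL_FEATURES) + ["label"]
    table = pd.DataFrame(rows, index=pd.Index(index, name="record_id"),
                         columns=columns)
    return table
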