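"""Three-stage ECG cleaning chain: band-pass 0.5-50 Hz, LOESS baseline removal,
non-local-means (NLM) smoothing.

The band-pass strips DC offset, slow drift and everything above the clinically
relevant band; LOESS (local-linear, tricube weights) removes residual baseline
wander; NLM averages each sample with samples whose surrounding patches look
alike anywhere in the search window, which suppresses broadband noise while
preserving sharp QRS morphology.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import signal as sps
from sklearn.base import BaseEstimator, TransformerMixin
from statsmodels.nonparametric.smoothers_lowess import lowess

__all__ = [
    "FilterSpec",
    "NLMParams",
    "ConfigurationError",
    "bandpass",
    "loess_baseline",
    "nlm_denoise",
    "denoise_pipeline",
    "ECGDenoiser",
]


class ConfigurationError(ValueError):
    """Denoising parameters violate their invariants."""


@dataclasses.dataclass(frozen=True)
class FilterSpec:
    """Butterworth band-pass specification (defaults: 0.5-50 Hz, order 4, zero phase)."""

    low: float = 0.5
    high: float = 50.0
    order: int = 4
    zero_phase: bool = True

    def validate(self, fs: float) -> None:
        if not (0.0 < self.low < self.high < fs / 2):
            raise ConfigurationError(
                f"band edges must satisfy 0 < low < high < fs/2; "
                f"got low={self.low}, high={self.high}, fs={fs}"
            )
        if self.order < 1:
            raise ConfigurationError(f"filter order must be >= 1, got {self.order}")


@dataclasses.dataclass(frozen=True)
class NLMParams:
    """Non-local-means parameters.

    ``search_half_width`` may be the string ``"full"`` to search the entire
    signal (O(N^2)).  ``h_scale`` multiplies the robust noise-SD estimate to
    give the similarity bandwidth.
    """

    patch_half_width: int = 10
    search_half_width: int | str = 500
    h_scale: float = 0.6

    def validate(self) -> None:
        if self.patch_half_width < 1:
            raise ConfigurationError("patch_half_width must be >= 1")
        if self.search_half_width != "full" and int(self.search_half_width) < 1:
            raise ConfigurationError("search_half_width must be >= 1 or 'full'")
        if self.h_scale <= 0:
            raise ConfigurationError("h_scale must be > 0")


def bandpass(x, fs: float, spec: FilterSpec | None = None) -> np.ndarray:
    """Band-pass filter ``x``; zero-phase (forward-backward) by default."""
    spec = spec or FilterSpec()
    spec.validate(fs)
    x = np.asarray(x, dtype=float)
    if x.size < 3 * spec.order:
        raise ConfigurationError(
            f"signal of length {x.size} too short for order-{spec.order} filter"
        )
    sos = sps.butter(spec.order, [spec.low, spec.high], btype="bandpass",
                     fs=fs, output="sos")
    if spec.zero_phase:
        return sps.sosfiltfilt(sos, x)
    return sps.sosfilt(sos, x)


def loess_baseline(x, fs: float, span_seconds: float = 1.5):
    """Local-linear tricube-weighted baseline fit.

    Returns ``(baseline, detrended)`` with ``detrended = x - baseline``.  The
    span (default 1.5 s) is wide enough that wander below ~0.5 Hz lands in the
    baseline while QRS complexes are left in the residual.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    window = span_seconds * fs
    if window < 10:
        raise ConfigurationError(
            f"LOESS span of {span_seconds} s at {fs} Hz covers only "
            f"{window:.0f} samples (< 10)"
        )
    t = np.arange(n, dtype=float)
    frac = min(1.0, window / n)
    # delta interpolates linearly between anchors; exact for the local-linear fit
    baseline = lowess(x, t, frac=frac, it=0, delta=0.002 * n, return_sorted=False)
    return baseline, x - baseline


def estimate_noise_sd(x) -> float:
    """Robust noise SD from the median absolute first difference."""
    x = np.asarray(x, dtype=float)
    return float(np.median(np.abs(np.diff(x))) / 0.6745 / np.sqrt(2.0))


def nlm_denoise(x, params: NLMParams | None = None) -> np.ndarray:
    """1-D non-local means.

    Each output sample is a convex combination of candidate samples within the
    search window, weighted by ``exp(-d2 / (h^2 * L))`` where ``d2`` is the
    squared Euclidean distance between the length-``L`` patches centred on the
    two samples and ``h = h_scale * sigma_hat``.  The centre sample's own
    weight is set to the maximum off-centre weight.
    """
    params = params or NLMParams()
    params.validate()
    x = np.asarray(x, dtype=float)
    n = x.size
    p = params.patch_half_width
    if n <= 2 * p:
        raise ConfigurationError(
            f"signal of length {n} too short for patch half-width {p}"
        )
    s = n - 1 if params.search_half_width == "full" else int(params.search_half_width)
    s = min(s, n - 1)
    sigma = estimate_noise_sd(x)
    if sigma == 0.0:
        return x.copy()
    h2 = (params.h_scale * sigma) ** 2
    patch_len = 2 * p + 1

    pad = s + p
    xp = np.pad(x, pad, mode="reflect")
    num = np.zeros(n)
    den = np.zeros(n)
    wmax = np.zeros(n)
    base = pad  # index of x[0] inside xp
    for t in range(-s, s + 1):
        if t == 0:
            continue
        # squared differences on the region covering all patches of x
        a = base - p
        seg = xp[a : a + n + 2 * p]
        seg_t = xp[a + t : a + t + n + 2 * p]
        d = seg - seg_t
        cs = np.concatenate(([0.0], np.cumsum(d * d)))
        d2 = cs[patch_len:] - cs[:-patch_len]  # length n, patch distance at each centre
        w = np.exp(-d2 / (h2 * patch_len))
        num += w * xp[base + t : base + t + n]
        den += w
        np.maximum(wmax, w, out=wmax)
    num += wmax * x
    den += wmax
    # if every candidate weight underflowed, keep the sample unchanged
    ok = den > 0
    out = x.copy()
    out[ok] = num[ok] / den[ok]
    return out


def denoise_pipeline(
    x,
    fs: float,
    filter_spec: FilterSpec | None = None,
    span_seconds: float = 1.5,
    nlm_params: NLMParams | None = None,
) -> np.ndarray:
    """Full cleaning chain in order: band-pass -> LOESS detrend -> NLM."""
    y = bandpass(x, fs, filter_spec)
    _, y = loess_baseline(y, fs, span_seconds)
    return nlm_denoise(y, nlm_params)


class ECGDenoiser(TransformerMixin, BaseEstimator):
    """Scikit-learn transformer applying the cleaning chain row-wise.

    Stateless: :meth:`fit` only records the input width.  ``X`` is an
    ``(n_records, n_samples)`` array of single-lead signals.

    Parameters
    ----------
    fs : sampling rate in Hz.
    low, high, order, zero_phase : band-pass design (see :class:`FilterSpec`).
    span_seconds : LOESS span.
    patch_half_width, search_half_width, h_scale : NLM parameters.
    """

    def __init__(self, fs=500.0, low=0.5, high=50.0, order=4, zero_phase=True,
                 span_seconds=1.5, patch_half_width=10, search_half_width=500,
                 h_scale=0.6):
        self.fs = fs
        self.low = low
        self.high = high
        self.order = order
        self.zero_phase = zero_phase
        self.span_seconds = span_seconds
        self.patch_half_width = patch_half_width
        self.search_half_width = search_half_width
        self.h_scale = h_scale

    def _specs(self):
        return (
            FilterSpec(self.low, self.high, self.order, self.zero_phase),
            NLMParams(self.patch_half_width, self.search_half_width, self.h_scale),
        )

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        fspec, nparams = self._specs()
        fspec.validate(self.fs)
        nparams.validate()
        self.n_features_in_ = X.shape[1] if X.ndim == 2 else X.shape[0]
        return self

    def transform(self, X):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        fspec, nparams = self._specs()
        return np.vstack(
            [denoise_pipeline(row, self.fs, fspec, self.span_seconds, nparams)
             for row in X]
        )
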