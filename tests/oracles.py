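"""Independent brute-force oracles: direct-formula implementations with plain
loops, kept deliberately free of the package's own code paths."""

import math

import numpy as np


# --- time domain -----------------------------------------------------------

def amplitude_range(x):
    return max(x) - min(x)


def mean_amplitude(x):
    return sum(abs(v) for v in x) / len(x)


def median_stepping_increment(x):
    steps = sorted(abs(x[i + 1] - x[i]) for i in range(len(x) - 1))
    n = len(steps)
    return steps[n // 2] if n % 2 else 0.5 * (steps[n // 2 - 1] + steps[n // 2])


def signal_integral(x, fs):
    return sum(abs(v) for v in x) / fs


def rms(x):
    return math.sqrt(sum(v * v for v in x) / len(x))


def mean_slope(x, fs):
    return sum(abs(x[i + 1] - x[i]) for i in range(len(x) - 1)) / (len(x) - 1) * fs


def median_slope(x, fs):
    d = sorted(x[i + 1] - x[i] for i in range(len(x) - 1))
    n = len(d)
    med = d[n // 2] if n % 2 else 0.5 * (d[n // 2 - 1] + d[n // 2])
    return med * fs


def sneo(x):
    """Mean Bartlett(7)-smoothed Teager energy, 'same'-mode convolution."""
    psi = [x[n] ** 2 - x[n - 1] * x[n + 1] for n in range(1, len(x) - 1)]
    win = np.bartlett(7)
    win = list(win / win.sum())
    m = len(psi)
    sm = []
    # numpy 'same' convolution: output i = sum_k psi[i - 3 + k] * win[6 - k]
    for i in range(m):
        acc = 0.0
        for k in range(7):
            j = i + 3 - k  # index into psi for reversed kernel
            if 0 <= j < m:
                acc += psi[j] * win[k]
        sm.append(acc)
    return sum(sm) / m


# --- spectral (operate on a given frequency grid + power/amplitude) --------

def band_select(freqs, values, lo, hi):
    return [(f, v) for f, v in zip(freqs, values) if lo <= f <= hi]


def centroid_frequency(freqs, power, lo, hi):
    sel = band_select(freqs, power, lo, hi)
    tot = sum(p for _, p in sel)
    return sum(f * p for f, p in sel) / tot


def peak_frequency(freqs, power, lo, hi):
    sel = band_select(freqs, power, lo, hi)
    return max(sel, key=lambda fp: fp[1])[0]


def total_energy(freqs, power, lo, hi):
    return sum(p for _, p in band_select(freqs, power, lo, hi))


def max_power(freqs, power, lo, hi):
    return max(p for _, p in band_select(freqs, power, lo, hi))


def spectral_flatness(freqs, power, lo, hi):
    sel = [p for _, p in band_select(freqs, power, lo, hi)]
    if any(p <= 0 for p in sel):
        return 0.0
    log_mean = sum(math.log(p) for p in sel) / len(sel)
    return math.exp(log_mean) / (sum(sel) / len(sel))


def amplitude_spectrum_area(freqs, amplitude, lo, hi):
    return sum(f * a for f, a in band_select(freqs, amplitude, lo, hi))


def spectral_entropy(freqs, power, lo, hi):
    sel = [p for _, p in band_select(freqs, power, lo, hi)]
    tot = sum(sel)
    ent = 0.0
    for p in sel:
        if p > 0:
            q = p / tot
            ent -= q * math.log(q)
    return ent / math.log(len(sel))


# --- nonlinear -------------------------------------------------------------

def lac(x, max_lag=50):
    n = len(x)
    mean = sum(x) / n
    z = [v - mean for v in x]
    denom = sum(v * v for v in z)
    total = 0.0
    for k in range(1, max_lag + 1):
        rho = sum(z[i] * z[i + k] for i in range(n - k)) / denom
        total += abs(rho)
    return math.log10(total)


def approximate_entropy(x, m=2, r=None):
    n = len(x)
    if r is None:
        mean = sum(x) / n
        r = 0.2 * math.sqrt(sum((v - mean) ** 2 for v in x) / n)

    def phi(mm):
        templates = [x[i : i + mm] for i in range(n - mm + 1)]
        total = 0.0
        for a in templates:
            count = 0
            for b in templates:
                if max(abs(u - v) for u, v in zip(a, b)) <= r:
                    count += 1
            total += math.log(count / len(templates))
        return total / len(templates)

    return phi(m) - phi(m + 1)


def mutual_information_bits(x, y):
    n = len(x)
    from collections import Counter
    cx, cy, cxy = Counter(x), Counter(y), Counter(zip(x, y))
    mi = 0.0
    for (a, b), c in cxy.items():
        pxy = c / n
        mi += pxy * math.log2(pxy / (cx[a] / n * cy[b] / n))
    return mi


# --- cluster validity ------------------------------------------------------

def _dist(a, b):
    return math.sqrt(sum((u - v) ** 2 for u, v in zip(a, b)))


def silhouette_mean(X, labels):
    n = len(X)
    classes = sorted(set(labels))
    vals = []
    for i in range(n):
        by_class = {c: [] for c in classes}
        for j in range(n):
            if j != i:
                by_class[labels[j]].append(_dist(X[i], X[j]))
        a = sum(by_class[labels[i]]) / len(by_class[labels[i]])
        b = min(sum(d) / len(d) for c, d in by_class.items()
                if c != labels[i] and d)
        vals.append((b - a) / max(a, b))
    return sum(vals) / n


def davies_bouldin(X, labels):
    classes = sorted(set(labels))
    cents, scatters = {}, {}
    for c in classes:
        pts = [x for x, l in zip(X, labels) if l == c]
        cent = [sum(col) / len(pts) for col in zip(*pts)]
        cents[c] = cent
        scatters[c] = sum(_dist(p, cent) for p in pts) / len(pts)
    total = 0.0
    for ci in classes:
        total += max((scatters[ci] + scatters[cj]) / _dist(cents[ci], cents[cj])
                     for cj in classes if cj != ci)
    return total / len(classes)


def calinski_harabasz(X, labels):
    n, k = len(X), len(set(labels))
    overall = [sum(col) / n for col in zip(*X)]
    between = within = 0.0
    for c in sorted(set(labels)):
        pts = [x for x, l in zip(X, labels) if l == c]
        cent = [sum(col) / len(pts) for col in zip(*pts)]
        between += len(pts) * _dist(cent, overall) ** 2
        within += sum(_dist(p, cent) ** 2 for p in pts)
    return (between / (k - 1)) / (within / (n - k))
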