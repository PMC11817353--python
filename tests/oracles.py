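"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written as literal nested loops or direct
definitions, independent of the production implementations it checks.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import find_peaks

from coromix.ecg_io import CLASS_NAMES, LEAD_NAMES
from coromix.synthetic import territory_leads


def relieff_bruteforce(X, y, k=10, sigma=20.0):
    """Literal nested-loop ReliefF with exponential rank weighting."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n, p = X.shape
    rng_span = X.max(axis=0) - X.min(axis=0)
    safe = np.where(rng_span > 0, rng_span, 1.0)
    classes = sorted(set(y.tolist()))
    priors = {c: np.mean(y == c) for c in classes}
    W = np.zeros(p)
    for i in range(n):
        for c in classes:
            cand = [j for j in range(n) if y[j] == c and j != i]
            if not cand:
                continue
            dists = [sum(abs(X[i, f] - X[j, f]) / safe[f] for f in range(p))
                     for j in cand]
            order = [cand[j] for j in np.argsort(dists, kind="stable")]
            kk = min(k, len(order))
            nearest = order[:kk]
            d = np.array([np.exp(-(((r + 1) / sigma) ** 2)) for r in range(kk)])
            d = d / d.sum()
            for rank, j in enumerate(nearest):
                for f in range(p):
                    diff = abs(X[i, f] - X[j, f]) / safe[f]
                    if c == y[i]:
                        W[f] -= d[rank] * diff / n
                    else:
                        W[f] += (priors[c] / (1.0 - priors[y[i]])) * d[rank] * diff / n
    W[rng_span == 0] = 0.0
    return W


def dft_magnitude_frame(signal, start, window, nfft):
    """|DFT| of one Hamming-windowed frame by the definition sum."""
    frame = np.asarray(signal[start : start + window], dtype=float) * np.hamming(window)
    padded = np.concatenate([frame, np.zeros(nfft - window)])
    bins = nfft // 2 + 1
    out = np.empty(bins)
    for k in range(bins):
        re = sum(padded[t] * np.cos(-2 * np.pi * k * t / nfft) for t in range(nfft))
        im = sum(padded[t] * np.sin(-2 * np.pi * k * t / nfft) for t in range(nfft))
        out[k] = np.hypot(re, im)
    return out


def confusion_bruteforce(y_true, y_pred, classes):
    cm = np.zeros((len(classes), len(classes)), dtype=int)
    for i, ci in enumerate(classes):
        for j, cj in enumerate(classes):
            cm[i, j] = sum(
                1 for t, p in zip(y_true, y_pred) if t == ci and p == cj
            )
    return cm


def st_deviation_per_lead(record):
    """Mean ST-window level minus PR baseline, per lead, averaged over beats."""
    fs = record.fs
    ii = record.leads["II"]
    peaks, _ = find_peaks(ii, height=0.4 * ii.max(), distance=int(0.4 * fs))
    devs = {}
    for lead in LEAD_NAMES:
        x = record.leads[lead]
        vals = []
        for r in peaks:
            st0, st1 = r + int(0.045 * fs), r + int(0.125 * fs)
            pr0, pr1 = r - int(0.120 * fs), r - int(0.060 * fs)
            if pr0 < 0 or st1 > len(x):
                continue
            vals.append(x[st0:st1].mean() - x[pr0:pr1].mean())
        devs[lead] = float(np.mean(vals)) if vals else 0.0
    return devs


def territory_rule_classifier(record, threshold):
    """Assign the class whose lead territory best matches the depressed leads."""
    devs = st_deviation_per_lead(record)
    depressed = {l for l in LEAD_NAMES if l != "aVR" and -devs[l] > threshold}
    best, best_d = None, len(LEAD_NAMES) + 1
    for c in CLASS_NAMES:
        d = len(depressed ^ set(territory_leads(c)))
        if d < best_d:
            best, best_d = c, d
    return best
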