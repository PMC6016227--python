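"""Independent brute-force oracles used only by the tests.

These deliberately avoid the vectorized code paths of the package:
plain double loops and direct enumeration, so agreement is meaningful.
"""

from __future__ import annotations

import math

import numpy as np


def brute_force_match_counts(series, m: int, r: float) -> tuple[int, int]:
    """O(N^2 m) double-loop template match counts (B at m, A at m+1).

    Templates of both lengths start at indices 0..N-m-1; Chebyshev
    distance strictly below r * SD; unordered pairs i < j.
    """
    x = [float(v) for v in series]
    n = len(x)
    mean = sum(x) / n
    sd = math.sqrt(sum((v - mean) ** 2 for v in x) / n)
    tol = r * sd
    n_templates = n - m
    b = 0
    a = 0
    for i in range(n_templates):
        for j in range(i + 1, n_templates):
            d_m = max(abs(x[i + k] - x[j + k]) for k in range(m))
            if d_m < tol:
                b += 1
                d_m1 = max(d_m, abs(x[i + m] - x[j + m]))
                if d_m1 < tol:
                    a += 1
    return b, a


def brute_force_sampen(series, m: int, r: float) -> float:
    """-ln(A/B) from the double-loop counts; NaN when undefined."""
    b, a = brute_force_match_counts(series, m, r)
    if b == 0 or a == 0:
        return float("nan")
    return -math.log(a / b)


def brute_force_extrema(series) -> tuple[list[int], list[int]]:
    """Strict interior extrema by direct neighbour comparison (no plateaus)."""
    x = list(series)
    maxima = [i for i in range(1, len(x) - 1) if x[i] > x[i - 1] and x[i] > x[i + 1]]
    minima = [i for i in range(1, len(x) - 1) if x[i] < x[i - 1] and x[i] < x[i + 1]]
    return maxima, minima


def dominant_frequency(signal, fs: float) -> float:
    """Location (Hz) of the largest FFT magnitude peak, DC excluded."""
    x = np.asarray(signal, dtype=float)
    spec = np.abs(np.fft.rfft(x - x.mean()))
    freqs = np.fft.rfftfreq(x.size, d=1.0 / fs)
    return float(freqs[1:][np.argmax(spec[1:])])


def confusion_accuracy(y_true, y_pred) -> float:
    """Accuracy via an explicit confusion-matrix tally."""
    labels = sorted(set(list(y_true) + list(y_pred)))
    idx = {c: i for i, c in enumerate(labels)}
    mat = [[0] * len(labels) for _ in labels]
    for t, p in zip(y_true, y_pred):
        mat[idx[t]][idx[p]] += 1
    correct = sum(mat[i][i] for i in range(len(labels)))
    return correct / len(list(y_true))
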