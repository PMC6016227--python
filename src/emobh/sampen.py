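"""Sample entropy (SampEn) of short physiological time series.

SampEn(m, r, N) is the negative natural logarithm of the conditional
probability that two sequences similar for ``m`` points (Chebyshev
distance below a tolerance) remain similar at ``m + 1`` points.  Low
values indicate regular, self-similar signals; high values indicate
irregularity.  Self-matches are excluded, which is what distinguishes
SampEn from approximate entropy and gives it better statistical
consistency on short windows.

Conventions used here (Richman & Moorman):

* templates of length ``m`` and ``m + 1`` are both formed from start
  indices ``0 .. N - m - 1`` so the two populations match and the
  constant pair-count denominators cancel in the ratio;
* distance is Chebyshev (max over components), strictly below tolerance;
* tolerance is ``r`` times the standard deviation of the analyzed
  window (per-window, not per-recording).

When no template pair matches at either length the conditional
probability is undefined; :data:`UNDEFINED` (NaN) is returned so callers
can apply their own imputation policy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist

__all__ = [
    "SampEnParams",
    "MatchCounts",
    "UNDEFINED",
    "count_matches",
    "sample_entropy",
    "windowed_sample_entropy",
]

#: Sentinel for undefined entropy (no matches, or zero-variance input).
UNDEFINED: float = float("nan")


@dataclass(frozen=True)
class SampEnParams:
    """Parameters of the sample-entropy statistic.

    Attributes
    ----------
    m : embedding dimension (template length), default 2.
    r : tolerance as a fraction of the window standard deviation,
        default 0.15.
    window : window length in samples over which SampEn is evaluated,
        default 128.  Longer series are split into non-overlapping
        windows of this length whose entropies are averaged (see
        :func:`windowed_sample_entropy`).
    """

    m: int = 2
    r: float = 0.15
    window: int = 128

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError(f"embedding dimension m must be >= 1, got {self.m}")
        if not 0.0 < self.r < 1.0:
            raise ValueError(f"tolerance fraction r must be in (0, 1), got {self.r}")
        if self.window <= self.m + 1:
            raise ValueError(
                f"window length must exceed m + 1 = {self.m + 1}, got {self.window}"
            )


@dataclass(frozen=True)
class MatchCounts:
    """Template-pair match counts at lengths m (``B``) and m+1 (``A``)."""

    B: int
    A: int

    def __post_init__(self) -> None:
        if not 0 <= self.A <= self.B:
            raise ValueError(f"match counts must satisfy 0 <= A <= B, got A={self.A}, B={self.B}")


def _embed(x: np.ndarray, m: int) -> np.ndarray:
    """Delay-embedding matrix: rows are templates x[i:i+m], i = 0..N-m."""
    n = x.size - m + 1
    return np.lib.stride_tricks.sliding_window_view(x, m)[:n]


def count_matches(series: np.ndarray, params: SampEnParams) -> MatchCounts:
    """Count template pairs within tolerance at lengths m and m+1.

    Pairs are unordered (i < j); self-pairs are excluded.  Both template
    populations use start indices ``0 .. N - m - 1``.

    Raises
    ------
    ValueError
        If the series is shorter than ``m + 2`` samples or has zero
        variance (the tolerance degenerates and similarity is
        meaningless).
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise ValueError("series must be one-dimensional")
    n = x.size
    m = params.m
    if n < m + 2:
        raise ValueError(f"series length {n} too short for m={m} (need >= m + 2)")
    sd = float(np.std(x))
    if sd == 0.0:
        raise ValueError("zero-variance series: sample entropy undefined")
    tol = params.r * sd

    # Templates of both lengths from the same n - m start indices.
    templates_m1 = _embed(x, m + 1)  # (n - m) rows
    templates_m = templates_m1[:, :m]

    d_m = pdist(templates_m, metric="chebyshev")
    d_m1 = pdist(templates_m1, metric="chebyshev")
    b = int(np.count_nonzero(d_m < tol))
    a = int(np.count_nonzero(d_m1 < tol))
    return MatchCounts(B=b, A=a)


def sample_entropy(series: np.ndarray, params: SampEnParams | None = None) -> float:
    """SampEn of a single window: ``-ln(A / B)``.

    Returns :data:`UNDEFINED` (NaN) when ``B == 0`` or ``A == 0``, i.e.
    when the conditional probability cannot be formed or is zero.
    Zero-variance input also yields :data:`UNDEFINED`.
    """
    params = params or SampEnParams()
    try:
        counts = count_matches(series, params)
    except ValueError:
        return UNDEFINED
    if counts.B == 0 or counts.A == 0:
        return UNDEFINED
    return -math.log(counts.A / counts.B)


def windowed_sample_entropy(series: np.ndarray, params: SampEnParams | None = None) -> float:
    """Average SampEn over non-overlapping windows of ``params.window`` samples.

    A frame is split into ``floor(len / window)`` full windows; windows
    with undefined entropy are skipped and the remaining values
    averaged.  If every window is undefined (or the series is shorter
    than one window, in which case the whole series is used as a single
    window) the result is :data:`UNDEFINED`.
    """
    params = params or SampEnParams()
    x = np.asarray(series, dtype=float)
    w = params.window
    if x.size < w:
        return sample_entropy(x, params)
    n_windows = x.size // w
    values = [sample_entropy(x[k * w : (k + 1) * w], params) for k in range(n_windows)]
    defined = [v for v in values if not math.isnan(v)]
    if not defined:
        return UNDEFINED
    return float(np.mean(defined))
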