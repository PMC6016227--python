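"""Empirical Mode Decomposition (EMD) by cubic-spline sifting.

EMD decomposes a signal into a small set of Intrinsic Mode Functions
(IMFs) plus a residue.  An IMF satisfies two conditions: (i) its number
of extrema and number of zero-crossings are equal or differ by at most
one, and (ii) the mean of its upper and lower spline envelopes is
(approximately) zero everywhere.  Sifting extracts an IMF by repeatedly
subtracting the envelope mean; the IMF is then removed from the running
residue and the process repeats, so the decomposition reconstructs the
input exactly by construction (telescoping subtraction).

Choices the classical recipe leaves open, fixed here:

* envelopes are natural cubic splines through the extrema, with the
  first/last two extrema mirrored across the signal boundaries to tame
  end swings;
* plateau extrema contribute their middle sample (deterministic
  tie-break);
* the inner sift loop stops when the candidate passes the IMF check
  with envelope-mean tolerance ``tol_mean`` (fraction of the candidate's
  amplitude range, default 0.05) or after ``max_sifts`` iterations;
* extraction stops early once the residue has at most one interior
  extremum (monotone or single-hump residue).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline

__all__ = [
    "EnvelopePair",
    "IMFSet",
    "find_extrema",
    "envelope_mean",
    "zero_crossings",
    "is_imf",
    "sift",
    "emd_decompose",
]

DEFAULT_TOL_MEAN = 0.05
DEFAULT_MAX_SIFTS = 50


@dataclass(frozen=True)
class EnvelopePair:
    """Upper/lower spline envelopes of a signal and their pointwise mean."""

    upper: np.ndarray
    lower: np.ndarray
    mean: np.ndarray


@dataclass
class IMFSet:
    """Ordered IMFs plus residue from one frame; sums back to the input."""

    imfs: list[np.ndarray]
    residue: np.ndarray
    n_sifts_used: list[int] = field(default_factory=list)

    def reconstruct(self) -> np.ndarray:
        out = self.residue.copy()
        for imf in self.imfs:
            out += imf
        return out


def find_extrema(signal: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indices of strict interior local maxima and minima.

    A plateau (run of equal samples) bounded by strictly lower (higher)
    neighbours on both sides counts as one maximum (minimum) at the
    plateau's middle sample, rounding down.  Endpoints are never
    extrema.
    """
    x = np.asarray(signal, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 samples to locate extrema")

    # Compress equal-value runs so plateaus become single points.
    change = np.flatnonzero(np.diff(x) != 0.0)
    if change.size == 0:  # constant signal
        empty = np.array([], dtype=int)
        return empty, empty
    run_starts = np.concatenate(([0], change + 1))
    run_ends = np.concatenate((change, [x.size - 1]))  # inclusive
    vals = x[run_starts]

    mids = (run_starts + run_ends) // 2
    above_prev = vals[1:-1] > vals[:-2]
    above_next = vals[1:-1] > vals[2:]
    maxima = mids[1:-1][above_prev & above_next]
    minima = mids[1:-1][~above_prev & ~above_next]
    return maxima.astype(int), minima.astype(int)


def _mirrored_spline(idx: np.ndarray, val: np.ndarray, n: int) -> np.ndarray:
    """Natural cubic spline through (idx, val), extended by mirroring the
    first/last two knots across the boundaries, evaluated on 0..n-1."""
    xs = idx.astype(float)
    ys = val.astype(float)
    left_x, left_y = [], []
    for j in (0, 1):
        if j < xs.size and xs[j] > 0:
            left_x.append(-xs[j])
            left_y.append(ys[j])
    right_x, right_y = [], []
    last = n - 1
    for j in (xs.size - 1, xs.size - 2):
        if j >= 0 and xs[j] < last:
            right_x.append(2 * last - xs[j])
            right_y.append(ys[j])
    full_x = np.concatenate((left_x[::-1], xs, right_x))
    full_y = np.concatenate((left_y[::-1], ys, right_y))
    # Mirroring can in principle duplicate an abscissa; keep first occurrence.
    full_x, keep = np.unique(full_x, return_index=True)
    full_y = full_y[keep]
    if full_x.size < 2:
        return np.full(n, ys[0])
    spline = CubicSpline(full_x, full_y, bc_type="natural")
    return spline(np.arange(n))


def envelope_mean(signal: np.ndarray) -> EnvelopePair:
    """Upper/lower cubic-spline envelopes through extrema and their mean.

    Raises
    ------
    ValueError
        If the signal has fewer than 2 maxima or 2 minima — by
        convention such a signal is a residue, not a sifting candidate.
    """
    x = np.asarray(signal, dtype=float)
    maxima, minima = find_extrema(x)
    if maxima.size < 2 or minima.size < 2:
        raise ValueError(
            f"too few extrema for envelopes ({maxima.size} maxima, {minima.size} minima): residue"
        )
    upper = _mirrored_spline(maxima, x[maxima], x.size)
    lower = _mirrored_spline(minima, x[minima], x.size)
    return EnvelopePair(upper=upper, lower=lower, mean=0.5 * (upper + lower))


def zero_crossings(signal: np.ndarray) -> int:
    """Number of sign changes, ignoring exactly-zero samples."""
    x = np.asarray(signal, dtype=float)
    s = np.sign(x)
    s = s[s != 0]
    if s.size < 2:
        return 0
    return int(np.count_nonzero(np.diff(s) != 0))


def is_imf(candidate: np.ndarray, tol_mean: float = DEFAULT_TOL_MEAN) -> bool:
    """Check the two IMF conditions.

    True iff ``|#extrema - #zero-crossings| <= 1`` and the envelope mean
    stays within ``tol_mean`` times the candidate's amplitude range.
    Signals whose envelopes cannot be formed (too few extrema) are
    residues, never IMFs.
    """
    x = np.asarray(candidate, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 samples")
    maxima, minima = find_extrema(x)
    n_ext = maxima.size + minima.size
    if abs(n_ext - zero_crossings(x)) > 1:
        return False
    try:
        env = envelope_mean(x)
    except ValueError:
        return False
    amp = float(x.max() - x.min())
    if amp == 0.0:
        return False
    return float(np.max(np.abs(env.mean))) <= tol_mean * amp


def sift(
    signal: np.ndarray,
    max_sifts: int = DEFAULT_MAX_SIFTS,
    tol_mean: float = DEFAULT_TOL_MEAN,
) -> tuple[np.ndarray, int]:
    """Extract one IMF candidate by iterated envelope-mean subtraction.

    Iterates ``h <- h - envelope_mean(h)`` until ``h`` passes the IMF
    check or ``max_sifts`` is reached.  Returns the candidate and the
    number of sifts performed.

    Raises
    ------
    ValueError
        If the input has too few extrema to form envelopes.
    """
    h = np.asarray(signal, dtype=float).copy()
    maxima, minima = find_extrema(h)
    if maxima.size < 2 or minima.size < 2:
        raise ValueError("too few extrema to sift: signal is a residue")
    n_sifts = 0
    for _ in range(max_sifts):
        try:
            env = envelope_mean(h)
        except ValueError:
            break
        h = h - env.mean
        n_sifts += 1
        if is_imf(h, tol_mean):
            break
    return h, n_sifts


def emd_decompose(
    signal: np.ndarray,
    n_imfs: int = 4,
    max_sifts: int = DEFAULT_MAX_SIFTS,
    tol_mean: float = DEFAULT_TOL_MEAN,
) -> IMFSet:
    """Decompose a frame into at most ``n_imfs`` IMFs plus a residue.

    Extraction stops early once the running residue has at most one
    interior extremum.  ``sum(imfs) + residue`` equals the input to
    floating-point round-off because each IMF is subtracted from the
    running residue (telescoping identity).
    """
    x = np.asarray(signal, dtype=float)
    if x.size < 3:
        raise ValueError("input shorter than 3 samples")
    residue = x.copy()
    imfs: list[np.ndarray] = []
    sift_counts: list[int] = []
    for _ in range(n_imfs):
        maxima, minima = find_extrema(residue)
        if maxima.size + minima.size <= 1:
            break
        try:
            imf, n_used = sift(residue, max_sifts=max_sifts, tol_mean=tol_mean)
        except ValueError:
            break
        if n_used < max_sifts and not is_imf(imf, tol_mean):
            # Sifting aborted early (candidate lost its extrema): what is
            # left belongs to the residue, not to a new IMF.
            break
        imfs.append(imf)
        sift_counts.append(n_used)
        residue = residue - imf
    return IMFSet(imfs=imfs, residue=residue, n_sifts_used=sift_counts)
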