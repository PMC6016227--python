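"""Frame segmentation, beta-band filtering, PSD, and channel selection.

The pipeline works on the EEG beta band (12.5–30 Hz by default), which
carries most of the valence/arousal discrimination here.  Sessions are
band-filtered as a whole (avoiding per-frame edge transients), cut into
fixed-length non-overlapping frames, and the two channels with the
highest mean beta-band power spectral density are retained — mirroring
the practice of picking the most reactive electrodes (e.g. F3/C4) from
a full montage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .synthetic import Session

__all__ = [
    "Frame",
    "BandpassSpec",
    "segment_frames",
    "beta_bandpass",
    "mean_psd",
    "select_channels",
]

BETA_LOW_HZ = 12.5
BETA_HIGH_HZ = 30.0


@dataclass(frozen=True)
class BandpassSpec:
    """Butterworth bandpass design: cutoffs in Hz and filter order."""

    low_hz: float = BETA_LOW_HZ
    high_hz: float = BETA_HIGH_HZ
    order: int = 3

    def validate(self, fs: float) -> None:
        if not (0.0 < self.low_hz < self.high_hz < fs / 2.0):
            raise ValueError(
                f"cutoffs must satisfy 0 < {self.low_hz} < {self.high_hz} < fs/2 = {fs / 2}"
            )
        if self.order < 1:
            raise ValueError("filter order must be >= 1")


@dataclass(frozen=True)
class Frame:
    """One fixed-length window of one channel, labelled by its session."""

    samples: np.ndarray
    fs: float
    session_id: str
    channel_index: int
    label: int  # emotion quadrant, 1..4


def segment_frames(
    session: Session, frame_seconds: int = 9, channels: list[int] | None = None
) -> list[list[Frame]]:
    """Cut a session into consecutive non-overlapping frames per channel.

    Returns one list of time-ordered frames per requested channel (all
    channels by default).  A trailing partial window is discarded.

    Raises
    ------
    ValueError
        If the session is shorter than one frame.
    """
    frame_len = int(round(session.fs * frame_seconds))
    n_samples = session.signal.shape[0]
    n_frames = n_samples // frame_len
    if n_frames < 1:
        raise ValueError(
            f"session of {n_samples} samples shorter than one {frame_len}-sample frame"
        )
    if channels is None:
        channels = list(range(session.signal.shape[1]))
    label = session.class_id
    out: list[list[Frame]] = []
    for ch in channels:
        col = session.signal[:, ch]
        out.append(
            [
                Frame(
                    samples=col[k * frame_len : (k + 1) * frame_len].copy(),
                    fs=session.fs,
                    session_id=session.session_id,
                    channel_index=ch,
                    label=label,
                )
                for k in range(n_frames)
            ]
        )
    return out


def beta_bandpass(
    signal: np.ndarray, fs: float, spec: BandpassSpec = BandpassSpec()
) -> np.ndarray:
    """Zero-phase Butterworth bandpass of one channel.

    The filter is applied forward and backward (``sosfiltfilt``), so the
    phase response is zero and the effective magnitude order doubles;
    this keeps features aligned in time across channels.
    """
    spec.validate(fs)
    sos = sps.butter(
        spec.order, [spec.low_hz, spec.high_hz], btype="bandpass", fs=fs, output="sos"
    )
    return sps.sosfiltfilt(sos, np.asarray(signal, dtype=float))


def mean_psd(
    signal: np.ndarray,
    fs: float,
    band: tuple[float, float] = (BETA_LOW_HZ, BETA_HIGH_HZ),
) -> float:
    """Mean power spectral density inside a band (default: beta).

    Welch estimate with 1-second Hann segments and 50% overlap, averaged
    over the frequency bins falling in ``band`` (inclusive).

    Raises
    ------
    ValueError
        If the signal is shorter than two PSD segments (2 s).
    """
    x = np.asarray(signal, dtype=float)
    nperseg = int(fs)
    if x.size < 2 * nperseg:
        raise ValueError(f"need at least {2 * nperseg} samples for a Welch PSD estimate")
    freqs, psd = sps.welch(x, fs=fs, window="hann", nperseg=nperseg, noverlap=nperseg // 2)
    in_band = (freqs >= band[0]) & (freqs <= band[1])
    return float(np.mean(psd[in_band]))


def select_channels(session: Session, k: int = 2) -> list[int]:
    """Indices of the ``k`` channels with highest mean beta-band PSD.

    Returned in descending PSD order; ties broken by lower channel
    index.  With the default two-channel synthetic sessions this is the
    identity selection, but on wider montages it mimics choosing the
    most beta-active electrodes.
    """
    n_channels = session.signal.shape[1]
    if k > n_channels:
        raise ValueError(f"cannot select {k} channels from {n_channels}")
    psds = [mean_psd(session.signal[:, ch], session.fs) for ch in range(n_channels)]
    order = sorted(range(n_channels), key=lambda ch: (-psds[ch], ch))
    return order[:k]
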