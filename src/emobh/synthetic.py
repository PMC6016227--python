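"""Labelled synthetic EEG-like sessions for the emotion-quadrant pipeline.

Real affective-EEG corpora are access-restricted, so the pipeline is
exercised on generated two-channel sessions that reproduce the
statistical structure the method relies on:

* a beta-band oscillation (random centre frequency in 12.5–30 Hz) whose
  amplitude encodes the *arousal* level — high-arousal classes carry a
  stronger beta rhythm;
* additive Gaussian noise whose standard deviation encodes the
  *valence* level — low-valence classes are noisier, hence more
  irregular, hence higher sample entropy in the fast IMFs;
* a slow sinusoidal drift common to both channels, standing in for
  baseline wander.

The two channels share the class structure but receive independent
noise draws and phases.  Emotion classes are the quadrants of the
valence/arousal plane in counter-clockwise order:

====  =======  =======
code  valence  arousal
====  =======  =======
1     high     high
2     low      high
3     low      low
4     high     low
====  =======  =======

The generator makes no attempt to mimic full EEG spectra (no 1/f
background, alpha rhythm, or blink artifacts); it provides exactly the
beta-power and irregularity contrasts the feature extractor is built to
detect.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "QUADRANTS",
    "SessionSpec",
    "Session",
    "EffectSizes",
    "generate_session",
    "generate_dataset",
    "write_dataset",
    "read_dataset",
]

#: class id -> (valence, arousal), counter-clockwise quadrants of the
#: Circumplex valence/arousal plane.
QUADRANTS: dict[int, tuple[str, str]] = {
    1: ("high", "high"),
    2: ("low", "high"),
    3: ("low", "low"),
    4: ("high", "low"),
}

DEFAULT_FS = 128.0
FRAME_SECONDS = 9


@dataclass(frozen=True)
class EffectSizes:
    """Class-contrast knobs of the generator.

    ``beta_amp_high/low`` set the beta-oscillation amplitude for high
    vs. low arousal (default ratio 2:1); ``noise_sd_high/low`` set the
    additive-noise SD for low vs. high valence (low valence = high
    noise, ratio 2:1).  Defaults separate the classes clearly without
    making the task trivial.
    """

    beta_amp_high: float = 2.0
    beta_amp_low: float = 1.0
    noise_sd_high: float = 1.0  # low valence: irregular signal
    noise_sd_low: float = 0.5  # high valence: smoother signal
    drift_amp: float = 0.5
    drift_hz: float = 0.3
    n_channels: int = 2


@dataclass(frozen=True)
class SessionSpec:
    """Recipe for one synthetic session."""

    class_id: int
    duration_s: float = 36.0
    fs: float = DEFAULT_FS
    seed: int = 0
    effects: EffectSizes = field(default_factory=EffectSizes)

    def __post_init__(self) -> None:
        if self.class_id not in QUADRANTS:
            raise ValueError(f"class_id must be in {{1,2,3,4}}, got {self.class_id}")
        n = self.duration_s * self.fs
        if abs(n - round(n)) > 1e-9:
            raise ValueError(
                f"duration_s * fs = {n} is not an integer sample count"
            )
        if round(n) < self.fs * FRAME_SECONDS:
            raise ValueError(
                f"session must contain at least one {FRAME_SECONDS}-s frame"
            )

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.fs))


@dataclass(frozen=True)
class Session:
    """A labelled multichannel recording (samples x channels)."""

    signal: np.ndarray
    fs: float
    valence: str
    arousal: str
    session_id: str = ""

    def __post_init__(self) -> None:
        if self.signal.ndim != 2 or self.signal.shape[1] < 2:
            raise ValueError("signal must be samples x channels with >= 2 channels")
        if not np.all(np.isfinite(self.signal)):
            raise ValueError("signal contains non-finite samples")

    @property
    def class_id(self) -> int:
        for cid, (v, a) in QUADRANTS.items():
            if (v, a) == (self.valence, self.arousal):
                return cid
        raise ValueError(f"no quadrant for valence={self.valence}, arousal={self.arousal}")


def generate_session(spec: SessionSpec) -> Session:
    """Generate one session; bit-identical output for identical specs."""
    rng = np.random.default_rng(spec.seed)
    valence, arousal = QUADRANTS[spec.class_id]
    eff = spec.effects
    beta_amp = eff.beta_amp_high if arousal == "high" else eff.beta_amp_low
    noise_sd = eff.noise_sd_low if valence == "high" else eff.noise_sd_high

    n = spec.n_samples
    t = np.arange(n) / spec.fs
    # Session-level beta rhythm: one centre frequency per session, well
    # inside the analysis band.
    f_beta = rng.uniform(13.0, 29.0)
    drift = eff.drift_amp * np.sin(2 * np.pi * eff.drift_hz * t + rng.uniform(0, 2 * np.pi))

    channels = []
    for _ in range(eff.n_channels):
        phase = rng.uniform(0, 2 * np.pi)
        beta = beta_amp * np.sin(2 * np.pi * f_beta * t + phase)
        noise = rng.normal(0.0, noise_sd, size=n)
        channels.append(beta + drift + noise)
    sig = np.column_stack(channels)
    return Session(
        signal=sig,
        fs=spec.fs,
        valence=valence,
        arousal=arousal,
        session_id=f"c{spec.class_id}_s{spec.seed}",
    )


def generate_dataset(
    n_per_class: int,
    base_seed: int = 0,
    duration_s: float = 36.0,
    fs: float = DEFAULT_FS,
    effects: EffectSizes | None = None,
) -> list[Session]:
    """Balanced dataset: ``4 * n_per_class`` sessions, seeds derived from
    ``base_seed`` deterministically (class-major order)."""
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    effects = effects or EffectSizes()
    sessions = []
    seed = base_seed
    for class_id in sorted(QUADRANTS):
        for _ in range(n_per_class):
            sessions.append(
                generate_session(
                    SessionSpec(
                        class_id=class_id,
                        duration_s=duration_s,
                        fs=fs,
                        seed=seed,
                        effects=effects,
                    )
                )
            )
            seed += 1
    return sessions


def write_dataset(sessions: list[Session], out_dir: str | Path) -> Path:
    """Write sessions as per-session CSVs plus a manifest.

    Each session becomes ``<session_id>.csv`` with header ``ch1,ch2,...``
    and no index column; the manifest ``manifest.csv`` has columns
    ``session_id, path, fs, valence, arousal``.  Returns the manifest
    path.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in sessions:
        fname = f"{s.session_id}.csv"
        cols = {f"ch{i + 1}": s.signal[:, i] for i in range(s.signal.shape[1])}
        pd.DataFrame(cols).to_csv(out_dir / fname, index=False, float_format="%.8g")
        rows.append(
            {
                "session_id": s.session_id,
                "path": fname,
                "fs": s.fs,
                "valence": s.valence,
                "arousal": s.arousal,
            }
        )
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def read_dataset(manifest_path: str | Path) -> list[Session]:
    """Load sessions from a manifest written by :func:`write_dataset`.

    User-supplied real recordings in the same shape (CSV per session,
    one column per channel) are accepted identically.
    """
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    table = pd.read_csv(manifest_path)
    sessions = []
    for row in table.itertuples(index=False):
        sig = pd.read_csv(base / row.path).to_numpy(dtype=float)
        sessions.append(
            Session(
                signal=sig,
                fs=float(row.fs),
                valence=str(row.valence),
                arousal=str(row.arousal),
                session_id=str(row.session_id),
            )
        )
    return sessions
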