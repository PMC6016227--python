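"""Per-frame 8-dimensional sample-entropy feature vectors.

Each 9-second frame of the two selected channels is decomposed by EMD
into its first four IMFs; the sample entropy of each IMF forms the
feature vector, ordered channel A IMF1..4 then channel B IMF1..4, with
the session's emotion quadrant as the label.

Two edge cases the decomposition can produce are handled
deterministically:

* fewer than four IMFs available → the residue's entropy fills the
  missing slots, keeping the vector length fixed at 8;
* undefined SampEn (no template matches anywhere in a frame-IMF) →
  imputed, table-wide, with the maximum *defined* value observed for
  that component, since zero matches indicates maximal irregularity.
  The imputation count is recorded on the table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .emd import emd_decompose
from .preprocess import BandpassSpec, Frame, beta_bandpass, segment_frames, select_channels
from .sampen import SampEnParams, windowed_sample_entropy, sample_entropy
from .synthetic import QUADRANTS, Session

__all__ = [
    "PipelineConfig",
    "FeatureTable",
    "quadrant_label",
    "frame_features",
    "extract_features",
]

logger = logging.getLogger(__name__)

N_FEATURES = 8


@dataclass(frozen=True)
class PipelineConfig:
    """Feature-extraction settings: filtering, framing, EMD and SampEn."""

    frame_seconds: int = 9
    n_imfs: int = 4
    max_sifts: int = 50
    tol_mean: float = 0.05
    n_channels: int = 2
    bandpass: BandpassSpec = field(default_factory=BandpassSpec)
    sampen: SampEnParams = field(default_factory=SampEnParams)
    #: if True, SampEn over whole frames instead of averaged 128-sample windows
    whole_frame_sampen: bool = False


@dataclass
class FeatureTable:
    """Feature matrix + labels with the parameters that produced them."""

    frame: pd.DataFrame  # columns: frame_id, f1..f8, label
    config: PipelineConfig = field(default_factory=PipelineConfig)
    n_imputed: int = 0

    @property
    def X(self) -> np.ndarray:
        return self.frame[[f"f{i + 1}" for i in range(N_FEATURES)]].to_numpy(dtype=float)

    @property
    def y(self) -> np.ndarray:
        return self.frame["label"].to_numpy(dtype=int)

    def __len__(self) -> int:
        return len(self.frame)

    def to_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path, index=False, float_format="%.12g")

    @classmethod
    def from_csv(cls, path: str | Path, config: PipelineConfig | None = None) -> "FeatureTable":
        return cls(frame=pd.read_csv(path), config=config or PipelineConfig())


def quadrant_label(valence: str, arousal: str) -> int:
    """Map (valence, arousal) levels to the emotion-quadrant class 1..4."""
    for cid, pair in QUADRANTS.items():
        if pair == (valence, arousal):
            return cid
    raise ValueError(f"invalid levels: valence={valence!r}, arousal={arousal!r}")


def _imf_entropies(samples: np.ndarray, config: PipelineConfig) -> list[float]:
    """SampEn of the first ``n_imfs`` IMFs of one frame channel.

    Missing IMF slots (early decomposition stop) are filled with the
    residue's entropy.  Values may be NaN (undefined); imputation
    happens at table level.
    """
    decomp = emd_decompose(
        samples,
        n_imfs=config.n_imfs,
        max_sifts=config.max_sifts,
        tol_mean=config.tol_mean,
    )
    entropy = (
        sample_entropy if config.whole_frame_sampen else windowed_sample_entropy
    )
    values = [entropy(imf, config.sampen) for imf in decomp.imfs]
    if len(values) < config.n_imfs:
        logger.debug(
            "decomposition stopped at %d IMFs; padding with residue entropy", len(values)
        )
        residue_h = entropy(decomp.residue, config.sampen)
        values.extend([residue_h] * (config.n_imfs - len(values)))
    return values


def frame_features(
    frame_ch_a: Frame, frame_ch_b: Frame, config: PipelineConfig | None = None
) -> tuple[list[float], int]:
    """Raw 8-vector for one frame pair: chA IMF1..4 then chB IMF1..4.

    Returns (values, label); values may contain NaN pending table-level
    imputation.
    """
    config = config or PipelineConfig()
    if len(frame_ch_a.samples) != len(frame_ch_b.samples):
        raise ValueError("channel frames have mismatched lengths")
    if frame_ch_a.label != frame_ch_b.label or frame_ch_a.session_id != frame_ch_b.session_id:
        raise ValueError("channel frames come from different sessions")
    values = _imf_entropies(frame_ch_a.samples, config) + _imf_entropies(
        frame_ch_b.samples, config
    )
    return values, frame_ch_a.label


def extract_features(
    sessions: list[Session], config: PipelineConfig | None = None
) -> FeatureTable:
    """Full feature pipeline over a dataset.

    Per session: select the two most beta-active channels, beta-bandpass
    each whole channel, segment into frames, and compute the 8-vector
    per frame.  Row order is (session order, frame time order);
    extraction is deterministic — there is no randomness on this path.
    """
    config = config or PipelineConfig()
    if not sessions:
        raise ValueError("no sessions given")
    rows = []
    for session in sessions:
        ch_a, ch_b = select_channels(session, k=config.n_channels)[:2]
        filtered = session.signal.copy()
        for ch in (ch_a, ch_b):
            filtered[:, ch] = beta_bandpass(session.signal[:, ch], session.fs, config.bandpass)
        filt_session = Session(
            signal=filtered,
            fs=session.fs,
            valence=session.valence,
            arousal=session.arousal,
            session_id=session.session_id,
        )
        frames = segment_frames(filt_session, config.frame_seconds, channels=[ch_a, ch_b])
        for t, (fa, fb) in enumerate(zip(frames[0], frames[1])):
            values, label = frame_features(fa, fb, config)
            rows.append([f"{session.session_id}_f{t}", *values, label])

    cols = ["frame_id"] + [f"f{i + 1}" for i in range(N_FEATURES)] + ["label"]
    table = pd.DataFrame(rows, columns=cols)

    # Impute undefined entropies with the per-component maximum defined
    # value: zero matches = maximal irregularity.
    n_imputed = 0
    for i in range(N_FEATURES):
        col = f"f{i + 1}"
        nan_mask = table[col].isna()
        if nan_mask.any():
            defined = table.loc[~nan_mask, col]
            if defined.empty:
                raise ValueError(f"feature {col} undefined for every frame")
            table.loc[nan_mask, col] = defined.max()
            n_imputed += int(nan_mask.sum())
    if n_imputed:
        logger.info("imputed %d undefined SampEn values", n_imputed)
    return FeatureTable(frame=table, config=config, n_imputed=n_imputed)
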