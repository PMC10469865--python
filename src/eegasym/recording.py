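"""Core data carriers shared across pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

EMOTIONS: tuple[str, ...] = ("neutral", "sad", "fear", "happy")


@dataclass
class EEGRecording:
    """One trial: channels x samples signal in microvolts."""

    data: np.ndarray
    fs: float
    channels: tuple[str, ...]
    subject_id: str
    session_id: int
    trial_id: int
    emotion: str

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.channels = tuple(self.channels)
        self.validate()

    def validate(self) -> None:
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if self.data.shape[0] != len(self.channels):
            raise ValueError(
                f"data has {self.data.shape[0]} rows but {len(self.channels)} "
                "channel labels"
            )
        if not self.fs > 0:
            raise ValueError("fs must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data contains non-finite samples")
        if self.emotion not in EMOTIONS:
            raise ValueError(
                f"unknown emotion {self.emotion!r}; expected one of {EMOTIONS}"
            )

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs


@dataclass
class Segment:
    """One fixed-length analysis window cut from a recording."""

    data: np.ndarray
    channels: tuple[str, ...]
    subject_id: str
    session_id: int
    trial_id: int
    segment_index: int
    emotion: str
    fs: float = 200.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.channels = tuple(self.channels)
        if self.data.ndim != 2 or self.data.shape[0] != len(self.channels):
            raise ValueError("segment data must be channels x samples")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("segment contains non-finite samples")

    @property
    def ids(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "session_id": self.session_id,
            "trial_id": self.trial_id,
            "segment_index": self.segment_index,
            "emotion": self.emotion,
        }
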