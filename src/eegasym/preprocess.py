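"""Resampling, band-pass filtering, and fixed-window segmentation."""

from __future__ import annotations

from dataclasses import replace
from fractions import Fraction

import numpy as np
from scipy import signal as sps

from .recording import EEGRecording, Segment

TARGET_FS = 200.0
BAND_LOW = 0.5
BAND_HIGH = 50.0
WINDOW_SECONDS = 4.0
FILTER_ORDER = 4


def resample_recording(rec: EEGRecording, target_fs: float = TARGET_FS) -> EEGRecording:
    """Downsample to ``target_fs`` with polyphase anti-alias filtering.

    Upsampling is refused: the pipeline only ever reduces the rate.
    A recording already at the target rate is returned unchanged.
    """
    if rec.fs < target_fs:
        raise ValueError(
            f"cannot upsample from {rec.fs:g} Hz to {target_fs:g} Hz"
        )
    if rec.fs == target_fs:
        return rec
    ratio = Fraction(target_fs / rec.fs).limit_denominator(10000)
    data = sps.resample_poly(rec.data, ratio.numerator, ratio.denominator, axis=1)
    return replace(rec, data=data, fs=float(target_fs))


def bandpass_filter(
    rec: EEGRecording,
    low: float = BAND_LOW,
    high: float = BAND_HIGH,
    order: int = FILTER_ORDER,
) -> EEGRecording:
    """Zero-phase Butterworth band-pass, applied per channel."""
    nyq = rec.fs / 2.0
    if not 0 < low < high:
        raise ValueError(f"need 0 < low < high, got low={low}, high={high}")
    if high >= nyq:
        raise ValueError(f"high edge {high:g} Hz must be below Nyquist {nyq:g} Hz")
    sos = sps.butter(order, [low, high], btype="bandpass", fs=rec.fs, output="sos")
    data = sps.sosfiltfilt(sos, rec.data, axis=1)
    return replace(rec, data=data)


def bandpass_magnitude_response(
    freqs: np.ndarray,
    low: float = BAND_LOW,
    high: float = BAND_HIGH,
    fs: float = TARGET_FS,
    order: int = FILTER_ORDER,
) -> np.ndarray:
    """|H(f)|^2-of-the-applied-filter at ``freqs`` (forward-backward pass).

    Used by the synthetic generator to anticipate how much of each spectral
    component survives preprocessing.
    """
    sos = sps.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")
    _, h = sps.sosfreqz(sos, worN=np.asarray(freqs, dtype=float), fs=fs)
    # sosfiltfilt applies the filter twice -> squared magnitude
    return np.abs(h) ** 2


def segment_recording(
    rec: EEGRecording, window_seconds: float = WINDOW_SECONDS
) -> list[Segment]:
    """Cut a recording into non-overlapping windows starting at sample 0.

    The trailing remainder shorter than one window is discarded; a recording
    shorter than one window yields an empty list.
    """
    if rec.fs != TARGET_FS:
        raise ValueError(
            f"segmentation expects fs = {TARGET_FS:g} Hz, got {rec.fs:g}; "
            "resample first"
        )
    win = int(round(window_seconds * rec.fs))
    if win <= 0:
        raise ValueError("window must span at least one sample")
    n_windows = rec.n_samples // win
    segments = []
    for i in range(n_windows):
        segments.append(
            Segment(
                data=rec.data[:, i * win:(i + 1) * win],
                channels=rec.channels,
                subject_id=rec.subject_id,
                session_id=rec.session_id,
                trial_id=rec.trial_id,
                segment_index=i,
                emotion=rec.emotion,
                fs=rec.fs,
            )
        )
    return segments


def preprocess_recording(
    rec: EEGRecording,
    target_fs: float = TARGET_FS,
    low: float = BAND_LOW,
    high: float = BAND_HIGH,
    window_seconds: float = WINDOW_SECONDS,
) -> list[Segment]:
    """Resample -> band-pass -> segment (the canonical stage order)."""
    rec = resample_recording(rec, target_fs)
    rec = bandpass_filter(rec, low, high)
    return segment_recording(rec, window_seconds)
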