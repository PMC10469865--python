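"""Relative wavelet band energy and paired-channel asymmetry features.

A six-level db2 decomposition at 200 Hz splits the 0-100 Hz range
dyadically; detail levels d2..d6 are read as the gamma, beta, alpha,
theta and delta bands. Each band's energy is expressed as a fraction of
the total coefficient energy over all seven components (d1..d6 and a6).
The asymmetry feature for a (left, right) channel pair is the natural
log of the ratio of their relative band energies, which is identically
the difference of their log relative energies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import dwt
from .montage import ChannelPairMap, build_pair_map
from .recording import Segment

#: Canonical band order used everywhere (slow to fast).
BANDS: tuple[str, ...] = ("delta", "theta", "alpha", "beta", "gamma")

#: Detail level carrying each band (six-level decomposition at 200 Hz).
BAND_LEVELS: dict[str, int] = {"gamma": 2, "beta": 3, "alpha": 4, "theta": 5, "delta": 6}

#: Dyadic frequency intervals (Hz) of each band at fs = 200.
BAND_EDGES: dict[str, tuple[float, float]] = {
    "delta": (1.5625, 3.125),
    "theta": (3.125, 6.25),
    "alpha": (6.25, 12.5),
    "beta": (12.5, 25.0),
    "gamma": (25.0, 50.0),
}

REQUIRED_FS = 200.0
DWT_LEVELS = 6
#: Absolute floor applied to relative energies inside the log.
EPSILON = 1e-12

ID_COLUMNS: tuple[str, ...] = (
    "subject_id", "session_id", "trial_id", "segment_index", "emotion",
)


def feature_name(left: str, right: str, band: str) -> str:
    return f"{left}_{right}_{band}"


def feature_columns(pairs: ChannelPairMap | None = None) -> list[str]:
    """Canonical 135 feature names: pair-major, band-minor (delta..gamma)."""
    if pairs is None:
        pairs = ChannelPairMap()
    return [
        feature_name(left, right, band)
        for (left, right) in pairs
        for band in BANDS
    ]


def dwt_decompose(signal: np.ndarray, levels: int = DWT_LEVELS):
    """Six-level db2 decomposition of one or more channels (last axis = time)."""
    return dwt.wavedec(signal, levels=levels)


@dataclass
class BandEnergyTable:
    """Relative wavelet energy per channel per band for one segment."""

    channels: tuple[str, ...]
    relative: np.ndarray        # (n_channels, 5) fractions, BANDS order
    e_total: np.ndarray         # (n_channels,) total coefficient energy
    residual: np.ndarray        # (n_channels,) d1 + a6 relative energy

    def energy(self, channel: str, band: str) -> float:
        return float(self.relative[self.channels.index(channel), BANDS.index(band)])


def relative_band_energy(
    data: np.ndarray, channels, fs: float = REQUIRED_FS
) -> BandEnergyTable:
    """Compute per-channel relative band energies for one segment.

    The band-to-level map is only valid at 200 Hz; other sampling rates are
    rejected (resample first).
    """
    if float(fs) != REQUIRED_FS:
        raise ValueError(
            f"band/level map requires fs = {REQUIRED_FS:g} Hz, got {fs:g}; "
            "resample the recording first"
        )
    data = np.atleast_2d(np.asarray(data, dtype=float))
    approx, details = dwt_decompose(data)
    level_energy = np.stack(
        [np.sum(d * d, axis=-1) for d in details] + [np.sum(approx * approx, axis=-1)],
        axis=-1,
    )  # (..., 7): d1..d6, a6
    e_total = level_energy.sum(axis=-1)
    if np.any(e_total <= 0):
        bad = [channels[i] for i in np.nonzero(e_total <= 0)[0]]
        raise ValueError(f"degenerate all-zero segment for channel(s): {bad}")
    rel = np.stack(
        [level_energy[..., BAND_LEVELS[b] - 1] / e_total for b in BANDS], axis=-1
    )
    residual = (level_energy[..., 0] + level_energy[..., 6]) / e_total
    return BandEnergyTable(tuple(channels), rel, e_total, residual)


def band_energy_from_segment(segment: Segment) -> BandEnergyTable:
    return relative_band_energy(segment.data, segment.channels, segment.fs)


def asymmetry_ratio(e_left, e_right, eps: float = EPSILON):
    """ln(E_left / E_right) with an epsilon floor absorbing exact zeros.

    The log-ratio and the difference of logs are the same quantity; this is
    the single shared implementation for both forms.
    """
    e_left = np.asarray(e_left, dtype=float)
    e_right = np.asarray(e_right, dtype=float)
    if np.any(e_left < 0) or np.any(e_right < 0):
        raise ValueError("relative energies must be non-negative")
    out = np.log(np.maximum(e_left, eps)) - np.log(np.maximum(e_right, eps))
    if out.ndim == 0:
        return float(out)
    return out


@dataclass
class AsymmetryFeatureVector:
    """The 135 log-ratio features of one segment, in canonical order."""

    values: np.ndarray
    names: tuple[str, ...]
    ids: dict

    def __len__(self) -> int:
        return len(self.values)


def feature_vector(
    energies: BandEnergyTable,
    pairs: ChannelPairMap,
    ids: dict | None = None,
    eps: float = EPSILON,
) -> AsymmetryFeatureVector:
    """Pair-major, band-minor vector of log-ratio asymmetry features."""
    missing = [
        ch for pair in pairs for ch in pair if ch not in energies.channels
    ]
    if missing:
        raise ValueError(f"energy table lacks channels: {missing}")
    li = [energies.channels.index(l) for l in pairs.left_labels]
    ri = [energies.channels.index(r) for r in pairs.right_labels]
    left = energies.relative[li, :]    # (27, 5)
    right = energies.relative[ri, :]
    values = asymmetry_ratio(left, right, eps=eps).reshape(-1)
    names = tuple(feature_columns(pairs))
    return AsymmetryFeatureVector(values, names, dict(ids or {}))


def extract_features(
    segments, pairs: ChannelPairMap | None = None, chunk_size: int = 256
) -> pd.DataFrame:
    """Feature matrix for a batch of segments.

    Returns a DataFrame with the ID columns followed by the 135 canonical
    feature columns, one row per segment. Segments are processed in chunks
    with a vectorized decomposition.
    """
    segments = list(segments)
    if not segments:
        raise ValueError("no segments given")
    if pairs is None:
        pairs = build_pair_map(segments[0].channels)
    channels = segments[0].channels
    fs = segments[0].fs
    for seg in segments:
        if seg.channels != channels or seg.fs != fs:
            raise ValueError("segments must share channel layout and fs")
    if float(fs) != REQUIRED_FS:
        raise ValueError(
            f"band/level map requires fs = {REQUIRED_FS:g} Hz, got {fs:g}"
        )
    li = [channels.index(l) for l in pairs.left_labels]
    ri = [channels.index(r) for r in pairs.right_labels]
    blocks = []
    for start in range(0, len(segments), chunk_size):
        chunk = segments[start:start + chunk_size]
        stack = np.stack([s.data for s in chunk])  # (m, ch, n)
        approx, details = dwt_decompose(stack)
        level_energy = np.stack(
            [np.sum(d * d, axis=-1) for d in details]
            + [np.sum(approx * approx, axis=-1)],
            axis=-1,
        )
        e_total = level_energy.sum(axis=-1)
        if np.any(e_total <= 0):
            raise ValueError("degenerate all-zero segment in batch")
        rel = np.stack(
            [level_energy[..., BAND_LEVELS[b] - 1] / e_total for b in BANDS],
            axis=-1,
        )  # (m, ch, 5)
        blocks.append(asymmetry_ratio(rel[:, li, :], rel[:, ri, :]).reshape(len(chunk), -1))
    values = np.concatenate(blocks, axis=0)
    meta = pd.DataFrame([seg.ids for seg in segments])
    feats = pd.DataFrame(values, columns=feature_columns(pairs))
    return pd.concat([meta, feats], axis=1)
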