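"""From averaged coefficients to per-channel directional associations.

The 135 fold-averaged coefficients live on pairwise log-ratio features.
Because each feature is log E_left - log E_right, a coefficient w at
(pair, band) contributes +w to the left channel and -w to the right
channel of that pair, turning the model into a per-channel, per-band
signed association map whose linear predictor is identical to the
original one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .features import BANDS, feature_columns
from .models import FoldResult
from .montage import ChannelPairMap


@dataclass
class AveragedModel:
    emotion: str
    omega_bar: np.ndarray   # length 135, fold-mean including zeros
    n_folds: int

    def __post_init__(self) -> None:
        self.omega_bar = np.asarray(self.omega_bar, dtype=float)
        if self.omega_bar.shape != (len(feature_columns()),):
            raise ValueError("omega_bar must have the canonical feature length")


@dataclass
class ChannelAssociationMap:
    emotion: str
    channels: tuple[str, ...]      # the 54 lateral labels
    values: np.ndarray             # (54, 5) signed, BANDS order
    normalized: bool = False

    def value(self, channel: str, band: str) -> float:
        return float(self.values[self.channels.index(channel), BANDS.index(band)])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for bi, band in enumerate(BANDS):
            for ch in self.channels:
                rows.append(
                    {
                        "emotion": self.emotion,
                        "channel": ch,
                        "band": band,
                        "value": float(self.values[self.channels.index(ch), bi]),
                        "normalized": self.normalized,
                    }
                )
        return pd.DataFrame(rows)


def average_coefficients(folds: list[FoldResult]) -> AveragedModel:
    """Element-wise mean of the embedded per-fold coefficient vectors."""
    if not folds:
        raise ValueError("need at least one fold")
    emotions = {f.emotion for f in folds}
    if len(emotions) != 1:
        raise ValueError(f"folds mix emotions: {sorted(emotions)}")
    omega = np.mean([f.omega for f in folds], axis=0)
    return AveragedModel(folds[0].emotion, omega, n_folds=len(folds))


def expand_to_channels(
    model: AveragedModel, pairs: ChannelPairMap | None = None
) -> ChannelAssociationMap:
    """Expand pair-level coefficients into the per-channel signed map."""
    if pairs is None:
        pairs = ChannelPairMap()
    n_expected = len(pairs) * len(BANDS)
    if model.omega_bar.shape[0] != n_expected:
        raise ValueError(
            f"model has {model.omega_bar.shape[0]} coefficients, "
            f"expected {n_expected}"
        )
    channels = tuple(ch for pair in pairs for ch in pair)
    values = np.zeros((len(channels), len(BANDS)))
    omega = model.omega_bar.reshape(len(pairs), len(BANDS))
    for pi, (left, right) in enumerate(pairs):
        li = channels.index(left)
        ri = channels.index(right)
        values[li, :] += omega[pi]
        values[ri, :] -= omega[pi]
    return ChannelAssociationMap(model.emotion, channels, values)


def top_k_coefficients(model: AveragedModel, k: int = 5):
    """The k highest and k lowest averaged coefficients.

    Returns two lists of ``((pair_index, band), value)``; ties broken by
    pair index then band order.
    """
    n = len(model.omega_bar)
    if k > n:
        raise ValueError(f"k={k} exceeds coefficient count {n}")
    keys = [
        (pi + 1, band)
        for pi in range(n // len(BANDS))
        for band in BANDS
    ]
    order_high = sorted(
        range(n), key=lambda i: (-model.omega_bar[i], keys[i][0], BANDS.index(keys[i][1]))
    )
    order_low = sorted(
        range(n), key=lambda i: (model.omega_bar[i], keys[i][0], BANDS.index(keys[i][1]))
    )
    highest = [(keys[i], float(model.omega_bar[i])) for i in order_high[:k]]
    lowest = [(keys[i], float(model.omega_bar[i])) for i in order_low[:k]]
    return highest, lowest


def normalize_map(assoc: ChannelAssociationMap) -> ChannelAssociationMap:
    """Scale by the max absolute value so the range is [-1, 1]."""
    peak = float(np.max(np.abs(assoc.values)))
    if peak == 0:
        raise ValueError("cannot normalize an all-zero association map")
    return ChannelAssociationMap(
        assoc.emotion, assoc.channels, assoc.values / peak, normalized=True
    )


def export_topography(assoc: ChannelAssociationMap, path) -> pd.DataFrame:
    """Write the long-format per-channel table (sorted by band, channel)."""
    df = assoc.to_frame().sort_values(["band", "channel"], kind="stable")
    df = df.reset_index(drop=True)
    df.to_csv(path, index=False)
    return df
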