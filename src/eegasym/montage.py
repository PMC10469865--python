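"""62-channel 10-20-extended montage and the left/right channel pairing.

The asymmetry analysis keeps the 54 lateral channels, pairs them across the
midline, and discards the 8 midline electrodes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

#: Canonical ordering of the 62-channel montage (frontal to occipital rows).
DEFAULT_MONTAGE: tuple[str, ...] = (
    "FP1", "FPZ", "FP2",
    "AF3", "AF4",
    "F7", "F5", "F3", "F1", "FZ", "F2", "F4", "F6", "F8",
    "FT7", "FC5", "FC3", "FC1", "FCZ", "FC2", "FC4", "FC6", "FT8",
    "T7", "C5", "C3", "C1", "CZ", "C2", "C4", "C6", "T8",
    "TP7", "CP5", "CP3", "CP1", "CPZ", "CP2", "CP4", "CP6", "TP8",
    "P7", "P5", "P3", "P1", "PZ", "P2", "P4", "P6", "P8",
    "PO7", "PO5", "PO3", "POZ", "PO4", "PO6", "PO8",
    "CB1", "O1", "OZ", "O2", "CB2",
)

#: Midline electrodes, excluded from the pairing.
MIDLINE: tuple[str, ...] = ("FPZ", "FZ", "FCZ", "CZ", "CPZ", "PZ", "POZ", "OZ")

#: The 27 (left, right) lateral pairs, in canonical pair order 1..27.
PAIRED_CHANNELS: tuple[tuple[str, str], ...] = (
    ("FP1", "FP2"), ("AF3", "AF4"), ("F1", "F2"), ("F3", "F4"),
    ("F5", "F6"), ("F7", "F8"), ("FT7", "FT8"), ("T7", "T8"),
    ("TP7", "TP8"), ("FC1", "FC2"), ("FC3", "FC4"), ("FC5", "FC6"),
    ("C1", "C2"), ("C3", "C4"), ("C5", "C6"), ("CP1", "CP2"),
    ("CP3", "CP4"), ("CP5", "CP6"), ("P1", "P2"), ("P3", "P4"),
    ("P5", "P6"), ("P7", "P8"), ("PO3", "PO4"), ("PO5", "PO6"),
    ("PO7", "PO8"), ("O1", "O2"), ("CB1", "CB2"),
)

#: All 54 lateral labels, left column first within each pair.
LATERAL_CHANNELS: tuple[str, ...] = tuple(
    ch for pair in PAIRED_CHANNELS for ch in pair
)


@dataclass(frozen=True)
class ChannelPairMap:
    """Ordered left/right channel pairing (pair indices are 1-based)."""

    pairs: tuple[tuple[str, str], ...] = field(default=PAIRED_CHANNELS)

    def __post_init__(self) -> None:
        left = [p[0] for p in self.pairs]
        right = [p[1] for p in self.pairs]
        if len(set(left)) != len(left) or len(set(right)) != len(right):
            raise ValueError("duplicate labels in pair map")
        if set(left) & set(right):
            raise ValueError("left and right label sets must be disjoint")

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self):
        return iter(self.pairs)

    @property
    def left_labels(self) -> tuple[str, ...]:
        return tuple(p[0] for p in self.pairs)

    @property
    def right_labels(self) -> tuple[str, ...]:
        return tuple(p[1] for p in self.pairs)

    def pair(self, index: int) -> tuple[str, str]:
        """Return the (left, right) labels of 1-based pair ``index``."""
        if not 1 <= index <= len(self.pairs):
            raise IndexError(f"pair index {index} out of range 1..{len(self.pairs)}")
        return self.pairs[index - 1]


def build_pair_map(channel_labels) -> ChannelPairMap:
    """Build the 27-pair left/right map from an ordered montage.

    Parameters
    ----------
    channel_labels : sequence of str
        Montage labels; must contain every lateral channel. Midline labels
        and any extras are ignored.

    Raises
    ------
    ValueError
        If any of the 54 lateral labels is missing (all missing labels are
        named in the message).
    """
    have = {str(lbl).upper() for lbl in channel_labels}
    missing = [ch for ch in LATERAL_CHANNELS if ch not in have]
    if missing:
        raise ValueError(
            "montage is missing required lateral channels: " + ", ".join(missing)
        )
    return ChannelPairMap(PAIRED_CHANNELS)
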