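"""Paired-channel asymmetry screening (Experiment 1).

For every (pair, band, emotion) cell, segments of the given emotion are
pooled across subjects, sessions and trials; the cell's statistic is the
median log energy difference between the left and right channel, tested
for symmetry about zero with a two-sided Wilcoxon signed-rank test and
Bonferroni-corrected over the full family of cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sst

from .features import BANDS, feature_name
from .montage import ChannelPairMap
from .recording import EMOTIONS

MIN_SAMPLES = 5
EXACT_MAX_N = 25


def collect_deltas(
    features: pd.DataFrame, pair: tuple[str, str], band: str, emotion: str
) -> np.ndarray:
    """All segment-level log differences for one (pair, band, emotion) cell."""
    col = feature_name(pair[0], pair[1], band)
    if col not in features.columns:
        raise KeyError(f"feature column {col!r} not present")
    mask = features["emotion"] == emotion
    if not mask.any():
        raise ValueError(
            f"no segments with emotion {emotion!r} for cell ({col})"
        )
    return features.loc[mask, col].to_numpy(dtype=float)


def wilcoxon_signed_rank(sample: np.ndarray) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test of symmetry about zero.

    Zeros are discarded before ranking. The exact null distribution is used
    for n <= 25; above that, the normal approximation with continuity
    correction. Returns ``(W, p)`` where W is the smaller of the positive-
    and negative-rank sums.

    Raises for n < 5 after zero-removal (test too coarse to be useful) and
    when all differences are zero (test undefined).
    """
    x = np.asarray(sample, dtype=float)
    x = x[x != 0.0]
    n = len(x)
    if np.asarray(sample).size > 0 and n == 0:
        raise ValueError("all differences are zero; test undefined")
    if n < MIN_SAMPLES:
        raise ValueError(f"need at least {MIN_SAMPLES} nonzero differences, got {n}")
    ranks = sst.rankdata(np.abs(x))
    w_pos = float(ranks[x > 0].sum())
    w_neg = float(ranks[x < 0].sum())
    if n <= EXACT_MAX_N:
        res = sst.wilcoxon(x, zero_method="wilcox", alternative="two-sided",
                           method="exact")
    else:
        res = sst.wilcoxon(x, zero_method="wilcox", alternative="two-sided",
                           method="approx", correction=True)
    return min(w_pos, w_neg), float(res.pvalue)


def wilcoxon_signed_rank_batch(samples: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized normal-approximation Wilcoxon over rows of ``samples``.

    Intended for large Monte-Carlo families (rows must be zero- and tie-free
    with n > 25, the approximation regime of the scalar function); agrees
    with :func:`wilcoxon_signed_rank` on such inputs.
    """
    X = np.asarray(samples, dtype=float)
    if X.ndim != 2:
        raise ValueError("expected a 2-D (families x n) array")
    m, n = X.shape
    if n <= EXACT_MAX_N:
        raise ValueError(f"batch path requires n > {EXACT_MAX_N}")
    if np.any(X == 0.0):
        raise ValueError("batch path does not handle zero differences")
    ranks = sst.rankdata(np.abs(X), axis=1)
    w_pos = np.where(X > 0, ranks, 0.0).sum(axis=1)
    w_neg = n * (n + 1) / 2.0 - w_pos
    mean = n * (n + 1) / 4.0
    se = np.sqrt(n * (n + 1) * (2 * n + 1) / 24.0)
    d = 0.5 * np.sign(w_pos - mean)  # continuity correction
    z = (w_pos - mean - d) / se
    p = np.clip(2.0 * sst.norm.sf(np.abs(z)), 0.0, 1.0)
    return np.minimum(w_pos, w_neg), p


def bonferroni(p_values, alpha_family: float = 0.05) -> tuple[np.ndarray, float]:
    """Family-wise correction: flag p < alpha / m; returns (flags, threshold)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value family")
    threshold = alpha_family / p.size
    return p < threshold, threshold


@dataclass
class PairTestResult:
    pair_index: int
    pair: tuple[str, str]
    band: str
    emotion: str
    n: int
    eta: float
    W: float
    p_value: float
    significant: bool = False


@dataclass
class AsymmetryMatrix:
    """All per-cell results with the family-wise correction applied."""

    results: list[PairTestResult]
    n_tests: int
    alpha_family: float
    corrected_alpha: float

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "pair_index": r.pair_index,
                "pair_left": r.pair[0],
                "pair_right": r.pair[1],
                "band": r.band,
                "emotion": r.emotion,
                "n": r.n,
                "eta": r.eta,
                "W": r.W,
                "p_value": r.p_value,
                "significant": r.significant,
                "corrected_alpha": self.corrected_alpha,
            }
            for r in self.results
        ]
        return pd.DataFrame(rows)

    def cell(self, pair_index: int, band: str, emotion: str) -> PairTestResult:
        for r in self.results:
            if (r.pair_index, r.band, r.emotion) == (pair_index, band, emotion):
                return r
        raise KeyError((pair_index, band, emotion))


def build_asymmetry_matrix(
    features: pd.DataFrame,
    pairs: ChannelPairMap | None = None,
    alpha_family: float = 0.05,
    emotions=EMOTIONS,
) -> AsymmetryMatrix:
    """Run the full pair x band x emotion screen with Bonferroni correction."""
    if pairs is None:
        pairs = ChannelPairMap()
    present = set(features["emotion"].unique())
    missing = [e for e in emotions if e not in present]
    if missing:
        raise ValueError(f"emotions absent from the feature table: {missing}")
    results: list[PairTestResult] = []
    for pi, pair in enumerate(pairs, start=1):
        for band in BANDS:
            for emotion in emotions:
                deltas = collect_deltas(features, pair, band, emotion)
                w, p = wilcoxon_signed_rank(deltas)
                results.append(
                    PairTestResult(
                        pair_index=pi,
                        pair=pair,
                        band=band,
                        emotion=emotion,
                        n=len(deltas),
                        eta=float(np.median(deltas)),
                        W=w,
                        p_value=p,
                    )
                )
    flags, corrected = bonferroni([r.p_value for r in results], alpha_family)
    for r, f in zip(results, flags):
        r.significant = bool(f)
    return AsymmetryMatrix(
        results=results,
        n_tests=len(results),
        alpha_family=alpha_family,
        corrected_alpha=corrected,
    )
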