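"""Orthonormal periodized Daubechies-2 discrete wavelet transform.

The analysis needs an exactly energy-conserving decomposition (relative
band energies are ratios of coefficient energies to total signal energy),
so the transform uses circular (periodized) convolution with the
orthonormal db2 filter bank. When an intermediate approximation has odd
length, its final coefficient is carried unchanged into the next
approximation; the map stays orthogonal, so Parseval holds to machine
precision for any input length and depth.

Coefficient counts for an 800-sample input at 6 levels:
d1..d6 = 400, 200, 100, 50, 25, 12 and a6 = 13 (12 + 1 carried).
"""

from __future__ import annotations

import numpy as np

_SQRT3 = np.sqrt(3.0)
#: db2 orthonormal low-pass decomposition filter.
DB2_LOW = np.array(
    [1.0 + _SQRT3, 3.0 + _SQRT3, 3.0 - _SQRT3, 1.0 - _SQRT3]
) / (4.0 * np.sqrt(2.0))
#: Quadrature-mirror high-pass filter.
DB2_HIGH = np.array([DB2_LOW[3], -DB2_LOW[2], DB2_LOW[1], -DB2_LOW[0]])

_FILTER_LEN = 4


def _dwt_step(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    n = x.shape[-1]
    carry = None
    if n % 2 == 1:
        carry = x[..., -1:]
        x = x[..., :-1]
        n -= 1
    idx = (2 * np.arange(n // 2)[:, None] + np.arange(_FILTER_LEN)[None, :]) % n
    windows = x[..., idx]
    approx = windows @ DB2_LOW
    detail = windows @ DB2_HIGH
    if carry is not None:
        approx = np.concatenate([approx, carry], axis=-1)
    return approx, detail


def _idwt_step(approx: np.ndarray, detail: np.ndarray) -> np.ndarray:
    n_half = detail.shape[-1]
    carry = None
    if approx.shape[-1] == n_half + 1:
        carry = approx[..., -1:]
        approx = approx[..., :-1]
    elif approx.shape[-1] != n_half:
        raise ValueError("approximation/detail length mismatch")
    n = 2 * n_half
    x = np.zeros(approx.shape[:-1] + (n,), dtype=float)
    for k in range(_FILTER_LEN):
        pos = (2 * np.arange(n_half) + k) % n
        np.add.at(x, (..., pos), approx * DB2_LOW[k] + detail * DB2_HIGH[k])
    if carry is not None:
        x = np.concatenate([x, carry], axis=-1)
    return x


def min_input_length(levels: int) -> int:
    return 2 ** levels


def wavedec(x: np.ndarray, levels: int = 6) -> tuple[np.ndarray, list[np.ndarray]]:
    """Decompose ``x`` along its last axis.

    Returns
    -------
    approx : ndarray
        Final approximation coefficients (a_levels).
    details : list of ndarray
        Detail coefficients ``[d1, d2, ..., d_levels]``, finest first.
    """
    x = np.asarray(x, dtype=float)
    n = x.shape[-1]
    if n < min_input_length(levels):
        raise ValueError(
            f"input length {n} too short for {levels}-level decomposition; "
            f"need at least {min_input_length(levels)} samples"
        )
    details: list[np.ndarray] = []
    approx = x
    for _ in range(levels):
        approx, detail = _dwt_step(approx)
        details.append(detail)
    return approx, details


def waverec(approx: np.ndarray, details: list[np.ndarray]) -> np.ndarray:
    """Invert :func:`wavedec` exactly (orthogonal transform)."""
    x = np.asarray(approx, dtype=float)
    for detail in reversed(details):
        x = _idwt_step(x, np.asarray(detail, dtype=float))
    return x
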