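"""Empirical mode decomposition by standard sifting.

Cubic-spline upper/lower envelopes through local extrema, with mirrored
boundary extrema so the splines do not diverge at the edges.  A sift
stops on the Cauchy criterion SD < 0.2 or after 200 iterations; the
decomposition stops when the residual has too few extrema to envelope or
when the requested number of modes is reached.  By construction the sum
of the IMFs plus the final residual reproduces the input exactly (up to
floating-point accumulation).
"""

from __future__ import annotations

import numpy as np
from scipy.interpolate import CubicSpline

MAX_SIFTS = 200
CAUCHY_SD = 0.2
_N_MIRROR = 2  # extrema reflected at each boundary


def _local_extrema(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indices of strict local maxima and minima (plateaus take the midpoint)."""
    d = np.diff(x)
    # collapse zero slopes onto the preceding nonzero slope
    s = np.sign(d)
    for i in range(1, len(s)):
        if s[i] == 0:
            s[i] = s[i - 1]
    change = np.diff(s)
    maxima = np.nonzero(change < 0)[0] + 1
    minima = np.nonzero(change > 0)[0] + 1
    return maxima, minima


def _envelope(x: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Cubic-spline envelope through extrema at ``idx``, mirror-extended."""
    n = len(x)
    k = min(_N_MIRROR, len(idx) - 1)
    left_i = -idx[1:k + 1][::-1]
    right_i = 2 * (n - 1) - idx[-k - 1:-1][::-1]
    xi = np.concatenate([left_i, idx, right_i])
    yi = np.concatenate([x[idx[1:k + 1]][::-1], x[idx], x[idx[-k - 1:-1]][::-1]])
    return CubicSpline(xi, yi)(np.arange(n))


def emd(x, max_imfs: int = 12) -> list[np.ndarray]:
    """Decompose ``x`` into up to ``max_imfs`` intrinsic mode functions.

    Returns the list of IMFs; the residual is ``x - sum(imfs)``.
    """
    x = np.asarray(x, dtype=float)
    residual = x.copy()
    imfs: list[np.ndarray] = []
    for _ in range(max_imfs):
        maxima, minima = _local_extrema(residual)
        if len(maxima) < 2 or len(minima) < 2:
            break
        h = residual
        for _ in range(MAX_SIFTS):
            maxima, minima = _local_extrema(h)
            if len(maxima) < 2 or len(minima) < 2:
                break
            mean_env = 0.5 * (_envelope(h, maxima) + _envelope(h, minima))
            h_new = h - mean_env
            denom = np.sum(h ** 2)
            sd = np.sum((h - h_new) ** 2) / denom if denom > 0 else 0.0
            h = h_new
            if sd < CAUCHY_SD:
                break
        imfs.append(h)
        residual = residual - h
    return imfs
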