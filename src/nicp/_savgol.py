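"""Savitzky-Golay filtering with cached edge-fit matrices.

Equivalent to ``scipy.signal.savgol_filter(..., mode="interp")`` — interior
by convolution, edges by evaluating a least-squares polynomial fit over the
first/last window — but the edge projection matrices depend only on
(window, order, deriv, delta) and are cached, which matters when the filter
runs once per cardiac pulse over hours of signal.
"""

from __future__ import annotations

from functools import lru_cache
from math import factorial

import numpy as np
from scipy.signal import savgol_filter


@lru_cache(maxsize=64)
def _edge_matrix(window: int, order: int, deriv: int, delta: float) -> np.ndarray:
    """Matrix mapping the first ``window`` samples to the ``window//2``
    edge outputs of the deriv-th derivative of the LSQ polynomial fit."""
    i = np.arange(window, dtype=np.float64)
    vand = np.vander(i, order + 1, increasing=True)
    proj = np.linalg.pinv(vand)  # samples -> poly coefficients a_k
    half = window // 2
    pos = np.arange(half, dtype=np.float64)
    dmat = np.zeros((half, order + 1))
    for k in range(deriv, order + 1):
        coef = factorial(k) / factorial(k - deriv)
        dmat[:, k] = coef * pos ** (k - deriv)
    return (dmat @ proj) / delta**deriv


def savgol(x: np.ndarray, window: int, order: int, deriv: int = 0, delta: float = 1.0) -> np.ndarray:
    """Savitzky-Golay smoothing-differentiation, polynomial-fit edges."""
    if window > x.size:
        raise ValueError("window longer than the signal")
    y = savgol_filter(x, window, order, deriv=deriv, delta=delta, mode="constant")
    half = window // 2
    if half == 0:
        return y
    edge = _edge_matrix(window, order, deriv, float(delta))
    y[:half] = edge @ x[:window]
    # tail: fit on the reversed last window; odd derivatives flip sign
    sign = -1.0 if deriv % 2 else 1.0
    y[-half:] = sign * (edge @ x[-window:][::-1])[::-1]
    return y
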