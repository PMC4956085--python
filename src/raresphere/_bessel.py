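"""Log-space modified Bessel function of the second kind on an order ladder.

The Sichel pmf needs ``log K_{gamma+k}(beta)`` for every integer
``k = 0..k_max`` with ``k_max`` up to ~1e5.  ``scipy.special.kve``
overflows for large orders (K_v grows like Gamma(v)), so orders near zero
are seeded with ``kve`` and the remainder filled from the three-term
recurrence ``K_{v+1} = K_{v-1} + (2v/beta) K_v``.  Rather than running it
directly (which overflows) or via logaddexp (slow), the ladder tracks the
ratio ``r_v = K_{v+1}(beta) / K_v(beta)``, which obeys

    r_v = 2 v / beta + 1 / r_{v-1},

a positive, stable recursion once v >= 0.5; the log values are then a
cumulative sum of log-ratios.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit
from scipy.special import kve


@njit(cache=True)
def _fill_ratios(r: np.ndarray, v_first: float, beta: float, r_prev: float) -> None:
    for i in range(r.shape[0]):
        r_prev = 2.0 * (v_first + i) / beta + 1.0 / r_prev
        r[i] = r_prev


def log_kv_ladder(v0: float, beta: float, jmax: int) -> np.ndarray:
    """``log K_{v0+j}(beta)`` for j = 0..jmax (inclusive).

    ``beta > 0``; ``v0`` may be negative (K is symmetric in its order).
    """
    if not beta > 0:
        raise ValueError("beta must be positive")
    n = jmax + 1
    # seed directly while the recursion coefficient 2(v0+j-1)/beta could be
    # small or negative; K_{-v} = K_v handles negative orders
    jstart = max(2, math.ceil(1.5 - v0))
    jstart = min(jstart, n)
    orders = np.abs(v0 + np.arange(jstart))
    seed = np.log(kve(orders, beta)) - beta
    if jstart >= n:
        return seed[:n]
    r = np.empty(n - jstart)
    r_prev = math.exp(seed[jstart - 1] - seed[jstart - 2])
    _fill_ratios(r, v0 + jstart - 1.0, beta, r_prev)
    out = np.empty(n)
    out[:jstart] = seed
    out[jstart:] = seed[jstart - 1] + np.cumsum(np.log(r))
    return out


def log_kv(v: float, x: float) -> float:
    """``log K_v(x)`` for a single (small) order."""
    return float(np.log(kve(abs(v), x)) - x)
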