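"""Storey q-values for positive false discovery rate control.

The null proportion pi0 is estimated with the smoother method: pi0(lambda)
= #{p > lambda} / (m (1 - lambda)) over lambda in {0, 0.05, ..., 0.90}, a
cubic smoothing spline is fitted through the points and evaluated at the
largest lambda, and the result is clipped to (0, 1]. q-values are then
pi0 times the Benjamini-Hochberg step-up quantity; with pi0 pinned to 1
they coincide exactly with BH adjusted p-values.
"""

from __future__ import annotations

import numpy as np
from scipy.interpolate import UnivariateSpline

_LAMBDAS = np.arange(0.0, 0.95, 0.05)  # 0, 0.05, ..., 0.90


def estimate_pi0(p: np.ndarray, lambdas: np.ndarray = _LAMBDAS) -> float:
    """Smoother estimate of the proportion of true nulls."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    if m == 0:
        raise ValueError("empty p-value collection")
    pi0_lam = np.array([(p > lam).sum() / (m * (1.0 - lam)) for lam in lambdas])
    if np.allclose(pi0_lam, pi0_lam[0]):
        pi0 = pi0_lam[0]
    else:
        spline = UnivariateSpline(lambdas, pi0_lam, k=3)
        pi0 = float(spline(lambdas[-1]))
    return float(min(max(pi0, 1.0 / m), 1.0))


def storey_q(p, pi0: float | None = None) -> np.ndarray:
    """q-values in the input order.

    Parameters
    ----------
    p : array-like of p-values in [0, 1].
    pi0 : optional pin of the null proportion (pi0=1 gives BH exactly);
        estimated by :func:`estimate_pi0` when None.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    if pi0 is None:
        pi0 = estimate_pi0(p)
    if not (0 < pi0 <= 1):
        raise ValueError("pi0 must lie in (0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    # step-up: running minimum from the largest p downwards (max-rank ties)
    qs = np.minimum.accumulate(ranked[::-1])[::-1]
    qs = np.minimum(pi0 * qs, 1.0)
    out = np.empty(m)
    out[order] = qs
    return out
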