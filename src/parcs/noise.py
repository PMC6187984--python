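"""Null-conform residual series and MA noise-order estimation.

The block size of the permutation bootstrap must exceed the range of temporal
dependence in the noise.  For a finite MA(q) process the autocorrelation
function cuts off after lag q, so the order is read off the residual series
by testing successive lags against the asymptotic null
``acorr ~ N(-1/(T-tau), 1/(T-tau))`` and the block size is set to ``q + 1``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .cusum import CusumCurve

__all__ = ["H0Series", "h0_residual_series", "autocorr", "estimate_ma_order"]


@dataclass(frozen=True)
class H0Series:
    """Series with the fitted step structure removed (the no-change null).

    ``x0`` is obtained by subtracting the fitted PARCS curve from the CUSUM
    curve and inverting the CUSUM transform by first differences (with
    ``y_0 = 0``), adding the original series mean back.
    """

    x0: np.ndarray  # (T, N)
    source_model: object = None

    @property
    def T(self) -> int:
        return self.x0.shape[0]

    @property
    def N(self) -> int:
        return self.x0.shape[1]


def h0_residual_series(curve: CusumCurve, results) -> H0Series:
    """Regress the fitted model out of the CUSUM curve and invert the transform.

    ``y0 = y - yhat``; ``x0_t = y0_t - y0_{t-1} + <x>`` with ``y0_0 = 0``.
    """
    yhat = results.fittedvalues
    if yhat.shape != curve.y.shape:
        raise ValueError("model and curve shapes do not match")
    y0 = curve.y - yhat
    x0 = np.diff(y0, axis=0, prepend=0.0) + curve.x_mean
    return H0Series(x0=x0, source_model=results)


def autocorr(x, tau: int) -> float:
    """Sample autocorrelation at lag ``tau`` (biased normalisation).

    Numerator sums ``T - tau`` products of deviations from the overall mean;
    the denominator is the lag-0 sum over all ``T`` terms.  This is the
    estimator whose null distribution the order test assumes.
    """
    x = np.asarray(x, dtype=float).ravel()
    T = x.size
    if not 0 <= tau < T:
        raise ValueError("lag must satisfy 0 <= tau < T")
    d = x - x.mean()
    denom = float(d @ d)
    if denom == 0.0:
        raise ValueError("zero-variance series: autocorrelation undefined")
    if tau == 0:
        return 1.0
    return float(d[: T - tau] @ d[tau:]) / denom


def estimate_ma_order(x0, Q: int = 9, alpha: float = 0.05) -> int:
    """Estimate the MA order q of a (residual) series.

    Scans lags ``tau = 1..Q`` and returns ``tau - 1`` for the first lag whose
    autocorrelation falls inside the two-sided ``1 - alpha`` interval of
    ``N(-1/(T-tau), 1/(T-tau))``; returns ``Q`` if every lag rejects.  For a
    multivariate series the order is estimated per column and the maximum is
    returned (conservative: dependence is preserved in all columns).
    """
    if Q < 1:
        raise ValueError("upper bound Q must be >= 1")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    x0 = np.asarray(x0, dtype=float)
    if x0.ndim == 2 and x0.shape[1] > 1:
        return max(estimate_ma_order(x0[:, n], Q, alpha) for n in range(x0.shape[1]))
    x0 = x0.ravel()
    T = x0.size
    if Q >= T:
        raise ValueError("upper bound Q must be smaller than the series length")
    for tau in range(1, Q + 1):
        scale = 1.0 / (T - tau)
        lo, hi = stats.norm.ppf(
            [alpha / 2.0, 1.0 - alpha / 2.0], loc=-scale, scale=np.sqrt(scale)
        )
        if lo <= autocorr(x0, tau) <= hi:
            return tau - 1
    return Q
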