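"""CUSUM transformation and the classical at-most-one-change (AMOC) locator.

The CUSUM curve ``y_t = sum_{tau<=t} (x_tau - <x>)`` turns a step change in
the mean of ``x`` into a bend (slope change) in ``y``; its weighted absolute
maximum locates a single candidate CP, and the unweighted maximum is the
classical test statistic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["CusumCurve", "cusum_transform", "amoc_locator", "cusum_statistic"]


@dataclass(frozen=True)
class CusumCurve:
    """CUSUM-transformed series: ``y`` (T x N) and the per-column mean of the
    source series.  ``y[T-1]`` is identically zero (sums of deviations)."""

    y: np.ndarray
    x_mean: np.ndarray

    @property
    def T(self) -> int:
        return self.y.shape[0]

    @property
    def N(self) -> int:
        return self.y.shape[1]


def _as_matrix(x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    if x.ndim != 2 or x.shape[0] < 3:
        raise ValueError("input must be a T x N matrix with T >= 3")
    if not np.isfinite(x).all():
        raise ValueError("input contains non-finite values")
    return x


def cusum_transform(x) -> CusumCurve:
    """Column-wise cumulative sum of deviations from the column mean."""
    x = _as_matrix(x)
    mean = x.mean(axis=0)
    y = np.cumsum(x - mean, axis=0)
    return CusumCurve(y=y, x_mean=mean)


def _weights(T: int, gamma: float) -> np.ndarray:
    """Center-bias correction ``(T / (t (T - t)))**gamma`` on t = 1..T-1."""
    t = np.arange(1, T, dtype=float)
    return (T / (t * (T - t))) ** gamma


def amoc_locator(x, gamma: float = 0.0) -> int:
    """Single-CP locator: argmax over ``t in {1..T-1}`` of the weighted
    absolute CUSUM curve.

    ``gamma = 0`` is the generic CUSUM locator; ``gamma = 0.5`` is the
    maximum-likelihood variant for i.i.d. Gaussian noise.  Ties break to the
    smallest time index.  Raises on a constant series (statistic identically
    zero, location undefined).
    """
    if not 0.0 <= gamma <= 0.5:
        raise ValueError("gamma must lie in [0, 0.5]")
    curve = cusum_transform(x)
    if curve.N != 1:
        raise ValueError("amoc_locator expects a univariate series")
    stat = np.abs(curve.y[:-1, 0]) * _weights(curve.T, gamma)
    if np.max(stat) == 0.0:
        raise ValueError("constant series: CP location undefined")
    return int(np.argmax(stat)) + 1  # 1-based time index


def cusum_statistic(x) -> float:
    """Maximum absolute CUSUM deviation, ``S = max_{0<t<T} |y_t|``."""
    curve = cusum_transform(x)
    if curve.N != 1:
        raise ValueError("cusum_statistic expects a univariate series")
    return float(np.abs(curve.y[:-1, 0]).max())
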