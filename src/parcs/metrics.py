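"""Evaluation metrics for change-point detectors.

All metrics use the 1-based time convention of the step model (a CP at ``c``
means the mean shifts between ``t <= c`` and ``t > c``) and the discrete
Heaviside ``1_i = 1 iff i > 0``.
"""

from __future__ import annotations

from collections.abc import Iterable, Sequence

import numpy as np

__all__ = ["center_bias", "accuracy_score", "detection_hits", "error_rates"]


def center_bias(c: int, c_hat: int, T: int) -> float:
    """Signed displacement of an estimate toward the series center.

    ``cb = (2 * 1_{c - T/2} - 1) * (c - c_hat)``: positive when ``c_hat``
    falls on the side of ``c`` that faces the middle of the series, negative
    when it falls toward the nearer edge.
    """
    if not (1 <= c <= T and 1 <= c_hat <= T):
        raise ValueError("c and c_hat must lie in [1, T]")
    sign = 1.0 if (c - T / 2) > 0 else -1.0
    return sign * (c - c_hat)


def detection_hits(
    detections: Iterable[Sequence[int]], c: int, T: int, window_frac: float = 0.05
) -> np.ndarray:
    """Boolean per-realization indicator of a detection within ``±window_frac*T``
    of the true CP ``c`` (inclusive window)."""
    win = window_frac * T
    return np.array(
        [any(abs(d - c) <= win for d in det) for det in detections], dtype=bool
    )


def accuracy_score(
    detections: Iterable[Sequence[int]],
    c: int,
    T: int,
    M: int,
    alpha_hat: float,
    window_frac: float = 0.05,
) -> float:
    """Correct-detection rate around a true CP, penalised for false discoveries.

    Percentage of realizations with at least one significant detection within
    ``±window_frac*T`` of ``c``, minus ``alpha_hat / M`` where ``alpha_hat``
    is the empirical type-I error rate (in percent) measured in the same
    experiment and ``M`` the model order.
    """
    if M <= 0:
        raise ValueError("model order M must be positive")
    hits = detection_hits(detections, c, T, window_frac)
    return 100.0 * hits.mean() - alpha_hat / M


def error_rates(
    detections: Iterable[Sequence[int]],
    true_cps: Sequence[int],
    T: int,
    window_frac: float = 0.05,
) -> tuple[float, float]:
    """Empirical type-I and type-II error rates, in percent.

    A realization commits a type-I error when at least one significant
    detection lies farther than ``window_frac*T`` from *every* true CP, and a
    type-II error when at least one true CP has no significant detection
    within that window.
    """
    win = window_frac * T
    t1 = t2 = 0
    n = 0
    for det in detections:
        n += 1
        if any(all(abs(d - c) > win for c in true_cps) for d in det):
            t1 += 1
        if any(all(abs(d - c) > win for d in det) for c in true_cps):
            t2 += 1
    if n == 0:
        raise ValueError("no realizations supplied")
    return 100.0 * t1 / n, 100.0 * t2 / n
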