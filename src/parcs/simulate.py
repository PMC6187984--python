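"""Synthetic piecewise-stationary time series.

The generative model is a step change in the mean: each of ``N`` covariates
holds a constant level within segments delimited by a common, ordered set of
change points (CPs), and a jump of size ``w_mn`` occurs *after* time step
``c_m`` (the new level is effective from ``t = c_m + 1``).  Noise is either a
stationary Gaussian moving-average (MA) process of finite order ``q`` shared
in structure across covariates (but drawn independently per covariate), or
independent Poisson counts whose rate follows the piecewise-constant profile.

Time is 1-based in every user-facing contract: a change point ``c`` means the
mean differs between ``t <= c`` and ``t > c``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "StepModelSpec",
    "mean_profile",
    "simulate_step_series",
    "simulate_poisson_counts",
    "simulate",
    "sqrt_transform",
]


@dataclass(frozen=True)
class StepModelSpec:
    """Generative parameters of a piecewise-stationary step-mean process.

    Parameters
    ----------
    T : int
        Series length (number of time steps).
    baseline : array_like
        Per-covariate baseline level ``b_n``; a scalar is broadcast to all
        covariates.  Length defines ``N`` together with ``weights``.
    cps : tuple of int
        Ordered change points ``c_1 < ... < c_M``, each in ``{2, ..., T-1}``
        on the 1-based time axis.  The new mean starts at ``t = c_m + 1``.
    weights : array_like
        ``M x N`` step sizes ``w_mn`` (rows follow ``cps``).  A 1-D array is
        interpreted as one column per entry for M=1, or one row (univariate
        multi-CP) when its length matches ``len(cps)``.
    noise_kind : {"gaussian_ma", "poisson"}
    sigma : float
        Innovation standard deviation of the MA noise (ignored for Poisson).
    kappas : tuple of float
        MA coefficients ``kappa_1 .. kappa_q``; ``kappa_0 = 1`` is implicit
        and must not be supplied.  Empty tuple means white noise (q = 0).
    seed : int or None
        Seed for the default RNG when none is passed to the simulator.
    """

    T: int
    baseline: tuple = (0.0,)
    cps: tuple = ()
    weights: tuple = ()
    noise_kind: str = "gaussian_ma"
    sigma: float = 1.0
    kappas: tuple = ()
    seed: int | None = None

    # normalized arrays, computed once
    _b: np.ndarray = field(init=False, repr=False, compare=False, default=None)
    _w: np.ndarray = field(init=False, repr=False, compare=False, default=None)

    def __post_init__(self):
        if self.T < 3:
            raise ValueError("series length T must be at least 3")
        b = np.atleast_1d(np.asarray(self.baseline, dtype=float))
        cps = tuple(int(c) for c in self.cps)
        M = len(cps)
        w = np.asarray(self.weights, dtype=float)
        if w.size == 0:
            w = np.zeros((0, b.size))
        elif w.ndim == 1:
            if M == 1:
                w = w.reshape(1, -1)
            elif w.size == M:
                w = w.reshape(M, 1)
            else:
                raise ValueError("1-D weights must have one entry per change point")
        if b.size == 1 and w.shape[1] > 1:
            b = np.repeat(b, w.shape[1])
        if w.shape != (M, b.size):
            raise ValueError(f"weights must be {M}x{b.size}, got {w.shape}")
        if any(c2 <= c1 for c1, c2 in zip(cps, cps[1:])):
            raise ValueError("change points must be strictly increasing")
        if M and not (1 < cps[0] and cps[-1] < self.T):
            raise ValueError("change points must lie strictly inside (1, T)")
        if self.noise_kind not in ("gaussian_ma", "poisson"):
            raise ValueError(f"unknown noise_kind {self.noise_kind!r}")
        if self.noise_kind == "gaussian_ma" and not self.sigma > 0:
            raise ValueError("sigma must be positive for gaussian_ma noise")
        kap = tuple(float(k) for k in self.kappas)
        if kap and self.noise_kind == "poisson":
            raise ValueError("MA coefficients are meaningless for Poisson counts")
        object.__setattr__(self, "cps", cps)
        object.__setattr__(self, "kappas", kap)
        object.__setattr__(self, "_b", b)
        object.__setattr__(self, "_w", w)
        if self.noise_kind == "poisson":
            prof = mean_profile(self)
            if (prof < 0).any():
                raise ValueError("Poisson rates must be nonnegative in every segment")

    @property
    def N(self) -> int:
        return self._b.size

    @property
    def M(self) -> int:
        return len(self.cps)

    @property
    def order(self) -> int:
        """MA order q (number of nonzero-indexed coefficients supplied)."""
        return len(self.kappas)


def mean_profile(spec: StepModelSpec) -> np.ndarray:
    """Deterministic ``T x N`` piecewise-constant mean (or rate) profile."""
    prof = np.tile(spec._b, (spec.T, 1))
    for c, w in zip(spec.cps, spec._w):
        prof[c:, :] += w  # row index c is time t = c+1
    return prof


def _ma_noise(spec: StepModelSpec, rng: np.random.Generator) -> np.ndarray:
    """Stationary MA(q) Gaussian noise, T x N.

    Draws q pre-sample innovations per covariate so the process has its
    stationary distribution from t = 1 on.
    """
    q = spec.order
    eps = rng.normal(0.0, spec.sigma, size=(spec.T + q, spec.N))
    noise = eps[q:].copy()
    for tau, kappa in enumerate(spec.kappas, start=1):
        noise += kappa * eps[q - tau : spec.T + q - tau]
    return noise


def simulate_step_series(
    spec: StepModelSpec, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Simulate the Gaussian-MA step model; returns a ``T x N`` matrix."""
    if spec.noise_kind != "gaussian_ma":
        raise ValueError("simulate_step_series requires noise_kind='gaussian_ma'")
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    return mean_profile(spec) + _ma_noise(spec, rng)


def simulate_poisson_counts(
    spec: StepModelSpec, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Independent Poisson counts with the piecewise-constant rate profile."""
    if spec.noise_kind != "poisson":
        raise ValueError("simulate_poisson_counts requires noise_kind='poisson'")
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    return rng.poisson(mean_profile(spec)).astype(float)


def simulate(spec: StepModelSpec, rng: np.random.Generator | None = None) -> np.ndarray:
    """Dispatch on ``spec.noise_kind``."""
    if spec.noise_kind == "poisson":
        return simulate_poisson_counts(spec, rng)
    return simulate_step_series(spec, rng)


def sqrt_transform(x: np.ndarray) -> np.ndarray:
    """Elementwise square root, the standard variance-stabilising transform
    for count data (Var(sqrt(Poisson)) ~ 1/4, roughly rate-independent)."""
    x = np.asarray(x, dtype=float)
    if (x < 0).any():
        raise ValueError("sqrt_transform requires nonnegative entries")
    return np.sqrt(x)
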