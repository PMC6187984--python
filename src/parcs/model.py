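"""Paired adaptive regressors on the CUSUM curve (the PARCS model).

A step change in the mean of ``x`` at time ``c`` appears in the CUSUM curve
``y`` as a bend: ``y`` is piecewise linear in the mean, with a slope change
of exactly the step size ``w`` at ``c``.  PARCS therefore models ``y`` as an
intercept plus ``M`` *pairs* of hinge splines anchored at integer knots
``c in {2..T-1}``::

    h+_{t,c} = t - c  (t > c)      h-_{t,c} = c - t  (t < c)

    y_t ~ beta_0 + sum_m [ beta_m^+ h+_{t,c_m} + beta_m^- h-_{t,c_m} ]

Knots are placed adaptively: a greedy *forward* stage grows the model to a
liberal bound ``L``, a *pruning* stage removes the least useful pairs down to
the requested order ``M``, and a *ranking* stage orders the surviving knots
by explained variance.  Coefficients are re-estimated by ordinary least
squares at every addition or removal.  For ``N > 1`` response series the
knots are shared, each response gets its own coefficients, and selection uses
the response-averaged residual mean-square error.

The slope change at a fitted knot, ``beta^+ + beta^-``, estimates the step
size; summing the ``beta^-`` column and subtracting from the series mean
recovers the baseline.  These inversions live on :class:`ParcsResults`.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from functools import lru_cache

import numpy as np

from .cusum import CusumCurve, cusum_transform, _as_matrix

__all__ = [
    "Parcs",
    "ParcsResults",
    "StepEstimates",
    "fit_fixed_knots",
    "forward_select",
    "prune",
    "rank_knots",
    "fit_parcs",
]

# Knot sets are compared on mse with this relative tolerance; ties break to
# the smallest knot index.
_REL_TOL = 1e-12

# Above this length the precomputed Gram matrix of the full hinge design
# (O(T^2) memory) is not built and fits fall back to explicit least squares.
_GRAM_MAX_T = 2048


def _knot_cols(knots) -> np.ndarray:
    """Column indices of the (intercept + hinge-pair) design for a knot set."""
    idx = [0]
    for c in knots:
        base = 1 + 2 * (c - 2)
        idx.extend((base, base + 1))
    return np.asarray(idx, dtype=np.intp)


@lru_cache(maxsize=4)
def _full_design(T: int):
    """Design of all hinge pairs at knots 2..T-1 plus intercept.

    Returns the raw design ``D``, the Gram matrix of the column-normalised
    design (normalisation keeps the generalised inverses well conditioned;
    hinge columns otherwise scale like T^1.5), and the column norms.
    Cached per series length.
    """
    t = np.arange(1, T + 1, dtype=float)
    D = np.empty((T, 1 + 2 * (T - 2)))
    D[:, 0] = 1.0
    for c in range(2, T):
        base = 1 + 2 * (c - 2)
        D[:, base] = np.maximum(t - c, 0.0)
        D[:, base + 1] = np.maximum(c - t, 0.0)
    norms = np.linalg.norm(D, axis=0)
    Gn = (D.T @ D) / np.outer(norms, norms)
    return D, Gn, norms


def hinge_pair(T: int, c: int) -> tuple[np.ndarray, np.ndarray]:
    """The spline pair ``(h+, h-)`` anchored at knot ``c``, as length-T arrays."""
    if not 2 <= c <= T - 1:
        raise ValueError("knot must lie in {2..T-1}")
    t = np.arange(1, T + 1, dtype=float)
    return np.maximum(t - c, 0.0), np.maximum(c - t, 0.0)


def _explicit_design(T: int, knots) -> np.ndarray:
    cols = [np.ones(T)]
    for c in knots:
        hp, hm = hinge_pair(T, c)
        cols.extend((hp, hm))
    return np.column_stack(cols)


class _LstsqEngine:
    """Fallback least-squares engine building designs explicitly (large T)."""

    def __init__(self, curve: CusumCurve):
        self.curve = curve
        self.T, self.N = curve.T, curve.N
        self._yty = np.einsum("tn,tn->n", curve.y, curve.y)

    def _fit(self, knots):
        # The hinge-pair basis is structurally rank-deficient for two or more
        # knots (h+ - h- = t - c reproduces the global trend at every knot);
        # lstsq returns the minimum-norm solution, along whose null space the
        # fitted curve and every per-knot slope change are invariant.
        X = _explicit_design(self.T, knots)
        beta, _, rank, _ = np.linalg.lstsq(X, self.curve.y, rcond=None)
        if rank < min(X.shape[1], len(knots) + 2):
            raise ValueError(f"degenerate design for knots {tuple(knots)}")
        resid = self.curve.y - X @ beta
        mse_n = np.einsum("tn,tn->n", resid, resid) / self.T
        return beta, mse_n

    def solve(self, knots):
        return self._fit(knots)

    def scan_add(self, current, candidates):
        out = np.empty(len(candidates))
        for i, c in enumerate(candidates):
            _, mse_n = self._fit(tuple(current) + (c,))
            out[i] = mse_n.mean()
        return out

    def scan_remove(self, knots):
        out = np.empty(len(knots))
        for i in range(len(knots)):
            sub = tuple(knots[:i]) + tuple(knots[i + 1 :])
            _, mse_n = self._fit(sub)
            out[i] = mse_n.mean()
        return out

    def projector(self, knots):
        X = _explicit_design(self.T, knots)
        return np.linalg.pinv(X)

    def fitted(self, knots, beta):
        return _explicit_design(self.T, knots) @ beta


class _GramEngine:
    """Normal-equation engine over the cached full-design Gram matrix.

    Any knot-subset fit reduces to a small ``p x p`` system with
    ``p = 2*len(knots) + 1``; candidate scans batch those systems.  The
    hinge-pair basis is structurally rank-deficient for two or more knots
    (``h+ - h- = t - c`` reproduces the global trend at every knot), so the
    systems are solved with a pseudo-inverse: the minimum-norm solution,
    along whose null space the fitted curve, the per-knot slope changes and
    the pre-first-knot slope sum are all invariant.
    """

    _RCOND = 1e-11

    def __init__(self, curve: CusumCurve):
        self.curve = curve
        self.T, self.N = curve.T, curve.N
        self.D, self.Gn, self.norms = _full_design(self.T)
        self.bn = (self.D.T @ curve.y) / self.norms[:, None]  # (P, N)
        self._yty = np.einsum("tn,tn->n", curve.y, curve.y)

    def _solve_batch(self, idxmat: np.ndarray):
        """Minimum-norm normal-equation solutions for a stack of column sets,
        in the normalised basis.  Returns (beta_n (C,p,N), mse_avg (C,))."""
        A = self.Gn[idxmat[:, :, None], idxmat[:, None, :]]
        B = self.bn[idxmat]  # (C, p, N)
        beta = np.linalg.pinv(A, rcond=self._RCOND) @ B
        sse = self._yty[None, :] - np.einsum("cpn,cpn->cn", beta, B)
        mse = np.maximum(sse, 0.0).mean(axis=1) / self.T
        return beta, mse

    def solve(self, knots):
        idx = _knot_cols(knots)
        A = self.Gn[np.ix_(idx, idx)]
        B = self.bn[idx]
        beta_n = np.linalg.pinv(A, rcond=self._RCOND) @ B
        sse = self._yty - np.einsum("pn,pn->n", beta_n, B)
        beta = beta_n / self.norms[idx][:, None]
        return beta, np.maximum(sse, 0.0) / self.T

    def scan_add(self, current, candidates):
        base = _knot_cols(current)
        cand = np.asarray(candidates, dtype=np.intp)
        pair = 1 + 2 * (cand - 2)
        idxmat = np.concatenate(
            [
                np.broadcast_to(base, (cand.size, base.size)),
                pair[:, None],
                pair[:, None] + 1,
            ],
            axis=1,
        )
        _, mse = self._solve_batch(idxmat)
        return mse

    def scan_remove(self, knots):
        m = len(knots)
        keep = [
            tuple(knots[:i]) + tuple(knots[i + 1 :]) for i in range(m)
        ]
        idxmat = np.stack([_knot_cols(k) for k in keep])
        _, mse = self._solve_batch(idxmat)
        return mse

    def projector(self, knots):
        """Matrix ``W`` with ``beta = W @ y`` for this fixed knot set."""
        idx = _knot_cols(knots)
        A = self.Gn[np.ix_(idx, idx)]
        Dn = self.D[:, idx] / self.norms[idx]
        Wn = np.linalg.pinv(A, rcond=self._RCOND) @ Dn.T
        return Wn / self.norms[idx][:, None]

    def fitted(self, knots, beta):
        return self.D[:, _knot_cols(knots)] @ beta


def _make_engine(curve: CusumCurve):
    if curve.T <= _GRAM_MAX_T:
        return _GramEngine(curve)
    return _LstsqEngine(curve)


def _check_knots(T: int, knots):
    knots = tuple(int(c) for c in knots)
    if len(set(knots)) != len(knots):
        raise ValueError("knots must be distinct")
    if any(not 2 <= c <= T - 1 for c in knots):
        raise ValueError("knots must lie in {2..T-1}")
    if 2 * len(knots) + 1 >= T:
        raise ValueError("too many knots for series length")
    return knots


def _argmin_tied(values: np.ndarray) -> int:
    """Index of the minimum; near-ties (relative 1e-12) break to the first."""
    best = values.min()
    tol = best * (1.0 + _REL_TOL) if best > 0 else _REL_TOL * 0.0
    return int(np.flatnonzero(values <= max(best, tol))[0])


@dataclass(frozen=True)
class StepEstimates:
    """Step-model parameters recovered by inverting a fitted PARCS model."""

    baseline: np.ndarray  # (N,) b-hat per response
    weights: np.ndarray  # (M, N) w-hat per knot per response
    cps: tuple  # knot locations matching rows of `weights`
    mean_curve: np.ndarray  # (T, N) piecewise-constant mean estimate


@dataclass(frozen=True)
class ParcsResults:
    """Fitted PARCS model.

    ``knots`` are in ranking order (``knots[0]`` explains the most variance)
    when ``ranked`` is True, otherwise in selection order.  Coefficient rows
    follow ``knots``.
    """

    curve: CusumCurve
    knots: tuple
    intercept: np.ndarray  # (N,)
    coef_plus: np.ndarray  # (M, N)
    coef_minus: np.ndarray  # (M, N)
    mse_per_response: np.ndarray  # (N,)
    ranked: bool = False
    degenerate: bool = False
    model: "Parcs | None" = None

    @property
    def order(self) -> int:
        return len(self.knots)

    @property
    def T(self) -> int:
        return self.curve.T

    @property
    def nseries(self) -> int:
        return self.curve.N

    @property
    def mse(self) -> float:
        """Residual mean-square error, averaged over responses."""
        return float(self.mse_per_response.mean())

    @property
    def fittedvalues(self) -> np.ndarray:
        eng = _make_engine(self.curve)
        beta = self._beta_matrix()
        return eng.fitted(self.knots, beta)

    def _beta_matrix(self) -> np.ndarray:
        """(2M+1, N) coefficient matrix in engine column order."""
        M = self.order
        beta = np.empty((2 * M + 1, self.nseries))
        beta[0] = self.intercept
        beta[1::2] = self.coef_plus
        beta[2::2] = self.coef_minus
        return beta

    @property
    def bending(self) -> np.ndarray:
        """Per-knot, per-response slope change ``beta^+ + beta^-`` (M, N)."""
        return self.coef_plus + self.coef_minus

    def bending_statistic(self, m: int) -> float:
        """Test statistic ``S = |beta^+ + beta^-|`` at ranked knot index ``m``
        (0-based); averaged over responses for multivariate fits."""
        if not 0 <= m < self.order:
            raise IndexError("knot index out of range")
        return float(np.abs(self.bending[m]).mean())

    def step_estimates(self) -> StepEstimates:
        """Invert the fit to step-model parameters (b-hat, w-hat, mean curve).

        The slope change at each knot estimates the step size; the slope
        before the first knot, ``-sum_m beta_m^-``, estimates ``b - <x>``.
        """
        w = self.bending
        b = self.curve.x_mean - self.coef_minus.sum(axis=0)
        mean = np.tile(b, (self.T, 1))
        for c, w_m in zip(self.knots, w):
            mean[c:, :] += w_m
        return StepEstimates(baseline=b, weights=w, cps=self.knots, mean_curve=mean)

    def test_significance(
        self,
        alpha: float = 0.05,
        n_boot: int = 1000,
        block_size: int | None = None,
        max_order: int = 9,
        order_alpha: float = 0.05,
        seed=None,
    ):
        """Block-permutation bootstrap test of each ranked knot.

        When ``block_size`` is None the MA order of the residual series is
        estimated first and ``k = q + 1`` is used.  See
        :func:`parcs.bootstrap.parcs_significance_test`.
        """
        from .bootstrap import BootstrapConfig, parcs_significance_test
        from .noise import estimate_ma_order, h0_residual_series

        if block_size is None:
            h0 = h0_residual_series(self.curve, self)
            q = estimate_ma_order(h0.x0, Q=max_order, alpha=order_alpha)
            block_size = q + 1
        cfg = BootstrapConfig(n_boot=n_boot, block_size=block_size, alpha=alpha, seed=seed)
        return parcs_significance_test(self.curve, self, cfg)

    def summary(self) -> str:
        """Plain-text summary of the fitted model."""
        lines = [
            "PARCS model fit",
            "=" * 56,
            f"Series length T:      {self.T}",
            f"Responses N:          {self.nseries}",
            f"Model order M:        {self.order}",
            f"Residual MSE:         {self.mse:.6g}",
            f"Knots ranked:         {self.ranked}",
            "-" * 56,
            f"{'rank':>4} {'knot':>6} {'bend |b+ + b-|':>16} {'step w-hat':>12}",
        ]
        steps = self.step_estimates()
        for m, c in enumerate(self.knots):
            wbar = float(steps.weights[m].mean())
            lines.append(
                f"{m + 1:>4} {c:>6} {self.bending_statistic(m):>16.4f} {wbar:>12.4f}"
            )
        lines.append("-" * 56)
        base = ", ".join(f"{v:.3f}" for v in steps.baseline)
        lines.append(f"Baseline b-hat:       {base}")
        return "\n".join(lines)

    def plot(self, series: int = 0, ax=None):
        """Plot the CUSUM curve and the fitted piecewise-linear model."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        t = np.arange(1, self.T + 1)
        ax.plot(t, self.curve.y[:, series], lw=1, label="CUSUM curve")
        ax.plot(t, self.fittedvalues[:, series], lw=2, label="PARCS fit")
        for c in self.knots:
            ax.axvline(c, color="gray", ls=":", lw=1)
        ax.set_xlabel("time step")
        ax.set_ylabel("cumulative deviation")
        ax.legend()
        return ax


def fit_fixed_knots(curve: CusumCurve, knots, model=None) -> ParcsResults:
    """Ordinary least squares on the hinge-pair basis for a fixed knot set."""
    knots = _check_knots(curve.T, knots)
    eng = _make_engine(curve)
    beta, mse_n = eng.solve(knots)
    M = len(knots)
    return ParcsResults(
        curve=curve,
        knots=knots,
        intercept=beta[0],
        coef_plus=beta[1::2].reshape(M, curve.N),
        coef_minus=beta[2::2].reshape(M, curve.N),
        mse_per_response=mse_n,
        degenerate=bool((curve.y == 0).all()),
        model=model,
    )


def forward_select(curve: CusumCurve, L: int, model=None) -> ParcsResults:
    """Greedy forward stage: add the hinge pair reducing mse the most, L times."""
    if L < 1:
        raise ValueError("forward bound L must be >= 1")
    if 2 * L + 1 >= curve.T:
        raise ValueError("forward bound L too large for series length")
    eng = _make_engine(curve)
    knots: list[int] = []
    all_candidates = np.arange(2, curve.T)
    for _ in range(L):
        cand = np.array([c for c in all_candidates if c not in knots])
        mse = eng.scan_add(tuple(knots), cand)
        knots.append(int(cand[_argmin_tied(mse)]))
    return fit_fixed_knots(curve, knots, model=model)


def prune(results: ParcsResults, M: int) -> ParcsResults:
    """Backward stage: drop the pair whose removal costs least, down to M knots."""
    if M > results.order:
        raise ValueError("cannot prune to more knots than the model has")
    if M < 0:
        raise ValueError("target order must be >= 0")
    knots = list(results.knots)
    eng = _make_engine(results.curve)
    while len(knots) > M:
        mse = eng.scan_remove(tuple(knots))
        knots.pop(_argmin_tied(mse))
    if not knots:
        # intercept-only model
        y = results.curve.y
        mean = y.mean(axis=0)
        mse_n = np.einsum("tn,tn->n", y - mean, y - mean) / results.T
        return replace(
            results,
            knots=(),
            intercept=mean,
            coef_plus=np.zeros((0, results.nseries)),
            coef_minus=np.zeros((0, results.nseries)),
            mse_per_response=mse_n,
        )
    return fit_fixed_knots(results.curve, knots, model=results.model)


def rank_knots(results: ParcsResults) -> ParcsResults:
    """Ranking stage: order knots by explained variance.

    Knots are pruned further, one at a time, down to the empty model; the
    first knot removed explains the least variance and is ranked last.
    """
    if results.order == 0:
        return replace(results, ranked=True)
    knots = list(results.knots)
    eng = _make_engine(results.curve)
    removal: list[int] = []
    while knots:
        mse = eng.scan_remove(tuple(knots))
        removal.append(knots.pop(_argmin_tied(mse)))
    ranked = tuple(removal[::-1])  # last removed explains the most variance
    order = [results.knots.index(c) for c in ranked]
    return replace(
        results,
        knots=ranked,
        coef_plus=results.coef_plus[order],
        coef_minus=results.coef_minus[order],
        ranked=True,
    )


class Parcs:
    """PARCS change-point model for a (possibly multivariate) time series.

    Parameters
    ----------
    endog : array_like
        Observed series, shape ``(T,)`` or ``(T, N)``.  Rows are time steps.
    order : int
        Final model order ``M`` (number of candidate CPs retained).
    forward_bound : int, optional
        Forward-stage bound ``L``; defaults to ``3 * order`` (the upper end
        of the usual 2-3x heuristic).

    Examples
    --------
    >>> res = Parcs(x, order=2).fit()
    >>> res.knots
    (60, 20)
    >>> det = res.test_significance(alpha=0.05, n_boot=1000, seed=0)
    """

    def __init__(self, endog, order: int, forward_bound: int | None = None):
        self.endog = _as_matrix(endog)
        if order < 0:
            raise ValueError("order M must be >= 0")
        self.order = int(order)
        self.forward_bound = int(forward_bound) if forward_bound else 3 * self.order
        if self.forward_bound < self.order:
            raise ValueError("forward bound L must be >= order M")
        self.curve = cusum_transform(self.endog)

    @classmethod
    def from_dataframe(cls, df, order: int, forward_bound: int | None = None):
        """Build from a pandas DataFrame (rows = time steps, columns = series)."""
        return cls(np.asarray(df, dtype=float), order, forward_bound)

    @property
    def T(self) -> int:
        return self.curve.T

    @property
    def nseries(self) -> int:
        return self.curve.N

    def fit(self) -> ParcsResults:
        """Run forward selection, pruning and ranking; return the results."""
        if self.order == 0:
            y = self.curve.y
            mean = y.mean(axis=0)
            mse_n = np.einsum("tn,tn->n", y - mean, y - mean) / self.T
            return ParcsResults(
                curve=self.curve,
                knots=(),
                intercept=mean,
                coef_plus=np.zeros((0, self.nseries)),
                coef_minus=np.zeros((0, self.nseries)),
                mse_per_response=mse_n,
                ranked=True,
                model=self,
            )
        sel = forward_select(self.curve, self.forward_bound, model=self)
        return rank_knots(prune(sel, self.order))


def fit_parcs(x, M: int, L: int | None = None) -> ParcsResults:
    """Convenience one-call fit: ``Parcs(x, order=M, forward_bound=L).fit()``."""
    return Parcs(x, order=M, forward_bound=L).fit()
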