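"""Block-permutation bootstrap significance tests for change points.

The null distribution of a CP statistic is approximated by permuting
contiguous blocks of an H0-conform residual series (the observed series with
all fitted step structure removed).  Blocks of size ``k = q + 1`` preserve
the temporal dependence of an MA(q) noise process; ``k = 1`` is an ordinary
permutation for independent noise.  Two tests are provided:

* the classical CUSUM AMOC test — max absolute CUSUM deviation against the
  permuted-sample EDF;
* the PARCS test — the bending statistic ``S = |beta^+ + beta^-|`` of each
  ranked knot against the EDF of the same statistic computed on permuted
  samples, processed sequentially in rank order with accepted splines
  regressed out (conservative by construction).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .cusum import CusumCurve, _as_matrix, amoc_locator, cusum_statistic
from .model import ParcsResults, StepEstimates, _make_engine, fit_fixed_knots, fit_parcs
from .noise import estimate_ma_order, h0_residual_series

__all__ = [
    "BootstrapConfig",
    "CandidateTest",
    "DetectionResult",
    "block_permute",
    "edf_threshold",
    "bending_statistic",
    "cusum_amoc_test",
    "parcs_significance_test",
    "detect_changepoints",
]


@dataclass(frozen=True)
class BootstrapConfig:
    """Settings of the block-permutation bootstrap.

    ``n_boot`` is the number of permutations B, ``block_size`` the block
    length k, ``alpha`` the nominal level.  ``seed`` feeds a fresh
    ``numpy.random.default_rng`` per test invocation.
    """

    n_boot: int = 1000
    block_size: int = 1
    alpha: float = 0.05
    seed: object = None

    def __post_init__(self):
        if self.n_boot < 100:
            raise ValueError("at least 100 bootstrap permutations are required")
        if self.block_size < 1:
            raise ValueError("block size must be >= 1")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.alpha < 1.0 / self.n_boot:
            warnings.warn(
                "alpha below 1/B: the EDF cannot resolve the requested quantile",
                stacklevel=2,
            )

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass(frozen=True)
class CandidateTest:
    """Outcome of the bootstrap test at one candidate CP."""

    location: int
    rank: int  # 1-based position in the explained-variance ranking
    statistic: float
    threshold: float
    p_value: float
    accepted: bool


@dataclass(frozen=True)
class DetectionResult:
    """Significant CPs with their test records and inverted step estimates."""

    candidates: tuple  # of CandidateTest, in rank order
    model: ParcsResults | None = None
    steps: StepEstimates | None = None
    block_size: int = 1
    ma_order: int | None = None
    config: BootstrapConfig | None = None

    @property
    def significant(self) -> tuple:
        """Accepted CP locations, in rank order."""
        return tuple(c.location for c in self.candidates if c.accepted)

    @property
    def n_significant(self) -> int:
        return len(self.significant)

    def summary(self) -> str:
        lines = [
            "Change-point detection (block-permutation bootstrap)",
            "=" * 60,
            f"Block size k:     {self.block_size}"
            + (f"  (estimated MA order q = {self.ma_order})" if self.ma_order is not None else ""),
            f"Significant CPs:  {list(self.significant)}",
            "-" * 60,
            f"{'rank':>4} {'loc':>5} {'S':>10} {'thresh':>10} {'p':>8}  decision",
        ]
        for c in self.candidates:
            lines.append(
                f"{c.rank:>4} {c.location:>5} {c.statistic:>10.4f} "
                f"{c.threshold:>10.4f} {c.p_value:>8.4f}  "
                + ("significant" if c.accepted else "rejected")
            )
        if self.steps is not None and len(self.steps.cps):
            lines.append("-" * 60)
            for c, w in zip(self.steps.cps, self.steps.weights):
                wtxt = ", ".join(f"{v:+.3f}" for v in np.atleast_1d(w))
                lines.append(f"step at t={c}: w-hat = [{wtxt}]")
        return "\n".join(lines)


def _block_index_matrix(T: int, k: int, B: int, rng: np.random.Generator) -> np.ndarray:
    """(B, T) time indices of B independent block permutations.

    The series is cut into ``ceil(T/k)`` consecutive blocks (last one shorter
    when ``k`` does not divide ``T``); each row is a uniformly random block
    order, identical across columns of the series it will index.
    """
    if not 1 <= k <= T:
        raise ValueError("block size must satisfy 1 <= k <= T")
    starts = np.arange(0, T, k)
    lens = np.minimum(k, T - starts)
    nb = starts.size
    order = rng.permuted(np.tile(np.arange(nb), (B, 1)), axis=1)
    st = starts[order].ravel()
    ln = lens[order].ravel()
    csum = np.concatenate(([0], np.cumsum(ln)[:-1]))
    offsets = np.arange(B * T) - np.repeat(csum, ln)
    return (np.repeat(st, ln) + offsets).reshape(B, T)


def block_permute(x0, k: int, rng: np.random.Generator) -> np.ndarray:
    """One block permutation of a series (columns share the block order)."""
    x0 = np.asarray(x0, dtype=float)
    T = x0.shape[0]
    idx = _block_index_matrix(T, k, 1, rng)[0]
    return x0[idx] if x0.ndim == 1 else x0[idx, :]


def edf_threshold(samples, alpha: float) -> float:
    """(1 - alpha) quantile of the bootstrap EDF.

    Implemented as the ``ceil((1 - alpha) * B)``-th smallest order statistic;
    the rejection rule is ``S >= threshold``.
    """
    s = np.sort(np.asarray(samples, dtype=float).ravel())
    if s.size == 0:
        raise ValueError("empty bootstrap sample")
    if not np.isfinite(s).all():
        raise ValueError("non-finite bootstrap sample")
    j = int(np.ceil((1.0 - alpha) * s.size))
    return float(s[min(max(j, 1), s.size) - 1])


def _pvalue(samples: np.ndarray, s: float) -> float:
    return float((1 + np.sum(samples >= s)) / (samples.size + 1))


def bending_statistic(results: ParcsResults, m: int) -> float:
    """Bend magnitude ``|beta^+ + beta^-|`` at knot index ``m`` (0-based),
    averaged over responses for multivariate fits."""
    return results.bending_statistic(m)


def _permuted_curves(x0: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """CUSUM-transform every permuted sample; (B, T, N)."""
    xp = x0[idx, :]  # (B, T, N)
    return np.cumsum(xp - xp.mean(axis=1, keepdims=True), axis=1)


def cusum_amoc_test(x, cfg: BootstrapConfig, gamma: float = 0.0) -> DetectionResult:
    """Classical single-CP bootstrap test.

    Locates the candidate via the (optionally weighted) CUSUM locator,
    removes the estimated step to form the H0-conform series, and compares
    the max-CUSUM statistic with its EDF over block-permuted samples.
    """
    x = _as_matrix(x)
    if x.shape[1] != 1:
        raise ValueError("cusum_amoc_test expects a univariate series")
    xf = x[:, 0]
    T = xf.size
    c_hat = amoc_locator(xf, gamma)
    s_obs = cusum_statistic(xf)
    before = xf[:c_hat].mean()
    after = xf[c_hat:].mean()
    w_hat = after - before
    x0 = xf - w_hat * (np.arange(1, T + 1) > c_hat)
    rng = cfg.rng()
    idx = _block_index_matrix(T, cfg.block_size, cfg.n_boot, rng)
    yp = np.cumsum(
        x0[idx] - x0[idx].mean(axis=1, keepdims=True), axis=1
    )
    s_null = np.abs(yp[:, :-1]).max(axis=1)
    thr = edf_threshold(s_null, cfg.alpha)
    accepted = bool(s_obs >= thr)
    cand = CandidateTest(
        location=c_hat,
        rank=1,
        statistic=s_obs,
        threshold=thr,
        p_value=_pvalue(s_null, s_obs),
        accepted=accepted,
    )
    steps = None
    if accepted:
        steps = StepEstimates(
            baseline=np.array([before]),
            weights=np.array([[w_hat]]),
            cps=(c_hat,),
            mean_curve=(before + w_hat * (np.arange(1, T + 1) > c_hat))[:, None],
        )
    return DetectionResult(
        candidates=(cand,), steps=steps, block_size=cfg.block_size, config=cfg
    )


def parcs_significance_test(
    curve: CusumCurve, results: ParcsResults, cfg: BootstrapConfig
) -> DetectionResult:
    """Sequential bootstrap test of every ranked PARCS knot.

    For each knot in rank order: splines already accepted are regressed out
    of ``y``; the remaining knot set is refitted to the residual curve and
    the bending statistic read at the tested knot; the null EDF comes from
    block permutations of the global H0-conform series, each CUSUM-
    transformed and fitted with the *same* remaining knot set.
    """
    if not results.ranked:
        from .model import rank_knots

        results = rank_knots(results)
    T, N = curve.T, curve.N
    nblocks = int(np.ceil(T / cfg.block_size))
    if nblocks < 7:
        warnings.warn(
            f"only {nblocks} blocks: the permutation space may be too small "
            "for a reliable EDF",
            stacklevel=2,
        )
    rng = cfg.rng()
    x0 = h0_residual_series(curve, results).x0
    eng = _make_engine(curve)
    accepted: list[int] = []
    records: list[CandidateTest] = []
    for m in range(results.order):
        # Splines already accepted are regressed out of y; the remaining
        # ranked knots {c_m..c_M} are refit to the residual curve and the
        # bend is read at the tested knot.  The null EDF mirrors this exactly:
        # each block-permuted H0 series is CUSUM-transformed and fit with the
        # same remaining knot set, the statistic read at the same knot.
        if accepted:
            acc_fit = fit_fixed_knots(curve, tuple(accepted))
            y_res = curve.y - acc_fit.fittedvalues
        else:
            y_res = curve.y
        remaining = results.knots[m:]
        fit_m = fit_fixed_knots(CusumCurve(y=y_res, x_mean=curve.x_mean), remaining)
        s_obs = fit_m.bending_statistic(0)
        idx = _block_index_matrix(T, cfg.block_size, cfg.n_boot, rng)
        yp = _permuted_curves(x0, idx)
        W = eng.projector(remaining)  # (p, T): rows 1, 2 are h+/h- at the knot
        beta = np.einsum("pt,btn->bpn", W, yp)
        s_null = np.abs(beta[:, 1, :] + beta[:, 2, :]).mean(axis=1)
        thr = edf_threshold(s_null, cfg.alpha)
        ok = bool(s_obs >= thr) and not results.degenerate
        records.append(
            CandidateTest(
                location=remaining[0],
                rank=m + 1,
                statistic=s_obs,
                threshold=thr,
                p_value=_pvalue(s_null, s_obs),
                accepted=ok,
            )
        )
        if ok:
            accepted.append(remaining[0])
    steps = None
    if accepted:
        steps = fit_fixed_knots(curve, tuple(accepted)).step_estimates()
    return DetectionResult(
        candidates=tuple(records),
        model=results,
        steps=steps,
        block_size=cfg.block_size,
        config=cfg,
    )


def detect_changepoints(
    x,
    M: int,
    L: int | None = None,
    alpha: float = 0.05,
    n_boot: int = 1000,
    block_size: int | None = None,
    max_order: int = 9,
    order_alpha: float = 0.05,
    seed=None,
) -> DetectionResult:
    """End-to-end pipeline: fit PARCS_M, size the blocks, test the knots.

    ``block_size=None`` estimates the MA order q of the residual series and
    uses ``k = q + 1`` (q capped at ``max_order``); pass ``block_size=1`` for
    independent noise.
    """
    results = fit_parcs(x, M, L)
    q_hat = None
    if block_size is None:
        h0 = h0_residual_series(results.curve, results)
        q_hat = estimate_ma_order(h0.x0, Q=max_order, alpha=order_alpha)
        block_size = q_hat + 1
    cfg = BootstrapConfig(n_boot=n_boot, block_size=block_size, alpha=alpha, seed=seed)
    det = parcs_significance_test(results.curve, results, cfg)
    return DetectionResult(
        candidates=det.candidates,
        model=det.model,
        steps=det.steps,
        block_size=block_size,
        ma_order=q_hat,
        config=cfg,
    )
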