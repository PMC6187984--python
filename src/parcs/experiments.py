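"""Simulation experiments: replicate drivers, summary tables, file I/O.

These drivers reproduce the benchmark conditions used to validate the
method: single-CP (AMOC) grids with white or MA noise, the null-series size
study, three two-CP weight scenarios under white and MA(2) noise, and the
nine-covariate multivariate Gaussian and Poisson settings.  Each driver
returns one tidy record per replicate realization; summary helpers turn
those into rates and accuracy scores.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .binseg import binseg_detect
from .bootstrap import BootstrapConfig, cusum_amoc_test, detect_changepoints, parcs_significance_test
from .metrics import accuracy_score, error_rates
from .model import fit_parcs
from .noise import estimate_ma_order, h0_residual_series
from .simulate import StepModelSpec, simulate, sqrt_transform

__all__ = [
    "ExperimentConfig",
    "ResultsTable",
    "run_experiment",
    "amoc_replicates",
    "h0_size_study",
    "multicp_replicates",
    "binseg_replicates",
    "multivariate_replicates",
    "summarize_multicp",
    "read_series",
    "write_results",
    "SCENARIO_WEIGHTS",
    "MULTIVARIATE_PARAMS",
    "MA2_NOISE",
]

logger = logging.getLogger("parcs")

# Two-CP weight scenarios (steps at t = 20 and t = 60, T = 100, b = 0).
SCENARIO_WEIGHTS = {1: (1.0, 2.0), 2: (2.0, -1.0), 3: (2.0, 1.0)}

# Nine-covariate settings: common CPs at 20 and 60.
MULTIVARIATE_PARAMS = {
    "gaussian": dict(
        baseline=(0, 0, 0, 2, 2, 2, 0, 1, 2),
        weights=((1, 2, 2, -2, 0, 0, 0, 0, 0), (2, 1, -1, 0, 1, -1, 0, 0, 0)),
        sigma=1.0,
    ),
    "poisson": dict(
        baseline=(1, 1, 1, 3, 3, 3, 1, 2, 1),
        weights=((1, 2, 2, -2, 0, 0, 0, 0, 0), (2, 1, -1, 0, 1, -1, 0, 0, 0)),
    ),
}

# MA(2) noise used in the dependent-noise studies: sigma = 0.7 with
# kappa_1 = -0.5/sigma, kappa_2 = 0.4/sigma.
MA2_NOISE = dict(sigma=0.7, kappas=(-0.5 / 0.7, 0.4 / 0.7))


def _spawn_rngs(seed, R: int) -> list[np.random.Generator]:
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    return [np.random.default_rng(s) for s in ss.spawn(R)]


def _boot_seed(rng: np.random.Generator) -> int:
    return int(rng.integers(2**31))


# ---------------------------------------------------------------------------
# AMOC (single CP) studies
# ---------------------------------------------------------------------------


def amoc_replicates(
    c: int | None,
    R: int = 200,
    B: int = 1000,
    T: int = 100,
    w: float = 1.0,
    sigma: float = 1.0,
    kappas: tuple = (),
    alpha: float = 0.05,
    gamma: float = 0.0,
    block_size: int = 1,
    forward_bound: int = 3,
    seed=None,
) -> pd.DataFrame:
    """Single-CP study: the CUSUM test and the PARCS_1 test per replicate.

    ``c=None`` simulates pure noise (the no-change null).  Returns one row
    per replicate with each method's located CP, p-value and decision at the
    nominal ``alpha``.
    """
    rows = []
    for rng in _spawn_rngs(seed, R):
        spec = StepModelSpec(
            T=T,
            cps=(c,) if c is not None else (),
            weights=((w,),) if c is not None else (),
            sigma=sigma,
            kappas=kappas,
        )
        x = simulate(spec, rng)[:, 0]
        cfg_c = BootstrapConfig(B, block_size, alpha, seed=_boot_seed(rng))
        det_c = cusum_amoc_test(x, cfg_c, gamma).candidates[0]
        res = fit_parcs(x, M=1, L=forward_bound)
        cfg_p = BootstrapConfig(B, block_size, alpha, seed=_boot_seed(rng))
        det_p = parcs_significance_test(res.curve, res, cfg_p).candidates[0]
        rows.append(
            dict(
                cusum_c=det_c.location,
                cusum_p=det_c.p_value,
                cusum_sig=det_c.accepted,
                parcs_c=det_p.location,
                parcs_p=det_p.p_value,
                parcs_sig=det_p.accepted,
            )
        )
    return pd.DataFrame(rows)


def _rejects(p_values: np.ndarray, B: int, alpha: float) -> np.ndarray:
    """Decisions ``S >= F^-1(1-alpha)`` recovered from stored p-values.

    With continuous statistics ``p = (1 + #{S_i >= S}) / (B + 1)``, the
    threshold rule rejects iff ``#{S_i >= S} <= B - ceil((1-alpha) B)``.
    """
    n_geq = np.round(p_values * (B + 1) - 1).astype(int)
    return n_geq <= B - int(np.ceil((1.0 - alpha) * B))


def h0_size_study(
    R: int = 500,
    B: int = 1000,
    T: int = 100,
    sigma: float = 1.0,
    alphas=(0.05,),
    seed=None,
) -> pd.DataFrame:
    """Empirical type-I error rates of both tests on pure-noise series.

    One simulation per replicate; the stored bootstrap p-values are
    evaluated against every nominal level in ``alphas``.
    """
    rec = amoc_replicates(None, R=R, B=B, T=T, sigma=sigma, seed=seed)
    rows = []
    for a in alphas:
        rows.append(
            dict(
                alpha=a,
                cusum_rate=100.0 * _rejects(rec["cusum_p"].to_numpy(), B, a).mean(),
                parcs_rate=100.0 * _rejects(rec["parcs_p"].to_numpy(), B, a).mean(),
            )
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Multiple-CP studies
# ---------------------------------------------------------------------------


def multicp_replicates(
    weights: tuple,
    R: int = 200,
    B: int = 1000,
    T: int = 100,
    cps: tuple = (20, 60),
    sigma: float = 1.0,
    kappas: tuple = (),
    alpha: float = 0.05,
    M: int = 3,
    L: int | None = None,
    block_size: int | None = 1,
    max_order: int = 9,
    seed=None,
) -> pd.DataFrame:
    """Two-CP univariate study with PARCS_M detection.

    ``block_size=None`` estimates the MA order per replicate and uses
    ``k = q + 1`` (the dependent-noise protocol); ``block_size=1`` is the
    white-noise protocol.  Each row records the significant CP set.
    """
    rows = []
    for rng in _spawn_rngs(seed, R):
        spec = StepModelSpec(
            T=T,
            cps=cps,
            weights=tuple((w,) for w in weights),
            sigma=sigma,
            kappas=kappas,
        )
        x = simulate(spec, rng)[:, 0]
        det = detect_changepoints(
            x,
            M=M,
            L=L,
            alpha=alpha,
            n_boot=B,
            block_size=block_size,
            max_order=max_order,
            seed=_boot_seed(rng),
        )
        rows.append(
            dict(
                detected=det.significant,
                n_sig=det.n_significant,
                block_size=det.block_size,
                q_hat=det.ma_order,
            )
        )
    return pd.DataFrame(rows)


def binseg_replicates(
    weights: tuple,
    R: int = 200,
    B: int = 1000,
    T: int = 100,
    cps: tuple = (20, 60),
    sigma: float = 1.0,
    alpha: float = 0.05,
    max_depth: int = 1,
    min_len: int = 8,
    seed=None,
) -> pd.DataFrame:
    """Two-CP study for the binary-segmentation baseline (independent noise)."""
    rows = []
    for rng in _spawn_rngs(seed, R):
        spec = StepModelSpec(
            T=T, cps=cps, weights=tuple((w,) for w in weights), sigma=sigma
        )
        x = simulate(spec, rng)[:, 0]
        cfg = BootstrapConfig(B, 1, alpha, seed=_boot_seed(rng))
        found = binseg_detect(x, cfg, max_depth=max_depth, min_len=min_len)
        rows.append(dict(detected=tuple(found), n_sig=len(found)))
    return pd.DataFrame(rows)


def multivariate_replicates(
    kind: str = "gaussian",
    R: int = 200,
    B: int = 1000,
    T: int = 100,
    cps: tuple = (20, 60),
    w0: float = 1.0,
    alpha: float = 0.05,
    M: int = 3,
    L: int | None = None,
    block_size: int = 1,
    seed=None,
) -> pd.DataFrame:
    """Nine-covariate study (Gaussian noise or Poisson counts).

    Poisson counts are square-root transformed before fitting, the standard
    variance-stabilising step for spike-count data.  ``w0`` scales the
    Gaussian step weights (signal-to-noise dial).
    """
    params = MULTIVARIATE_PARAMS[kind]
    weights = tuple(
        tuple(w0 * v for v in row) if kind == "gaussian" else tuple(row)
        for row in params["weights"]
    )
    rows = []
    for rng in _spawn_rngs(seed, R):
        spec = StepModelSpec(
            T=T,
            baseline=params["baseline"],
            cps=cps,
            weights=weights,
            noise_kind="gaussian_ma" if kind == "gaussian" else "poisson",
            sigma=params.get("sigma", 1.0),
        )
        x = simulate(spec, rng)
        if kind == "poisson":
            x = sqrt_transform(x)
        det = detect_changepoints(
            x, M=M, L=L, alpha=alpha, n_boot=B, block_size=block_size,
            seed=_boot_seed(rng),
        )
        rows.append(dict(detected=det.significant, n_sig=det.n_significant))
    return pd.DataFrame(rows)


def ma_order_study(
    weights: tuple = SCENARIO_WEIGHTS[2],
    R: int = 1000,
    T: int = 100,
    cps: tuple = (20, 60),
    M: int = 3,
    Q: int = 9,
    alpha: float = 0.05,
    seed=None,
    **noise,
) -> pd.DataFrame:
    """Recovering the MA order from PARCS residual series (no bootstrap).

    Fits PARCS_M per replicate, inverts to the H0-conform residual series
    and estimates the MA order from its autocorrelation function.
    """
    noise = noise or MA2_NOISE
    rows = []
    for rng in _spawn_rngs(seed, R):
        spec = StepModelSpec(
            T=T, cps=cps, weights=tuple((w,) for w in weights), **noise
        )
        x = simulate(spec, rng)[:, 0]
        res = fit_parcs(x, M=M)
        x0 = h0_residual_series(res.curve, res).x0
        rows.append(dict(q_hat=estimate_ma_order(x0, Q=Q, alpha=alpha)))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------


def summarize_multicp(
    records: pd.DataFrame, true_cps=(20, 60), T: int = 100, M: int = 3
) -> dict:
    """Rates and accuracy scores from a multiple-CP replicate table."""
    detections = list(records["detected"])
    t1, t2 = error_rates(detections, true_cps, T)
    out = dict(
        n_replicates=len(detections),
        pct_exactly_m=100.0 * float((records["n_sig"] == len(true_cps)).mean()),
        type1_rate=t1,
        type2_rate=t2,
    )
    for c in true_cps:
        out[f"accuracy_c{c}"] = accuracy_score(detections, c, T, M, alpha_hat=t1)
    return out


# ---------------------------------------------------------------------------
# Configurable runner
# ---------------------------------------------------------------------------


@dataclass
class ExperimentConfig:
    """Declarative experiment description (CLI / config-file entry point)."""

    scenario: str  # amoc | amoc_h0 | multicp_white | multicp_ma | binseg |
    #               multivariate_gaussian | multivariate_poisson | ma_order
    replicates: int = 200
    n_boot: int = 1000
    alpha: float = 0.05
    T: int = 100
    seed: int | None = None
    options: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        known = {k: d[k] for k in ("scenario", "replicates", "n_boot", "alpha", "T", "seed") if k in d}
        extra = {k: v for k, v in d.items() if k not in known}
        return cls(**known, options=extra)


@dataclass
class ResultsTable:
    """Per-replicate records plus a scalar summary."""

    records: pd.DataFrame
    summary: dict


def run_experiment(cfg: ExperimentConfig) -> ResultsTable:
    """Run one experiment cell; deterministic given the config seed."""
    t0 = time.perf_counter()
    opt = dict(cfg.options)
    sc = cfg.scenario
    if sc == "amoc":
        rec = amoc_replicates(
            opt.pop("c", 20), R=cfg.replicates, B=cfg.n_boot, T=cfg.T,
            alpha=cfg.alpha, seed=cfg.seed, **opt,
        )
        both = rec["cusum_sig"] & rec["parcs_sig"]
        summary = dict(
            cusum_detect_rate=100.0 * float(rec["cusum_sig"].mean()),
            parcs_detect_rate=100.0 * float(rec["parcs_sig"].mean()),
            both_detect_rate=100.0 * float(both.mean()),
        )
    elif sc == "amoc_h0":
        tab = h0_size_study(
            R=cfg.replicates, B=cfg.n_boot, T=cfg.T,
            alphas=opt.pop("alphas", (cfg.alpha,)), seed=cfg.seed, **opt,
        )
        rec = tab
        summary = tab.to_dict("records")[0] if len(tab) == 1 else dict(rows=len(tab))
    elif sc in ("multicp_white", "multicp_ma"):
        scenario_id = opt.pop("weights_scenario", 1)
        weights = opt.pop("weights", SCENARIO_WEIGHTS[scenario_id])
        kw = dict(R=cfg.replicates, B=cfg.n_boot, T=cfg.T, alpha=cfg.alpha, seed=cfg.seed)
        if sc == "multicp_ma":
            kw.update(block_size=None, **MA2_NOISE)
        rec = multicp_replicates(weights, **kw, **opt)
        summary = summarize_multicp(rec, T=cfg.T)
    elif sc == "binseg":
        scenario_id = opt.pop("weights_scenario", 1)
        weights = opt.pop("weights", SCENARIO_WEIGHTS[scenario_id])
        rec = binseg_replicates(
            weights, R=cfg.replicates, B=cfg.n_boot, T=cfg.T,
            alpha=cfg.alpha, seed=cfg.seed, **opt,
        )
        summary = summarize_multicp(rec, T=cfg.T)
    elif sc in ("multivariate_gaussian", "multivariate_poisson"):
        rec = multivariate_replicates(
            sc.split("_")[1], R=cfg.replicates, B=cfg.n_boot, T=cfg.T,
            alpha=cfg.alpha, seed=cfg.seed, **opt,
        )
        summary = summarize_multicp(rec, T=cfg.T)
    elif sc == "ma_order":
        rec = ma_order_study(R=cfg.replicates, T=cfg.T, seed=cfg.seed, **opt)
        summary = dict(
            pct_order_2=100.0 * float((rec["q_hat"] == 2).mean()),
            mean_order=float(rec["q_hat"].mean()),
        )
    else:
        raise ValueError(f"unknown scenario {sc!r}")
    summary["runtime_s"] = round(time.perf_counter() - t0, 3)
    logger.info("scenario %s done in %.1fs", sc, summary["runtime_s"])
    return ResultsTable(records=rec, summary=summary)


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------


def read_series(path, header: str | bool = "auto") -> np.ndarray:
    """Read a T x N numeric matrix from delimited text (CSV/TSV).

    ``header='auto'`` treats the first line as a header iff it fails to
    parse as numbers.  Raises on ragged rows, non-numeric cells or T < 3.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    with open(path) as fh:
        first = fh.readline()
    if header == "auto":
        try:
            [float(v) for v in first.strip().split(sep)]
            header = False
        except ValueError:
            header = True
    df = pd.read_csv(
        path, sep=sep, header=0 if header else None, float_precision="round_trip"
    )
    x = df.to_numpy()
    if x.dtype == object or not np.issubdtype(x.dtype, np.number):
        raise ValueError(f"{path}: non-numeric cells")
    if np.isnan(x).any():
        raise ValueError(f"{path}: missing or ragged values")
    if x.shape[0] < 3:
        raise ValueError(f"{path}: need at least 3 time steps")
    return x.astype(float)


def write_series(x: np.ndarray, path, names=None) -> None:
    """Write a T x N matrix as CSV with a header row, full float precision."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[0] == 1:
        x = x.T
    if names is None:
        names = [f"series_{n + 1}" for n in range(x.shape[1])]
    np.savetxt(path, x, delimiter=",", header=",".join(names), comments="", fmt="%.17g")


def write_results(table: ResultsTable, path) -> None:
    """Write records to ``<path>.csv`` and the summary to ``<path>.json``."""
    base = Path(path)
    table.records.to_csv(base.with_suffix(".csv"), index=False)
    with open(base.with_suffix(".json"), "w") as fh:
        json.dump(table.summary, fh, indent=2, default=float)
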