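"""Baseline multiple-CP detector: CUSUM with standard binary segmentation.

A single-CP bootstrap test runs on the full series; upon detection the
series is split at the estimated CP and the test recurses on both halves.
Each partition depletes the sample, which is the baseline's structural
weakness relative to whole-series methods.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .bootstrap import BootstrapConfig, cusum_amoc_test
from .cusum import _as_matrix

__all__ = ["SegTreeNode", "binseg_detect"]


@dataclass(frozen=True)
class SegTreeNode:
    """One tested segment: bounds (1-based, inclusive, absolute), the CP
    detected inside it (absolute index) or None, and the recursion depth."""

    lo: int
    hi: int
    cp: int | None
    depth: int


def binseg_detect(
    x,
    cfg: BootstrapConfig,
    gamma: float = 0.0,
    max_depth: int = 1,
    min_len: int = 8,
    return_tree: bool = False,
):
    """Recursive CUSUM detection; returns sorted absolute CP locations.

    Recursion stops on a non-significant test, at ``max_depth``, or on
    segments shorter than ``min_len`` (bootstrap tests on a handful of
    points are meaningless).  Within-segment tests use the block size in
    ``cfg`` (k = 1 for the independent-noise setting this baseline targets).
    Change points follow the usual convention: the mean shifts after ``c``.
    """
    x = _as_matrix(x)
    if x.shape[1] != 1:
        raise ValueError("binseg_detect expects a univariate series")
    if min_len < 4:
        raise ValueError("min_len must be >= 4")
    xf = x[:, 0]
    T = xf.size
    rng = cfg.rng()
    cps: list[int] = []
    tree: list[SegTreeNode] = []

    def recurse(lo: int, hi: int, depth: int) -> None:
        # lo, hi are 1-based inclusive absolute bounds
        if hi - lo + 1 < min_len:
            return
        seg = xf[lo - 1 : hi]
        if np.ptp(seg) == 0.0:  # constant segment: no CP by definition
            tree.append(SegTreeNode(lo, hi, None, depth))
            return
        # independent permutation stream per segment, deterministic overall
        seg_cfg = BootstrapConfig(
            n_boot=cfg.n_boot,
            block_size=cfg.block_size,
            alpha=cfg.alpha,
            seed=rng.integers(2**31),
        )
        det = cusum_amoc_test(seg, seg_cfg, gamma)
        if not det.candidates[0].accepted:
            tree.append(SegTreeNode(lo, hi, None, depth))
            return
        c_abs = lo - 1 + det.candidates[0].location
        cps.append(c_abs)
        tree.append(SegTreeNode(lo, hi, c_abs, depth))
        if depth < max_depth:
            recurse(lo, c_abs, depth + 1)
            recurse(c_abs + 1, hi, depth + 1)

    recurse(1, T, 0)
    cps.sort()
    if return_tree:
        return cps, tree
    return cps
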