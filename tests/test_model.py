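"""PARCS model: fixed-knot OLS, forward selection, pruning, ranking,
and inversion to step-model estimates."""

import numpy as np
import pytest

from parcs.cusum import cusum_transform
from parcs.model import (
    Parcs,
    fit_fixed_knots,
    fit_parcs,
    forward_select,
    hinge_pair,
    prune,
    rank_knots,
)
from parcs.simulate import StepModelSpec, mean_profile, simulate


def oracle_mse(x, knots):
    """Independent oracle: generic lstsq on the explicitly built design."""
    x = np.asarray(x, dtype=float)
    T = x.size
    y = np.cumsum(x - x.mean())
    cols = [np.ones(T)]
    for c in knots:
        hp, hm = hinge_pair(T, c)
        cols.extend([hp, hm])
    X = np.column_stack(cols)
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(r @ r) / T


class TestHingePair:
    def test_disjoint_supports(self):
        hp, hm = hinge_pair(10, 5)
        assert np.all(hp * hm == 0.0)
        t = np.arange(1, 11)
        assert np.allclose(hp + hm, np.abs(t - 5))


class TestFixedKnots:
    def test_intercept_only(self, rng):
        x = rng.normal(size=40)
        res = prune(fit_fixed_knots(cusum_transform(x), (10,)), 0)
        y = cusum_transform(x).y[:, 0]
        assert res.intercept[0] == pytest.approx(y.mean())
        assert res.mse == pytest.approx(np.var(y))

    def test_noiseless_exact_fit(self, noiseless_single_step):
        curve = cusum_transform(noiseless_single_step)
        res = fit_fixed_knots(curve, (20,))
        assert res.mse < 1e-10

    def test_nested_mse_monotone(self, rng):
        # adding a knot to any model never increases mse
        x = rng.normal(size=50)
        curve = cusum_transform(x)
        base = fit_fixed_knots(curve, (10, 30))
        for extra in (5, 20, 44):
            grown = fit_fixed_knots(curve, (10, 30, extra))
            assert grown.mse <= base.mse + 1e-12

    def test_matches_lstsq_oracle(self, rng):
        x = rng.normal(size=45)
        for knots in [(7,), (7, 22), (5, 18, 33)]:
            res = fit_fixed_knots(cusum_transform(x), knots)
            assert res.mse == pytest.approx(oracle_mse(x, knots), abs=1e-9)

    def test_rejects_duplicates_and_range(self, rng):
        curve = cusum_transform(rng.normal(size=30))
        with pytest.raises(ValueError):
            fit_fixed_knots(curve, (10, 10))
        with pytest.raises(ValueError):
            fit_fixed_knots(curve, (1,))
        with pytest.raises(ValueError):
            fit_fixed_knots(curve, (30,))


class TestForwardSelect:
    def test_first_knot_equals_exhaustive_oracle(self, rng):
        # greedy first step == brute-force single-knot least squares
        for _ in range(10):
            x = rng.normal(size=rng.integers(20, 61))
            best = min(range(2, x.size), key=lambda c: oracle_mse(x, (c,)))
            res = forward_select(cusum_transform(x), 1)
            assert res.knots[0] == best

    def test_each_greedy_step_matches_conditional_oracle(self, noiseless_two_step):
        # the forward stage is greedy: each added knot is the conditional
        # exhaustive optimum given the knots already in the model (on the
        # two-bend curve the first greedy knot is a compromise between the
        # true CPs; pruning from a larger bound recovers the exact pair)
        x = noiseless_two_step
        res = forward_select(cusum_transform(x), 2)
        first = min(range(2, x.size), key=lambda c: oracle_mse(x, (c,)))
        assert res.knots[0] == first
        second = min(
            (c for c in range(2, x.size) if c != first),
            key=lambda c: oracle_mse(x, (first, c)),
        )
        assert res.knots[1] == second

    def test_mse_nonincreasing_over_iterations(self, rng):
        x = rng.normal(size=60)
        curve = cusum_transform(x)
        mses = [forward_select(curve, L).mse for L in (1, 2, 3, 4)]
        assert all(a >= b - 1e-12 for a, b in zip(mses, mses[1:]))

    def test_degenerate_constant_curve_flagged(self):
        res = forward_select(cusum_transform([1.0] * 20), 1)
        assert res.degenerate
        assert res.mse == pytest.approx(0.0)

    def test_l_too_large(self):
        with pytest.raises(ValueError):
            forward_select(cusum_transform(list(range(9))), 5)


class TestPruneAndRank:
    def test_prune_identity_at_same_order(self, rng):
        x = rng.normal(size=50)
        res = forward_select(cusum_transform(x), 3)
        assert prune(res, 3).knots == res.knots

    def test_prune_recovers_true_pair(self, noiseless_two_step):
        res = forward_select(cusum_transform(noiseless_two_step), 6)
        assert set(prune(res, 2).knots) == {20, 60}

    def test_prune_rejects_larger_order(self, rng):
        res = forward_select(cusum_transform(rng.normal(size=40)), 2)
        with pytest.raises(ValueError):
            prune(res, 3)

    def test_rank_orders_by_explained_variance(self, noiseless_two_step):
        # w = (1, 2): the larger step at 60 explains more variance
        res = rank_knots(prune(forward_select(cusum_transform(noiseless_two_step), 6), 2))
        assert res.knots == (60, 20)

    def test_rank_is_permutation_only(self, rng):
        x = rng.normal(size=60)
        res = prune(forward_select(cusum_transform(x), 4), 3)
        ranked = rank_knots(res)
        assert sorted(ranked.knots) == sorted(res.knots)
        assert ranked.ranked


class TestFitParcs:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_noiseless_exact_recovery(self, seed):
        # sigma -> 0 with well-separated CPs and distinct weights: exact CP set
        # and step weights within 1e-8
        r = np.random.default_rng(seed)
        T = 100
        cps = tuple(sorted(r.choice(np.arange(10, 91, 8), size=2, replace=False)))
        w = r.choice([-2.0, -1.0, 1.5, 2.5], size=2, replace=False)
        spec = StepModelSpec(T=T, cps=cps, weights=tuple((v,) for v in w))
        x = mean_profile(spec)[:, 0]
        res = fit_parcs(x, M=2, L=6)
        assert set(res.knots) == set(cps)
        st = res.step_estimates()
        got = {c: st.weights[i, 0] for i, c in enumerate(res.knots)}
        for c, v in zip(cps, w):
            assert got[c] == pytest.approx(v, abs=1e-8)
        assert st.baseline[0] == pytest.approx(0.0, abs=1e-8)

    def test_univariate_equals_single_column_multivariate(self, rng):
        x = rng.normal(size=80)
        a = fit_parcs(x, M=2)
        b = fit_parcs(x[:, None], M=2)
        assert a.knots == b.knots
        assert a.mse == pytest.approx(b.mse)

    def test_order_one_equals_exhaustive_single_knot(self, rng):
        for _ in range(5):
            x = rng.normal(size=50)
            best = min(range(2, x.size), key=lambda c: oracle_mse(x, (c,)))
            assert fit_parcs(x, M=1, L=1).knots == (best,)

    def test_from_dataframe(self, rng):
        import pandas as pd

        df = pd.DataFrame(rng.normal(size=(50, 2)), columns=["a", "b"])
        res = Parcs.from_dataframe(df, order=1).fit()
        assert res.nseries == 2

    def test_summary_mentions_knots(self, noiseless_two_step):
        res = fit_parcs(noiseless_two_step, M=2, L=6)
        text = res.summary()
        assert "60" in text and "20" in text and "MSE" in text


class TestStepInversion:
    def test_null_model_reconstruction(self, rng):
        x = rng.normal(size=40) + 3.0
        res = Parcs(x, order=0).fit()
        st = res.step_estimates()
        assert np.allclose(st.mean_curve, x.mean())

    def test_pure_trend_has_zero_bend(self):
        # beta+ = -beta- at a knot on a perfectly linear curve: no step
        from parcs.cusum import CusumCurve

        t = np.arange(1, 101, dtype=float)
        curve = CusumCurve(y=(2.0 * t - 7.0)[:, None], x_mean=np.zeros(1))
        res = fit_fixed_knots(curve, (50,))
        assert res.mse < 1e-16
        assert res.coef_plus[0, 0] == pytest.approx(-res.coef_minus[0, 0], abs=1e-8)
        assert res.bending_statistic(0) == pytest.approx(0.0, abs=1e-8)

    def test_multivariate_weights_per_series(self):
        spec = StepModelSpec(
            T=100, baseline=(0.0, 1.0), cps=(30,), weights=((2.0, -1.0),)
        )
        x = mean_profile(spec)
        res = fit_parcs(x, M=1, L=3)
        st = res.step_estimates()
        assert res.knots == (30,)
        assert st.weights[0] == pytest.approx([2.0, -1.0], abs=1e-8)
        assert st.baseline == pytest.approx([0.0, 1.0], abs=1e-8)
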