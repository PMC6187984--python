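"""Generative model: step means, MA/Poisson noise, evaluation metrics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from parcs.metrics import accuracy_score, center_bias, error_rates
from parcs.simulate import (
    StepModelSpec,
    mean_profile,
    simulate,
    simulate_poisson_counts,
    simulate_step_series,
    sqrt_transform,
)


class TestStepModelSpec:
    def test_rejects_nonincreasing_cps(self):
        with pytest.raises(ValueError, match="increasing"):
            StepModelSpec(T=100, cps=(60, 20), weights=((1.0,), (2.0,)))

    def test_rejects_boundary_cps(self):
        with pytest.raises(ValueError):
            StepModelSpec(T=100, cps=(1,), weights=((1.0,),))
        with pytest.raises(ValueError):
            StepModelSpec(T=100, cps=(100,), weights=((1.0,),))

    def test_rejects_nonpositive_sigma(self):
        with pytest.raises(ValueError, match="sigma"):
            StepModelSpec(T=100, sigma=0.0)

    def test_rejects_negative_poisson_rate(self):
        with pytest.raises(ValueError, match="rate"):
            StepModelSpec(
                T=100, baseline=(1.0,), cps=(20,), weights=((-2.0,),),
                noise_kind="poisson",
            )

    def test_rejects_weight_shape_mismatch(self):
        with pytest.raises(ValueError):
            StepModelSpec(T=100, cps=(20, 60), weights=((1.0,),))

    def test_kappa0_is_implicit(self):
        # kappas holds kappa_1..kappa_q only; the contract makes kappa_0 = 1
        spec = StepModelSpec(T=100, kappas=(0.3,))
        assert spec.order == 1


class TestStepSeries:
    def test_noiseless_heaviside(self):
        # step effective from t = c+1
        spec = StepModelSpec(T=100, cps=(20,), weights=((1.0,),))
        prof = mean_profile(spec)[:, 0]
        assert np.all(prof[:20] == 0.0)
        assert np.all(prof[20:] == 1.0)

    def test_deterministic_given_seed(self):
        spec = StepModelSpec(T=50, cps=(10,), weights=((1.0,),), sigma=0.5, seed=3)
        a, b = simulate_step_series(spec), simulate_step_series(spec)
        assert a.tobytes() == b.tobytes()

    def test_multivariate_segment_means(self, rng):
        # nine-covariate white-noise setting: per-segment column means match
        # the deterministic profile within Monte-Carlo error
        spec = StepModelSpec(
            T=100,
            baseline=(0, 0, 0, 2, 2, 2, 0, 1, 2),
            cps=(20, 60),
            weights=((1, 2, 2, -2, 0, 0, 0, 0, 0), (2, 1, -1, 0, 1, -1, 0, 0, 0)),
            sigma=1.0,
        )
        reps = np.mean(
            [simulate_step_series(spec, rng) for _ in range(300)], axis=0
        )
        prof = mean_profile(spec)
        for lo, hi in ((0, 20), (20, 60), (60, 100)):
            seg_err = np.abs(reps[lo:hi].mean(axis=0) - prof[lo:hi].mean(axis=0))
            assert np.all(seg_err < 5 / np.sqrt(300 * (hi - lo)))

    def test_ma_noise_variance(self, rng):
        # Var = sigma^2 (1 + k1^2 + k2^2) for an MA(2) process
        sigma = 0.7
        spec = StepModelSpec(
            T=100_000, sigma=sigma, kappas=(-0.5 / sigma, 0.4 / sigma)
        )
        x = simulate_step_series(spec, rng)[:, 0]
        expect = sigma**2 * (1 + (0.5 / sigma) ** 2 + (0.4 / sigma) ** 2)
        assert np.var(x) == pytest.approx(expect, rel=0.03)

    def test_ma_autocovariance_structure(self, rng):
        # acov(tau) = sigma^2 sum_j k_j k_{j+tau}, cutting off after q
        sigma, k1, k2 = 1.0, -0.5, 0.4
        spec = StepModelSpec(T=100_000, sigma=sigma, kappas=(k1, k2))
        x = simulate_step_series(spec, rng)[:, 0]
        d = x - x.mean()
        T = x.size
        se = 3 / np.sqrt(T)
        expect = {
            1: k1 + k1 * k2,
            2: k2,
            3: 0.0,
        }
        for tau, ac in expect.items():
            got = (d[:-tau] @ d[tau:]) / T
            assert got == pytest.approx(ac * sigma**2, abs=4 * se)


class TestPoisson:
    def test_constant_rate_moments(self, rng):
        spec = StepModelSpec(T=50_000, baseline=(1.0,), noise_kind="poisson")
        x = simulate_poisson_counts(spec, rng)[:, 0]
        assert x.mean() == pytest.approx(1.0, abs=0.05)
        assert x.var() == pytest.approx(1.0, abs=0.05)
        assert np.all(x == np.round(x))

    def test_zero_rate_segment(self, rng):
        spec = StepModelSpec(
            T=100, baseline=(1.0,), cps=(50,), weights=((-1.0,),),
            noise_kind="poisson",
        )
        x = simulate_poisson_counts(spec, rng)[:, 0]
        assert np.all(x[50:] == 0.0)

    def test_segment_rate_profile(self, rng):
        spec = StepModelSpec(
            T=100,
            baseline=(1, 1, 1, 3, 3, 3, 1, 2, 1),
            cps=(20, 60),
            weights=((1, 2, 2, -2, 0, 0, 0, 0, 0), (2, 1, -1, 0, 1, -1, 0, 0, 0)),
            noise_kind="poisson",
        )
        reps = np.mean([simulate_poisson_counts(spec, rng) for _ in range(300)], axis=0)
        assert np.abs(reps - mean_profile(spec)).max() < 0.5


class TestSqrtTransform:
    def test_elementwise(self):
        assert sqrt_transform(np.array([0.0, 4.0])).tolist() == [0.0, 2.0]

    def test_rejects_negative(self):
        with pytest.raises(ValueError):
            sqrt_transform(np.array([-1.0]))

    def test_variance_stabilisation(self, rng):
        # delta method: Var(sqrt(Poisson(lam))) -> 1/4, roughly rate-free,
        # while the raw variance grows linearly in the rate
        variances = [
            np.var(np.sqrt(rng.poisson(lam, size=200_000)))
            for lam in (4.0, 9.0, 16.0, 25.0)
        ]
        assert max(variances) / min(variances) < 1.3  # vs 6x on the raw scale
        assert all(0.2 < v < 0.32 for v in variances)
        assert variances[-1] == pytest.approx(0.25, abs=0.02)


class TestCenterBias:
    @pytest.mark.parametrize(
        "c,chat,expect", [(20, 24, 4.0), (80, 76, 4.0), (60, 64, -4.0), (20, 16, -4.0)]
    )
    def test_direct_formula(self, c, chat, expect):
        assert center_bias(c, chat, 100) == expect

    @given(c=st.integers(2, 99), chat=st.integers(1, 99))
    @settings(max_examples=200, deadline=None)
    def test_invariant_under_reflection(self, c, chat):
        # reflecting both points about the midpoint maps center-side
        # displacements to center-side displacements: cb is unchanged
        # (both the sign factor and the difference flip).  At exactly
        # c = T/2 the Heaviside convention breaks the symmetry of the sign
        # factor, and cb flips instead.
        T = 100
        if c == T // 2:
            assert center_bias(T - c, T - chat, T) == -center_bias(c, chat, T)
        else:
            assert center_bias(T - c, T - chat, T) == center_bias(c, chat, T)


class TestAccuracyScore:
    def test_all_hits_no_type1(self):
        dets = [[20]] * 10
        assert accuracy_score(dets, c=20, T=100, M=3, alpha_hat=0.0) == 100.0

    def test_no_detections(self):
        assert accuracy_score([[]] * 10, c=20, T=100, M=3, alpha_hat=0.0) == 0.0

    def test_alpha_adjustment(self):
        dets = [[22]] * 4 + [[40]] * 6  # 40 is outside the +-5 window
        score = accuracy_score(dets, c=20, T=100, M=2, alpha_hat=60.0)
        assert score == pytest.approx(40.0 - 30.0)

    def test_window_is_inclusive(self):
        assert accuracy_score([[25]], c=20, T=100, M=1, alpha_hat=0.0) == 100.0
        assert accuracy_score([[26]], c=20, T=100, M=1, alpha_hat=0.0) == 0.0

    def test_rejects_zero_order(self):
        with pytest.raises(ValueError):
            accuracy_score([[20]], c=20, T=100, M=0, alpha_hat=0.0)


class TestErrorRates:
    def test_counting_rule(self):
        # realization 1: perfect; 2: spurious far CP (type I); 3: missed CP (type II)
        dets = [[20, 60], [20, 60, 40], [20]]
        t1, t2 = error_rates(dets, (20, 60), 100)
        assert t1 == pytest.approx(100 / 3)
        assert t2 == pytest.approx(100 / 3)
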