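import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cueint.circstats import wrap_angle
from cueint.models import (
    MODEL_NAMES,
    CueBelief,
    ModelConfig,
    Weights,
    integrate,
    integrate_bvs,
    integrate_nvs,
    integrate_wam,
    integrate_wta,
    integrate_wvs,
    normalized_weights,
    sigmoid_adjust,
)

from conftest import polar_vector_sum_angle


def beliefs(theta_wind_deg, theta_light_deg, k_wind, k_light):
    return (
        CueBelief(theta=math.radians(theta_wind_deg), kappa=k_wind),
        CueBelief(theta=math.radians(theta_light_deg), kappa=k_light),
    )


class TestNormalizedWeights:
    def test_symmetry(self):
        w = normalized_weights(2.0, 2.0)
        assert (w.w_wind, w.w_light) == (0.5, 0.5)

    def test_fig_caption_kappas(self):
        w = normalized_weights(2.05, 2.0)
        assert w.w_wind == pytest.approx(2.05 / 4.05, rel=1e-12)
        assert w.w_wind == pytest.approx(0.50617, abs=1e-5)
        assert w.w_light == pytest.approx(0.49383, abs=1e-5)

    def test_single_cue_limit(self):
        w = normalized_weights(3.0, 0.0)
        assert (w.w_wind, w.w_light) == (1.0, 0.0)

    def test_degenerate(self):
        with pytest.raises(ValueError):
            normalized_weights(0.0, 0.0)

    @given(st.floats(0.01, 50), st.floats(0.01, 50))
    def test_sums_to_one(self, kw, kl):
        w = normalized_weights(kw, kl)
        assert w.w_wind + w.w_light == pytest.approx(1.0, abs=1e-12)


class TestSigmoidAdjust:
    def test_midpoint(self):
        assert sigmoid_adjust(0.5, 53.0) == 0.5

    def test_printed_steepness(self):
        assert sigmoid_adjust(0.6, 53.0) == pytest.approx(1 / (1 + math.exp(-5.3)))
        assert sigmoid_adjust(0.6, 53.0) == pytest.approx(0.99503, abs=1e-5)

    @given(st.floats(-1.0, 2.0), st.floats(0.1, 200.0))
    def test_complement_symmetry(self, x, a):
        assert sigmoid_adjust(x, a) + sigmoid_adjust(1 - x, a) == pytest.approx(
            1.0, abs=1e-9
        )

    def test_open_unit_interval_and_increasing(self):
        # strict bounds hold over the weight domain [0, 1] (far outside it
        # the float value saturates at 0/1, which is fine for BVS shifts)
        xs = np.linspace(0, 1, 101)
        g = sigmoid_adjust(xs, 53.0)
        assert np.all(g > 0) and np.all(g < 1)
        assert np.all(np.diff(g) > 0)

    def test_invalid_steepness(self):
        with pytest.raises(ValueError):
            sigmoid_adjust(0.5, 0.0)


class TestWTA:
    def test_wind_wins(self):
        wind, light = beliefs(30.0, -50.0, 3.0, 2.0)
        assert integrate_wta(wind, light) == wind.theta

    def test_light_wins(self):
        wind, light = beliefs(30.0, -50.0, 1.0, 2.0)
        assert integrate_wta(wind, light) == light.theta

    def test_tie_broken_fairly(self):
        rng = np.random.default_rng(3)
        wind = CueBelief(theta=np.zeros(10_000), kappa=2.0)
        light = CueBelief(theta=np.full(10_000, 1.0), kappa=2.0)
        out = integrate_wta(wind, light, rng=rng)
        frac_wind = np.mean(out == 0.0)
        assert frac_wind == pytest.approx(0.5, abs=0.02)

    def test_tie_without_rng_raises(self):
        wind, light = beliefs(0.0, 90.0, 2.0, 2.0)
        with pytest.raises(ValueError):
            integrate_wta(wind, light)


class TestWAM:
    def test_equal_weights_bisector(self):
        wind, light = beliefs(0.0, 120.0, 1.0, 1.0)
        assert integrate_wam(wind, light) == pytest.approx(math.radians(60))

    def test_zero_360_pathology(self):
        # the raw average of 0 and a full turn is half a turn
        wind = CueBelief(theta=0.0, kappa=1.0)
        light = CueBelief(theta=2 * math.pi, kappa=1.0)
        assert integrate_wam(wind, light) == pytest.approx(math.pi)

    def test_two_thirds_weighting(self):
        wind, light = beliefs(0.0, 90.0, 2.0, 1.0)
        assert integrate_wam(wind, light) == pytest.approx(math.radians(30))

    def test_frame_dependence_documented(self):
        # WAM is deliberately not rotation-equivariant: rotating inputs that
        # wrap across the discontinuity changes the answer
        wind, light = beliefs(170.0, -170.0, 1.0, 1.0)
        out = integrate_wam(wind, light)  # raw average of 170 and -170 is 0
        assert out == pytest.approx(0.0, abs=1e-12)


class TestWVS:
    def test_equal_weight_bisector(self):
        wind, light = beliefs(0.0, 120.0, 2.0, 2.0)
        assert integrate_wvs(wind, light) == pytest.approx(math.radians(60))

    def test_dominance_limit(self):
        wind, light = beliefs(40.0, -10.0, 2.0, 2.0)
        out = integrate_wvs(wind, light, weights=Weights(1.0, 1e-12))
        assert wrap_angle(out - wind.theta) == pytest.approx(0.0, abs=1e-9)

    def test_degenerate_zero_light_weight(self):
        wind, light = beliefs(40.0, -10.0, 2.0, 2.0)
        out = integrate_wvs(wind, light, weights=Weights(1.0, 0.0))
        assert out == pytest.approx(wind.theta)

    def test_printed_example(self):
        # theta_light=0, theta_wind=120 deg, kappas (wind 2.05, light 2)
        wind, light = beliefs(120.0, 0.0, 2.05, 2.0)
        assert math.degrees(integrate_wvs(wind, light)) == pytest.approx(
            61.22, abs=0.01
        )

    @given(
        st.floats(-math.pi, math.pi),
        st.floats(-math.pi, math.pi),
        st.floats(0.05, 20),
        st.floats(0.05, 20),
    )
    @settings(max_examples=200)
    def test_equals_polar_vector_sum(self, tw, tl, kw, kl):
        """Independent oracle: angle of the sum of the two polar vectors."""
        wind = CueBelief(theta=tw, kappa=kw)
        light = CueBelief(theta=tl, kappa=kl)
        w = normalized_weights(kw, kl)
        expected = polar_vector_sum_angle([tw, tl], [w.w_wind, w.w_light])
        got = integrate_wvs(wind, light)
        assert abs(wrap_angle(got - expected)) < 1e-9

    def test_180_separation_equal_weights_perpendicular_limit(self):
        # at exactly opposite cues with equal weights the vector sum is
        # unstable; float pi lands on the symmetric perpendicular limit
        wind, light = beliefs(0.0, 180.0, 2.0, 2.0)
        out = integrate_wvs(wind, light)
        assert abs(out) == pytest.approx(math.pi / 2)

    def test_degenerate_weights_return_theta_wind(self):
        # zero light weight (and even both weights zero) falls back to the
        # vector-sum limit: theta_wind with a zero offset
        from cueint.models import _vector_sum_heading

        assert _vector_sum_heading(0.3, 1.1, 1.0, 0.0) == pytest.approx(0.3)
        assert _vector_sum_heading(0.3, 1.1, 0.0, 0.0) == pytest.approx(0.3)


class TestNVS:
    def test_equal_kappas_match_wvs(self):
        wind, light = beliefs(10.0, 80.0, 2.0, 2.0)
        assert integrate_nvs(wind, light) == pytest.approx(
            integrate_wvs(wind, light)
        )

    def test_moderate_ratio_strong_dominance(self):
        # kappa ratio 1.2 at a=53: g pushes the weight ratio to ~11:1, i.e.
        # a ~5.1 degree residual pull at 90 degrees of separation; the
        # brute-force vector sum with the adjusted weights is the oracle
        wind, light = beliefs(0.0, 90.0, 2.4, 2.0)
        out = math.degrees(integrate_nvs(wind, light, a=53.0))
        w = normalized_weights(2.4, 2.0)
        gw, gl = sigmoid_adjust(w.w_wind, 53.0), sigmoid_adjust(w.w_light, 53.0)
        assert gw / gl == pytest.approx(11.12, abs=0.01)
        expected = polar_vector_sum_angle([0.0, math.pi / 2], [gw, gl])
        assert out == pytest.approx(math.degrees(expected), abs=1e-9)
        assert out == pytest.approx(5.137, abs=0.001)

    def test_larger_ratio_within_one_degree_of_dominant_cue(self):
        # kappa ratio 1.5 -> normalised weight 0.6 -> g ratio ~200:1
        wind, light = beliefs(0.0, 90.0, 3.0, 2.0)
        out = math.degrees(integrate_nvs(wind, light, a=53.0))
        assert abs(out) < 1.0

    def test_large_a_equals_wta(self):
        for tw, tl, kw, kl in [(0.3, -2.0, 2.2, 2.0), (1.0, 2.5, 1.0, 1.5)]:
            wind = CueBelief(theta=tw, kappa=kw)
            light = CueBelief(theta=tl, kappa=kl)
            nvs = integrate_nvs(wind, light, a=1e4)
            wta = integrate_wta(wind, light)
            assert abs(wrap_angle(nvs - wta)) < 1e-4

    def test_small_a_flattens_to_equal_weights(self):
        wind, light = beliefs(0.0, 90.0, 3.0, 2.0)
        out = integrate_nvs(wind, light, a=1e-6)
        assert out == pytest.approx(math.radians(45), abs=1e-4)


class TestBVS:
    def test_zero_bias_reduces_to_nvs(self):
        wind, light = beliefs(15.0, -60.0, 2.3, 2.0)
        assert integrate_bvs(wind, light, bias_b=0.0) == pytest.approx(
            integrate_nvs(wind, light)
        )

    def test_positive_bias_pulls_toward_light(self):
        wind, light = beliefs(0.0, 90.0, 2.0, 2.0)
        unbiased = integrate_bvs(wind, light, bias_b=0.0)
        biased = integrate_bvs(wind, light, bias_b=0.05)
        d_unbiased = abs(wrap_angle(unbiased - light.theta))
        d_biased = abs(wrap_angle(biased - light.theta))
        assert d_biased < d_unbiased

    def test_bias_reused_across_steps(self):
        # same bias value gives identical weighting on initial and conflict
        kw, kl = 2.0, 2.0
        b = 0.04
        initial = integrate_bvs(
            CueBelief(0.0, kw), CueBelief(0.0, kl), bias_b=b
        )
        conflict = integrate_bvs(
            CueBelief(math.radians(120), kw), CueBelief(0.0, kl), bias_b=b
        )
        # with noiseless inputs the change is fully determined by b
        again = integrate_bvs(
            CueBelief(math.radians(120), kw), CueBelief(0.0, kl), bias_b=b
        )
        assert conflict == again
        assert initial == pytest.approx(0.0)

    def test_shifted_weights_passed_unclamped(self):
        # a large bias drives the wind weight negative; g still maps it
        # into (0, 1) and the output stays finite and light-dominated
        wind, light = beliefs(0.0, 90.0, 2.0, 2.0)
        out = integrate_bvs(wind, light, a=53.0, bias_b=0.6)
        assert abs(wrap_angle(out - light.theta)) < math.radians(1.0)

    def test_vectorised_bias(self):
        wind = CueBelief(theta=np.zeros(3), kappa=2.0)
        light = CueBelief(theta=np.full(3, math.pi / 2), kappa=2.0)
        out = integrate_bvs(wind, light, bias_b=np.array([-0.05, 0.0, 0.05]))
        assert out[0] < out[1] < out[2]  # increasing pull toward light


class TestInvariants:
    @pytest.mark.parametrize("name", [m for m in MODEL_NAMES if m != "WAM"])
    def test_rotation_equivariance(self, name):
        rng = np.random.default_rng(8)
        for _ in range(50):
            tw, tl = rng.uniform(-math.pi, math.pi, 2)
            kw, kl = rng.uniform(0.2, 5.0, 2)
            delta = rng.uniform(-math.pi, math.pi)
            base = integrate(name, CueBelief(tw, kw), CueBelief(tl, kl), rng=rng)
            rotated = integrate(
                name,
                CueBelief(wrap_angle(tw + delta), kw),
                CueBelief(wrap_angle(tl + delta), kl),
                rng=rng,
            )
            assert abs(wrap_angle(rotated - (base + delta))) < 1e-9

    @pytest.mark.parametrize("name", MODEL_NAMES)
    def test_zero_conflict_returns_common_theta(self, name):
        rng = np.random.default_rng(9)
        theta = 0.7
        out = integrate(
            name, CueBelief(theta, 2.2), CueBelief(theta, 2.0), rng=rng
        )
        assert wrap_angle(out - theta) == pytest.approx(0.0, abs=1e-12)

    def test_wvs_resembles_wam_at_small_conflict(self):
        # equal weights, small separation: vector sum ~ bisector = WAM
        for delta_deg in (1.0, 5.0, 10.0):
            wind, light = beliefs(0.0, delta_deg, 2.0, 2.0)
            wvs = math.degrees(integrate_wvs(wind, light))
            wam = math.degrees(integrate_wam(wind, light))
            assert wvs == pytest.approx(wam, abs=1e-6)

    def test_wvs_approaches_wta_at_large_weight_ratio(self):
        wind, light = beliefs(0.0, 150.0, 20.0, 1.0)
        out = math.degrees(integrate_wvs(wind, light))
        assert abs(out) < 8.0  # close to the dominant (wind) cue


class TestModelConfig:
    def test_parameter_counts(self):
        expected = {"WTA": 0, "WAM": 0, "WVS": 0, "NVS": 1, "BVS": 2}
        for name, k in expected.items():
            assert ModelConfig(name).n_params == k

    def test_defaults(self):
        mc = ModelConfig("BVS")
        assert mc.a == 53.0
        assert mc.sigma_bias == pytest.approx(math.sqrt(0.000303))

    def test_unknown_name(self):
        with pytest.raises(ValueError):
            ModelConfig("XXX")

    def test_dispatch_unknown(self):
        with pytest.raises(ValueError):
            integrate("XXX", CueBelief(0, 1), CueBelief(0, 1))
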