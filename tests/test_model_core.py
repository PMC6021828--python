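"""Forward models, source transforms and their algebraic structure."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import moxquant as mq
from moxquant.lm import numeric_jacobian


def coeff_set(seed):
    """A random but valid coefficient set (for property checks)."""
    rng = np.random.default_rng(seed)
    return mq.ModelCoefficients(
        a=rng.uniform(-2, 80, (2, 2)),
        b=rng.uniform(-0.5, 0.5, (2, 2)),
        d=rng.uniform(-0.3, 0.3, 2),
        r=rng.uniform(0.2, 1.0, 2),
    )


class TestSourceTransforms:
    def test_zero_and_unit_fixed_points(self):
        r = np.array([0.6, 0.44])
        assert np.allclose(mq.sources_from_concentrations([0, 0], r), [0, 0])
        assert np.allclose(mq.sources_from_concentrations([1, 1], r), [1, 1])
        assert np.allclose(mq.concentrations_from_sources([0, 0], r), [0, 0])

    def test_power_law_matches_direct_arithmetic(self, ref):
        s = mq.sources_from_concentrations([20.0, 40.0], ref.r)
        assert np.allclose(s, [20.0**0.6, 40.0**0.44])
        assert np.allclose(s, [6.0342, 5.0688], atol=5e-4)
        back = mq.concentrations_from_sources(s, ref.r)
        assert np.allclose(back, [20.0, 40.0])

    @given(st.integers(0, 10_000))
    def test_round_trip_identity(self, seed):
        rng = np.random.default_rng(seed)
        c = rng.uniform(0, 40, (5, 2))
        r = rng.uniform(0.1, 1.4, 2)
        back = mq.concentrations_from_sources(mq.sources_from_concentrations(c, r), r)
        assert np.allclose(back, c, rtol=1e-12, atol=1e-12)

    def test_negative_inputs_rejected(self):
        r = np.array([0.6, 0.44])
        with pytest.raises(ValueError):
            mq.sources_from_concentrations([-1, 0], r)
        with pytest.raises(ValueError):
            mq.concentrations_from_sources([-0.1, 0], r)
        with pytest.raises(ValueError):
            mq.sources_from_concentrations([1, 1], [0.5, -0.5])


class TestForwardLQ:
    def test_clean_air_gives_unit_ratios(self, ref):
        assert np.allclose(mq.forward_lq([0.0, 0.0], ref), [1.0, 1.0])

    @given(st.integers(0, 500))
    def test_clean_air_unit_ratio_for_any_coefficients(self, seed):
        m = coeff_set(seed)
        assert np.allclose(mq.forward_lq([0.0, 0.0], m), [1.0, 1.0])

    def test_one_ppm_acetone_hand_arithmetic(self, ref):
        # c = (1, 0) ppm -> s = (1, 0): x1 = a11 + b11 + 1, x2 = a21 + b21 + 1
        s = mq.sources_from_concentrations([1.0, 0.0], ref.r)
        assert np.allclose(mq.forward_lq(s, ref), [81.15, 61.87])

    def test_batch_matches_single(self, ref, rng):
        s = rng.uniform(0, 6, (10, 2))
        batch = mq.forward_lq(s, ref)
        singles = np.array([mq.forward_lq(si, ref) for si in s])
        assert np.allclose(batch, singles)

    def test_exactly_quadratic_along_rays(self, ref, rng):
        # x(t*u) - 1 must be a polynomial of degree <= 2 in t: a cubic fit
        # through 4 points has a vanishing leading coefficient.
        u = rng.uniform(0.2, 1.0, 2)
        t = np.array([0.5, 1.0, 2.0, 3.0])
        vals = np.array([mq.forward_lq(ti * u, ref) for ti in t]) - 1.0
        for i in range(2):
            poly = np.polyfit(t, vals[:, i], 3)
            assert abs(poly[0]) < 1e-10 * max(1.0, np.abs(vals[:, i]).max())

    def test_degenerate_coefficients_reduce_to_linear(self, ref, rng):
        m_lin = mq.ModelCoefficients(a=ref.a, b=np.zeros((2, 2)), d=np.zeros(2), r=ref.r)
        s = rng.uniform(0, 5, (20, 2))
        assert np.allclose(mq.forward_lq(s, m_lin), s @ ref.a.T + 1.0)


class TestVariants:
    def test_linear_zero_concentration(self):
        v = mq.VariantCoefficients("linear", [2.0, 0.5, 1.5, 1.0, 0.6, 0.44])
        assert np.allclose(mq.forward_variant([0.0, 0.0], v), [1.0, 1.0])

    def test_bilinear_with_zero_interaction_is_linear(self, rng):
        p_lin = np.array([2.0, 0.5, 1.5, 1.0, 0.6, 0.44])
        v_lin = mq.VariantCoefficients("linear", p_lin)
        v_bil = mq.VariantCoefficients(
            "bilinear", [2.0, 0.5, 0.0, 1.5, 1.0, 0.0, 0.6, 0.44]
        )
        c = rng.uniform(0, 40, (30, 2))
        assert np.allclose(mq.forward_variant(c, v_lin), mq.forward_variant(c, v_bil))

    def test_lq_variant_equals_forward_lq(self, ref, rng):
        v = mq.VariantCoefficients.from_model_coefficients(ref)
        c = rng.uniform(0, 40, (100, 2))
        s = mq.sources_from_concentrations(c, ref.r)
        assert np.allclose(mq.forward_variant(c, v), mq.forward_lq(s, ref))

    def test_logarithmic_rejects_zero_concentration(self):
        v = mq.VariantCoefficients("logarithmic", [5, -0.2, -0.3, 0.01] * 2)
        with pytest.raises(ValueError, match="acetone|ethanol"):
            mq.forward_variant([0.0, 10.0], v)

    def test_parameter_count_enforced(self):
        with pytest.raises(ValueError):
            mq.VariantCoefficients("linear", [1.0, 2.0])


class TestJacobian:
    def test_origin_jacobian_is_linear_gain_matrix(self, ref):
        assert np.allclose(mq.jacobian_lq(np.zeros(2), ref), ref.a)

    def test_matches_central_finite_differences(self, ref, rng):
        for _ in range(50):
            s = rng.uniform(0.0, 6.0, 2)
            J = mq.jacobian_lq(s, ref)
            J_fd = numeric_jacobian(lambda ss: mq.forward_lq(ss, ref), s, rel_step=1e-6)
            assert np.allclose(J, J_fd, rtol=1e-6, atol=1e-6 * np.abs(J).max())

    def test_constant_when_model_is_linear(self, ref, rng):
        m_lin = mq.ModelCoefficients(a=ref.a, b=np.zeros((2, 2)), d=np.zeros(2), r=ref.r)
        J1 = mq.jacobian_lq(rng.uniform(0, 5, 2), m_lin)
        J2 = mq.jacobian_lq(rng.uniform(0, 5, 2), m_lin)
        assert np.allclose(J1, J2) and np.allclose(J1, ref.a)


class TestSerialization:
    def test_reference_fixture_exponents(self, ref):
        assert np.allclose(ref.r, [0.60, 0.44])
        assert np.allclose(ref.a, [[80.0, 0.32], [61.0, 1.47]])

    def test_json_round_trip(self, ref, tmp_path):
        path = tmp_path / "coeffs.json"
        ref.save(path)
        again = mq.ModelCoefficients.load(path)
        assert np.array_equal(again.to_params(), ref.to_params())

    def test_version_mismatch_rejected(self, ref, tmp_path):
        doc = ref.to_dict()
        doc["format_version"] = 99
        with pytest.raises(ValueError, match="version"):
            mq.ModelCoefficients.from_dict(doc)

    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            mq.ModelCoefficients(
                a=np.ones((2, 2)), b=np.ones((2, 2)), d=np.ones(2), r=[0.5, -0.1]
            )
        with pytest.raises(ValueError):
            mq.ObservationPair(np.array([1.0, -2.0]))
        with pytest.raises(ValueError):
            mq.GasSample(np.array([-1.0, 0.0]))
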