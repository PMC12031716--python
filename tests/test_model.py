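"""Event probabilities, learning operators, contraction constants, regimes."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from wyckoff import (
    EVENTS,
    ModelParams,
    ParameterError,
    SpecialCase,
    SpecialCaseTag,
    apply_operator,
    contraction_constants,
    event_probabilities,
    make_special_case,
    sample_params,
)

unit = st.floats(0.0, 1.0, allow_nan=False)
open_unit = st.floats(0.01, 0.99, allow_nan=False)
theta_vec = st.lists(open_unit, min_size=8, max_size=8)
lam_vec = st.lists(unit, min_size=8, max_size=8)


def params_from(theta, lam, u1, u2):
    return ModelParams(theta, lam, u1, u2)


class TestModelParams:
    def test_strict_theta_bounds_rejected(self):
        with pytest.raises(ParameterError, match="theta3"):
            ModelParams([0.5, 0.5, 1.0, 0.5, 0.5, 0.5, 0.5, 0.5], np.zeros(8), 0.5, 0.5)
        with pytest.raises(ParameterError, match="theta1"):
            ModelParams([0.0] + [0.5] * 7, np.zeros(8), 0.5, 0.5)

    def test_closed_lambda_and_u_bounds_accepted(self):
        p = ModelParams(np.full(8, 0.5), [0, 1, 0, 1, 0, 1, 0, 1], 0.0, 1.0)
        assert p.lam[1] == 1.0 and p.u1 == 0.0

    @pytest.mark.parametrize("bad", [{"u1": 1.5}, {"u2": -0.1}, {"lam": np.full(8, 1.01)}])
    def test_out_of_range_rejected_naming_field(self, bad):
        kwargs = dict(theta=np.full(8, 0.5), lam=np.zeros(8), u1=0.5, u2=0.5)
        kwargs.update(bad)
        with pytest.raises(ParameterError):
            ModelParams(**kwargs)

    def test_roundtrip_flat_mapping(self, general_params):
        d = general_params.to_dict()
        assert set(d) == {f"theta{k}" for k in range(1, 9)} | {
            f"lambda{k}" for k in range(1, 9)
        } | {"u1", "u2"}
        p2 = ModelParams.from_dict(d)
        np.testing.assert_array_equal(p2.theta, general_params.theta)
        np.testing.assert_array_equal(p2.lam, general_params.lam)

    def test_unknown_key_rejected_by_name(self, general_params):
        d = general_params.to_dict()
        d["theta9"] = 0.5
        with pytest.raises(ParameterError, match="theta9"):
            ModelParams.from_dict(d)


class TestEvents:
    def test_eight_events_bound_exactly(self):
        # (attention, choice, outcome) per the event table, E1..E8
        expected = [
            ("T", "A", "O1"), ("T", "A", "O2"), ("T", "B", "O1"), ("T", "B", "O2"),
            ("T~", "A", "O1"), ("T~", "A", "O2"), ("T~", "B", "O1"), ("T~", "B", "O2"),
        ]
        assert [(e.attention, e.choice, e.outcome) for e in EVENTS] == expected
        assert [e.index for e in EVENTS] == list(range(1, 9))
        assert [e.rewarded for e in EVENTS] == [True, False] * 4


class TestEventProbabilities:
    def test_attentive_extreme(self):
        p = event_probabilities(1.0, ModelParams.common(0.5, 0.5, u1=1.0, u2=0.0))
        np.testing.assert_allclose(p, [0.5, 0, 0, 0.5, 0, 0, 0, 0], atol=1e-15)

    def test_hand_evaluated_vector(self):
        p = event_probabilities(0.6, ModelParams.common(0.5, 0.5, u1=0.7, u2=0.4))
        np.testing.assert_allclose(
            p, [0.21, 0.09, 0.12, 0.18, 0.14, 0.06, 0.08, 0.12], atol=1e-15
        )

    @given(x=unit, u1=unit, u2=unit)
    def test_normalized_and_nonnegative(self, x, u1, u2):
        p = event_probabilities(x, ModelParams.common(0.5, 0.5, u1=u1, u2=u2))
        assert np.all(p >= 0)
        assert abs(p.sum() - 1.0) < 1e-12

    def test_dense_grid_normalization(self):
        xs = np.linspace(0, 1, 25)
        for u1 in np.linspace(0, 1, 9):
            for u2 in np.linspace(0, 1, 9):
                p = event_probabilities(xs, ModelParams.common(0.3, 0.2, u1=u1, u2=u2))
                np.testing.assert_allclose(p.sum(axis=-1), 1.0, atol=1e-12)

    def test_out_of_range_x_rejected(self, general_params):
        with pytest.raises(ParameterError, match="x"):
            event_probabilities(1.2, general_params)


class TestApplyOperator:
    def test_lambda_is_fixed_point(self, general_params):
        for k in range(1, 9):
            lam_k = general_params.lam[k - 1]
            assert apply_operator(k, lam_k, general_params) == pytest.approx(lam_k)

    def test_hand_evaluated(self):
        p = ModelParams([0.8] + [0.5] * 7, [0.25] + [0.0] * 7, 0.5, 0.5)
        assert apply_operator(1, 0.5, p) == pytest.approx(0.45)

    def test_reflex_elimination_scales_state(self):
        p = ModelParams.common(0.2, 0.0)
        for k in range(1, 9):
            assert apply_operator(k, 0.5, p) == pytest.approx(0.1)

    @given(theta=theta_vec, lam=lam_vec, x=unit)
    def test_maps_unit_interval_to_itself(self, theta, lam, x):
        p = ModelParams(theta, lam, 0.5, 0.5)
        for k in range(1, 9):
            assert 0.0 <= apply_operator(k, x, p) <= 1.0

    def test_invalid_index(self, general_params):
        with pytest.raises(IndexError):
            apply_operator(9, 0.5, general_params)


class TestContractionConstants:
    def test_collapse_theta02_lam0(self):
        d = contraction_constants(ModelParams.common(0.2, 0.0, u1=0.3, u2=0.9))
        assert d.K1 == pytest.approx(0.8, abs=1e-12)
        assert d.K3 == pytest.approx(0.8, abs=1e-12)
        assert d.contraction

    def test_collapse_theta02_lam05(self):
        d = contraction_constants(ModelParams.common(0.2, 0.5))
        assert d.K1 == pytest.approx(1.6, abs=1e-12)
        assert not d.contraction

    @given(theta=open_unit, lam=unit, u1=unit, u2=unit)
    def test_closed_forms_under_common_parameters(self, theta, lam, u1, u2):
        d = contraction_constants(ModelParams.common(theta, lam, u1=u1, u2=u2))
        assert d.K1 == pytest.approx(2 * (2 * theta + (1 - theta) * lam), abs=1e-12)
        assert d.K3 == pytest.approx(4 * theta, abs=1e-12)

    @given(theta=theta_vec, lam=lam_vec, u1=unit, u2=unit)
    def test_K3_is_K1_at_zero_lambda(self, theta, lam, u1, u2):
        p = ModelParams(theta, lam, u1, u2)
        p0 = ModelParams(theta, np.zeros(8), u1, u2)
        assert contraction_constants(p).K3 == pytest.approx(
            contraction_constants(p0).K1, abs=1e-12
        )

    def test_K4_exceeds_two_over_sweep(self, rng):
        for _ in range(10_000):
            p = sample_params(rng)
            assert contraction_constants(p).K4 > 2.0

    def test_K4_is_two_plus_K3(self, general_params):
        d = contraction_constants(general_params)
        assert d.K4 == pytest.approx(2.0 + d.K3, abs=1e-12)

    def test_K2_unavailable_for_unequal_lambdas(self, general_params):
        d = contraction_constants(general_params)
        assert d.K2 is None

    def test_K2_variants_differ_only_in_third_pair(self):
        theta = [0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8]
        p = ModelParams(theta, np.full(8, 0.4), u1=0.6, u2=0.9)
        as_printed = contraction_constants(p, "as_printed")
        corrected = contraction_constants(p, "typo_corrected")
        # third branch swaps theta3+theta3 for theta3+theta7
        lam, u2 = 0.4, 0.9
        delta = u2 * (1 - lam / 2) * (theta[6] - theta[2])
        assert corrected.K2 - as_printed.K2 == pytest.approx(delta, abs=1e-12)
        assert as_printed.k2_as_printed and not corrected.k2_as_printed
        # K2 hand value, as printed: sum_i w_i (lam + (1-lam/2)(pair_i))
        w = [0.6, 0.4, 0.9, 0.1]
        pairs = [theta[0] + theta[4], theta[1] + theta[5], theta[2] + theta[2], theta[3] + theta[7]]
        expect = sum(wi * (lam + (1 - lam / 2) * pr) for wi, pr in zip(w, pairs))
        assert as_printed.K2 == pytest.approx(expect, abs=1e-12)

    def test_unknown_variant_rejected(self, general_params):
        with pytest.raises(ValueError):
            contraction_constants(general_params, "other")


class TestSpecialCases:
    @pytest.mark.parametrize(
        "tag,expected",
        [(SpecialCaseTag.ALL_ZERO, 0.0), (SpecialCaseTag.ALL_ONE, 1.0)],
    )
    def test_absorption_regimes(self, general_params, tag, expected):
        p = make_special_case(general_params, SpecialCase(tag))
        np.testing.assert_array_equal(p.lam, np.full(8, expected))
        np.testing.assert_array_equal(p.theta, general_params.theta)

    def test_common_lambda(self, general_params):
        p = make_special_case(
            general_params, SpecialCase(SpecialCaseTag.COMMON_LAMBDA, 0.3)
        )
        np.testing.assert_array_equal(p.lam, np.full(8, 0.3))
        assert p.u1 == general_params.u1 and p.u2 == general_params.u2
        assert p.common_lambda

    def test_general_is_identity(self, general_params):
        assert make_special_case(general_params, SpecialCase(SpecialCaseTag.GENERAL)) is general_params

    def test_common_lambda_requires_value(self):
        with pytest.raises(ParameterError):
            SpecialCase(SpecialCaseTag.COMMON_LAMBDA)


class TestSampleParams:
    def test_deterministic_given_seed(self):
        a = sample_params(np.random.default_rng(7))
        b = sample_params(np.random.default_rng(7))
        np.testing.assert_array_equal(a.theta, b.theta)
        np.testing.assert_array_equal(a.lam, b.lam)
        assert (a.u1, a.u2) == (b.u1, b.u2)

    def test_contraction_postcondition(self, rng):
        for _ in range(5):
            p = sample_params(rng, require_contraction=True)
            assert contraction_constants(p).K1 < 1.0

    def test_all_draws_valid(self, rng):
        for _ in range(1000):
            p = sample_params(rng)
            assert np.all((p.theta > 0) & (p.theta < 1))
            assert np.all((p.lam >= 0) & (p.lam <= 1))
            assert 0 <= p.u1 <= 1 and 0 <= p.u2 <= 1

    def test_unattainable_contraction_raises_with_advice(self, rng):
        with pytest.raises(RuntimeError, match="theta_range"):
            sample_params(
                rng, require_contraction=True,
                theta_range=(0.9, 0.99), max_tries=2000,
            )
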