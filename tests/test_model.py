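"""Vector field, closed forms and derivative tensors of the mosaic model."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fgmosaic import ParameterSet
from fgmosaic.model import (
    derivatives,
    forest_only_rhs,
    human_feedback,
    jacobian,
    perceived_value,
    recruitment_rate,
    rhs,
)

from conftest import central_diff_jacobian


class TestRecruitment:
    @pytest.mark.parametrize(
        "f, kw, expected",
        [
            # hand evaluation: w(1/2) = 1/(1 + e^(b-k)) at f=1/2 since f/(1-f)=1
            (0.5, dict(k=10.03), 1.0 / (1.0 + np.exp(0.97))),
            (0.5, dict(k=11.0), 0.5),  # k=b: exponent vanishes, w = c/2
            (0.5, dict(k=11.0, c=0.4), 0.2),
            (0.0, dict(k=10.0), 1.0 / (1.0 + np.exp(11.0))),
        ],
    )
    def test_closed_form_values(self, f, kw, expected):
        assert recruitment_rate(f, ParameterSet(**kw)) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("f", [-0.1, 1.0, 1.5])
    def test_domain_error_names_value(self, f, defaults):
        with pytest.raises(ValueError, match=str(f)):
            recruitment_rate(f, defaults)

    def test_strictly_increasing_and_bounded(self, defaults):
        # strictly increasing wherever the logistic is not float-saturated,
        # non-decreasing and bounded by c everywhere
        fs = np.linspace(0.0, 1.0 - 1e-6, 2001)
        w = np.array([recruitment_rate(f, defaults) for f in fs])
        assert np.all(np.diff(w) >= 0)
        assert np.all(np.diff(w[fs < 0.8]) > 0)
        assert w[0] > 0 and np.all(w <= defaults.c)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(
        f=st.floats(0.0, 0.999),
        k=st.floats(0.1, 40.0),
        b=st.floats(0.0, 15.0),
    )
    def test_bounds_hold_for_generic_parameters(self, f, k, b):
        w = recruitment_rate(f, ParameterSet(k=k, b=b))
        assert 0.0 <= w <= 1.0


class TestPerceivedValueAndFeedback:
    def test_symmetric_default_is_linear(self, defaults):
        fs = np.linspace(0, 1, 21)
        for f in fs:
            assert perceived_value(f, defaults) == pytest.approx(1.0 - 2.0 * f, abs=1e-14)

    def test_general_shape(self):
        p = ParameterSet(r=1, q=1, m=2, n=1)
        assert perceived_value(0.25, p) == pytest.approx(0.75**2 - 0.25)

    @pytest.mark.parametrize("x, expected", [(0.5, 0.0), (1.0, -2.0), (0.722, 2 * (1 - 1.444))])
    def test_feedback_sign_convention(self, x, expected, defaults):
        # -J(x) > 0 (reforestation) exactly when the majority prefers forest
        assert human_feedback(x, defaults) == pytest.approx(expected)
        if x > 0.5:
            assert -human_feedback(x, defaults) > 0


class TestRhs:
    def test_bautin_coordinates_are_near_steady_state(self):
        # printed coordinates carry 3-4 significant figures
        p = ParameterSet(k=9.946, nu=1.906)
        assert np.linalg.norm(rhs(np.array([0.5, 0.722]), p)) < 5e-3

    @pytest.mark.parametrize("x0", [0.0, 1.0])
    def test_opinion_boundary_lines_are_invariant(self, x0, defaults):
        for f in (0.1, 0.5, 0.9):
            assert rhs(np.array([f, x0]), defaults)[1] == 0.0

    def test_symmetric_point_value(self, defaults):
        w_half = recruitment_rate(0.5, defaults)
        df, dx = rhs(np.array([0.5, 0.5]), defaults)
        assert dx == 0.0
        assert df == pytest.approx(w_half / 4.0 - defaults.nu / 2.0)

    def test_interior_opinion_equilibrium_only_at_half(self, defaults):
        # with defaults dx/dt = 0 at interior x iff f = 1/2 exactly
        assert rhs(np.array([0.5, 0.3]), defaults)[1] == 0.0
        assert rhs(np.array([0.499, 0.3]), defaults)[1] != 0.0


class TestForestOnly:
    def test_extinction_state(self, defaults):
        assert forest_only_rhs(0.0, defaults) == 0.0

    def test_uncoupled_limit_matches_full_model(self):
        p = ParameterSet(h=0.0, nu=0.7)
        for f in np.linspace(0.05, 0.95, 10):
            assert rhs(np.array([f, 0.3]), p)[0] == pytest.approx(forest_only_rhs(f, p), abs=1e-14)

    def test_hand_value_at_half(self):
        p = ParameterSet(k=11.0, nu=0.0)
        assert forest_only_rhs(0.5, p) == pytest.approx(1.0 / 8.0)


class TestDerivativeTensors:
    def test_jacobian_matches_finite_differences(self, defaults, rng):
        for _ in range(100):
            y = rng.uniform([0.05, 0.05], [0.9, 0.95])
            p = ParameterSet(k=rng.uniform(4, 16), nu=rng.uniform(0.1, 2.5))
            J = jacobian(y, p)
            J_fd = central_diff_jacobian(lambda z: rhs(z, p), y)
            assert np.allclose(J, J_fd, rtol=1e-5, atol=1e-7)

    def test_second_and_third_order_match_finite_differences(self, rng):
        p = ParameterSet(k=9.5, nu=1.5, r=1.2, q=1.2, m=3, n=2)
        for _ in range(10):
            y = rng.uniform([0.1, 0.1], [0.8, 0.9])
            bundle = derivatives(y, p)
            B_fd = central_diff_jacobian(lambda z: jacobian(z, p).ravel(), y, h=1e-5)
            assert np.allclose(bundle.second_order.reshape(4, 2), B_fd, rtol=2e-4, atol=1e-5)
            C_fd = central_diff_jacobian(
                lambda z: derivatives(z, p).second_order.ravel(), y, h=1e-5
            )
            assert np.allclose(bundle.third_order.reshape(8, 2), C_fd, rtol=2e-3, atol=1e-3)

    def test_tensors_match_symbolic_differentiation(self):
        """Independent oracle: sympy differentiation of the vector field."""
        import sympy as sp

        f, x = sp.symbols("f x")
        subs = {"b": 11, "c": 1, "k": 9.5, "nu": 1.5, "s": 10, "h": 2}
        w = subs["c"] / (1 + sp.exp(-subs["k"] * f / (1 - f) + subs["b"]))
        F = [
            w * f * (1 - f) - subs["nu"] * f - subs["h"] * (1 - 2 * x),
            subs["s"] * x * (1 - x) * (1 - 2 * f),
        ]
        p = ParameterSet(k=9.5, nu=1.5)
        point = {f: 0.47, x: 0.63}
        bundle = derivatives(np.array([0.47, 0.63]), p)
        for i, Fi in enumerate(F):
            for j, vj in enumerate((f, x)):
                ref = float(Fi.diff(vj).subs(point))
                assert bundle.jacobian[i, j] == pytest.approx(ref, rel=1e-10, abs=1e-12)
                for l, vl in enumerate((f, x)):
                    ref2 = float(Fi.diff(vj, vl).subs(point))
                    assert bundle.second_order[i, j, l] == pytest.approx(ref2, rel=1e-9, abs=1e-11)
                    for mth, vm in enumerate((f, x)):
                        ref3 = float(Fi.diff(vj, vl, vm).subs(point))
                        assert bundle.third_order[i, j, l, mth] == pytest.approx(
                            ref3, rel=1e-8, abs=1e-10
                        )

    def test_tensor_symmetry(self, defaults, rng):
        y = rng.uniform([0.2, 0.2], [0.8, 0.8])
        bundle = derivatives(y, defaults)
        B, C = bundle.second_order, bundle.third_order
        assert np.array_equal(B, B.transpose(0, 2, 1))
        for perm in [(0, 1, 3, 2), (0, 2, 1, 3), (0, 3, 2, 1)]:
            assert np.array_equal(C, C.transpose(*perm))

    def test_interior_jacobian_determinant_is_positive(self, defaults):
        # det = 4 h s x(1-x) > 0 at any f=1/2 equilibrium: never a saddle
        for x in (0.2, 0.5, 0.722):
            J = jacobian(np.array([0.5, x]), defaults)
            det = np.linalg.det(J)
            assert det == pytest.approx(4 * defaults.h * defaults.s * x * (1 - x), rel=1e-10)
            assert J[0, 1] == pytest.approx(2 * defaults.h)
            assert J[1, 1] == 0.0

    def test_bundle_contractions_accept_complex_vectors(self, defaults):
        bundle = derivatives(np.array([0.5, 0.7]), defaults)
        q = np.array([1.0 + 2.0j, -0.5j])
        assert bundle.B(q, np.conj(q)).shape == (2,)
        assert np.allclose(bundle.B(q, q), bundle.B(q, q))


class TestParameterSet:
    def test_rejects_unknown_keys(self):
        with pytest.raises(ValueError, match="unknown parameter"):
            ParameterSet.from_dict({"b": 11, "gamma": 1})

    def test_roundtrip_through_json(self, tmp_path, defaults):
        path = tmp_path / "params.json"
        import json

        path.write_text(json.dumps(defaults.to_dict()))
        assert ParameterSet.from_file(path) == defaults

    def test_roundtrip_through_yaml(self, tmp_path):
        path = tmp_path / "params.yaml"
        path.write_text("b: 4\nc: 1\nk: 3.2\nnu: 0.7\n")
        p = ParameterSet.from_file(path)
        assert (p.b, p.k) == (4.0, 3.2)

    @pytest.mark.parametrize("bad", [dict(c=-1), dict(k=0), dict(m=0.5), dict(nu=-0.1)])
    def test_invariant_violations_raise(self, bad):
        with pytest.raises(ValueError):
            ParameterSet(**bad)
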