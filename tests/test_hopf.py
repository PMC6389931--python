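"""Hopf detection, first Lyapunov coefficient and Bautin location.

Printed reference coordinates from the original analysis are matched at
0.6% relative tolerance (their reporting resolution); the exact analytic
invariants — locus membership, omega identity, criticality signs — are
asserted at 1e-6 or tighter.
"""

import numpy as np
import pytest

from fgmosaic import (
    ParameterSet,
    continue_branch,
    detect_hopf,
    find_bautin,
    first_lyapunov_coefficient,
    hopf_locus_nu,
    hopf_point_on_locus,
    interior_equilibrium,
)
from fgmosaic.hopf import hopf_from_equilibrium
from fgmosaic.normal_forms import bautin_normal_form, hopf_normal_form

REL = 6e-3  # reporting resolution of the printed reference coordinates


def k_sweep_hopf(p, nu, k_range=(5.0, 20.0)):
    eq = interior_equilibrium(p.with_(k=k_range[0], nu=nu))
    branch = continue_branch(eq, "k", k_range, step=0.05, max_step=0.15)
    return detect_hopf(branch)


class TestHopfLocus:
    @pytest.mark.parametrize("k, nu_expected", [(10.03, 2.00), (12.37, 2.00)])
    def test_printed_supercritical_pair_lies_at_nu_two(self, k, nu_expected, defaults):
        assert hopf_locus_nu(k, defaults) == pytest.approx(nu_expected, abs=5e-3)

    def test_peak_value_at_k_equals_b(self, defaults):
        # the exponential factor is 1/4 at k=b, so nu_H(b) = c*b/4
        assert hopf_locus_nu(defaults.b, defaults) == pytest.approx(defaults.c * defaults.b / 4)

    def test_rederived_locus_matches_eigenvalue_detection(self, defaults):
        """The closed form nu_H(k) must agree with Hopf points found from the
        eigenvalues of the numerically continued equilibrium branch."""
        for nu in (0.2, 0.9, 2.0):
            for hp in k_sweep_hopf(defaults, nu):
                assert hopf_locus_nu(hp.param_value, defaults) == pytest.approx(nu, abs=1e-6)

    def test_no_hopf_above_the_bell_peak(self, defaults):
        nu_max = hopf_locus_nu(defaults.b, defaults)
        assert k_sweep_hopf(defaults, nu_max + 0.1) == []


class TestHopfDetection:
    @pytest.mark.parametrize(
        "nu, k_pair, crits",
        [
            (0.2, (7.42, 15.31), ("subcritical", "subcritical")),
            (0.4, (8.09, 14.54), ("subcritical", "subcritical")),
            (1.4, (9.48, 12.96), ("subcritical", "subcritical")),
            (1.82, (9.82, 12.59), ("subcritical", "supercritical")),
            (2.0, (10.03, 12.37), ("supercritical", "supercritical")),
            (2.2, (10.22, 12.17), ("supercritical", "supercritical")),
        ],
    )
    def test_slices_match_reported_points_and_criticality(self, nu, k_pair, crits, defaults):
        hps = k_sweep_hopf(defaults, nu)
        assert len(hps) == 2
        for hp, k_ref, crit in zip(hps, k_pair, crits):
            assert hp.param_value == pytest.approx(k_ref, rel=REL)
            assert hp.criticality == crit

    def test_omega_identity(self, defaults):
        # at a Hopf point of the interior family omega = 2 sqrt(h s x*(1-x*))
        for hp in k_sweep_hopf(defaults, 1.0):
            x = hp.state[1]
            assert hp.omega == pytest.approx(
                2.0 * np.sqrt(defaults.h * defaults.s * x * (1 - x)), abs=1e-6
            )
            J = np.array([[0.0, 2 * defaults.h], [-2 * defaults.s * x * (1 - x), 0.0]])
            eigs = np.linalg.eigvals(J)
            assert sorted(np.abs(eigs.imag)) == pytest.approx([hp.omega, hp.omega], abs=1e-6)


class TestFirstLyapunovCoefficient:
    def test_supercritical_normal_form_sign(self):
        system, p = hopf_normal_form(mu=0.0, omega=1.0, cubic_sign=-1)
        l1 = first_lyapunov_coefficient(system.derivatives(np.zeros(2), p))
        assert l1 < 0

    def test_subcritical_normal_form_sign(self):
        system, p = hopf_normal_form(mu=0.0, omega=2.0, cubic_sign=+1)
        l1 = first_lyapunov_coefficient(system.derivatives(np.zeros(2), p))
        assert l1 > 0

    @pytest.mark.parametrize("k, sign", [(8.09, +1), (10.03, -1)])
    def test_model_criticality_signs(self, k, sign, defaults):
        hp = hopf_point_on_locus(k, defaults)
        assert np.sign(hp.l1) == sign

    def test_matches_guckenheimer_holmes_oracle(self):
        """Independent route: for a field already in rotation form
        (f_x = f_y(off) = ..., Jacobian [[0,-w],[w,0]]) the classic
        1/16-formula gives the criticality coefficient a; sign(l1) == sign(a).
        """
        rng = np.random.default_rng(7)
        for _ in range(20):
            w = rng.uniform(0.5, 3.0)
            c3 = rng.normal(size=8)  # cubic coefficients for both components

            def cubic(x, y):
                return np.array(
                    [
                        c3[0] * x**3 + c3[1] * x * x * y + c3[2] * x * y * y + c3[3] * y**3,
                        c3[4] * x**3 + c3[5] * x * x * y + c3[6] * x * y * y + c3[7] * y**3,
                    ]
                )

            # Guckenheimer-Holmes: 16a = fxxx + fxyy + gxxy + gyyy (+ quadratic
            # terms, absent here)
            a = (6 * c3[0] + 2 * c3[2] + 2 * c3[5] + 6 * c3[7]) / 16.0
            from fgmosaic.model import DerivativeBundle

            J = np.array([[0.0, -w], [w, 0.0]])
            C = np.zeros((2, 2, 2, 2))
            for i in range(2):
                base = c3[4 * i: 4 * i + 4]
                C[i, 0, 0, 0] = 6 * base[0]
                C[i, 0, 0, 1] = C[i, 0, 1, 0] = C[i, 1, 0, 0] = 2 * base[1]
                C[i, 0, 1, 1] = C[i, 1, 0, 1] = C[i, 1, 1, 0] = 2 * base[2]
                C[i, 1, 1, 1] = 6 * base[3]
            bundle = DerivativeBundle(
                value=np.zeros(2), jacobian=J, second_order=np.zeros((2, 2, 2)), third_order=C
            )
            l1 = first_lyapunov_coefficient(bundle)
            if abs(a) > 1e-12:
                assert np.sign(l1) == np.sign(a)

    def test_rejects_real_eigenvalues(self, defaults):
        from fgmosaic.model import derivatives

        bundle = derivatives(np.array([0.1, 0.9]), defaults)  # generic point, det < 0 or tr != 0
        with pytest.raises(ValueError):
            hopf_from_equilibrium(
                __import__("fgmosaic").mosaic_system(), np.array([0.1, 0.9]), defaults
            )


class TestBautin:
    @pytest.mark.parametrize(
        "kw, side, expected",
        [
            # (f, x, k, nu) reference coordinates
            (dict(), "low_k", (0.722, 9.946, 1.906)),
            (dict(), "high_k", (0.669, 12.59, 1.768)),
            (dict(c=0.4), "low_k", (0.588, 9.94, 0.76)),
            (dict(c=0.4), "high_k", (0.567, 12.592, 0.707)),
            (dict(b=4.0), "low_k", (0.569, 3.274, 0.719)),
            (dict(b=4.0), "high_k", (0.522, 6.024, 0.62)),
        ],
    )
    def test_bautin_points_match_reported_coordinates(self, kw, side, expected):
        gh = find_bautin(ParameterSet(**kw), side)
        assert gh is not None
        x_ref, k_ref, nu_ref = expected
        assert gh.f == 0.5
        assert gh.x == pytest.approx(x_ref, rel=REL)
        assert gh.k == pytest.approx(k_ref, rel=REL)
        assert gh.nu == pytest.approx(nu_ref, rel=REL)

    def test_point_sits_on_hopf_locus_with_vanishing_l1(self, defaults):
        gh = find_bautin(defaults, "low_k")
        assert gh.nu == pytest.approx(hopf_locus_nu(gh.k, defaults), abs=1e-10)
        assert abs(gh.l1_residual) < 1e-8

    def test_no_sign_change_reports_none(self, defaults):
        # l1 does not vanish between the peak and the low-k Bautin point
        assert find_bautin(defaults, "high_k", k_bracket=(13.5, 17.0)) is None

    def test_mixed_criticality_window(self, defaults):
        """Both Hopf points subcritical below the high-k Bautin nu, mixed
        between the two Bautin nu values, both supercritical above."""
        gh1 = find_bautin(defaults, "low_k")
        gh2 = find_bautin(defaults, "high_k")
        assert gh2.nu < gh1.nu
        crits = {nu: [hp.criticality for hp in k_sweep_hopf(defaults, nu)]
                 for nu in (1.5, 1.82, 2.0)}
        assert crits[1.5] == ["subcritical", "subcritical"]
        assert crits[1.82] == ["subcritical", "supercritical"]
        assert crits[2.0] == ["supercritical", "supercritical"]

    def test_bautin_normal_form_fixture_recovery(self):
        """l1 along the Hopf line beta1=0 changes sign at beta2=0, pinning the
        Bautin point at the origin of the (beta1, beta2) plane."""
        system, _ = bautin_normal_form()
        l1_of = {}
        for beta2 in (-0.3, 0.3):
            _, p = bautin_normal_form(beta1=0.0, beta2=beta2)
            hp = hopf_from_equilibrium(system, np.zeros(2), p)
            l1_of[beta2] = hp.l1
        assert l1_of[-0.3] < 0 < l1_of[0.3]
        from scipy.optimize import brentq

        def l1_at(beta2):
            _, p = bautin_normal_form(beta1=0.0, beta2=float(beta2))
            return hopf_from_equilibrium(system, np.zeros(2), p).l1

        root = brentq(l1_at, -0.3, 0.3, xtol=1e-12)
        assert abs(root) < 1e-10
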