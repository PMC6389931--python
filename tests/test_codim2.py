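"""Two-parameter structure: Hopf/LPC loci, Bautin organising centres, regimes."""

import numpy as np
import pytest

from fgmosaic import (
    ParameterSet,
    classify_regime,
    find_bautin,
    hopf_ks_at_nu,
    hopf_locus_nu,
    interior_equilibrium,
    search_cycles,
    trace_hopf_curve,
)
from fgmosaic.codim2 import trace_lpc_curve
from fgmosaic.cycles import continue_cycle_branch, detect_lpc, initial_cycle_from_hopf
from fgmosaic.hopf import hopf_from_equilibrium
from fgmosaic.systems import mosaic_system


@pytest.fixture(scope="module")
def bautins(defaults):
    return find_bautin(defaults, "low_k"), find_bautin(defaults, "high_k")


@pytest.fixture(scope="module")
def lpc_seeds(defaults):
    """Folds of the nu=0.2 cycle branches, used to seed the LPC loci."""
    system = mosaic_system()
    ks = hopf_ks_at_nu(defaults, 0.2)
    seeds = {}
    for side, k_h, direction in (("low", ks[0], -1), ("high", ks[1], +1)):
        pk = defaults.with_(nu=0.2, k=k_h)
        eq = interior_equilibrium(pk)
        hp = hopf_from_equilibrium(system, eq.state, pk, param_name="k")
        c0 = initial_cycle_from_hopf(system, hp, offset=5e-3)
        branch = continue_cycle_branch(
            system, c0, "k", (0.5, 60.0), step=0.05, max_step=1.0,
            direction=direction, hopf_ends=tuple(ks), max_param_reversals=1,
        )
        seeds[side] = detect_lpc(branch, system)[0]
    return seeds


class TestHopfCurve:
    def test_single_humped_with_supercritical_core(self, defaults, bautins):
        curve = trace_hopf_curve(defaults, (5.0, 20.0), n=200)
        # single hump: nu rises to the peak at k=b then falls
        i_peak = np.argmax(curve.nu)
        assert np.all(np.diff(curve.nu[: i_peak + 1]) > 0)
        assert np.all(np.diff(curve.nu[i_peak:]) < 0)
        # the k-prefactor shifts the peak slightly above the switch offset b
        assert defaults.b - 1.0 < curve.k[i_peak] < defaults.b + 1.0
        # supercritical (l1 < 0) exactly between the two Bautin k-values
        gh1, gh2 = bautins
        sup = curve.k[curve.aux["l1"] < 0]
        assert sup.min() == pytest.approx(gh1.k, abs=0.1)
        assert sup.max() == pytest.approx(gh2.k, abs=0.1)

    def test_curve_passes_through_nu02_hopf_pair(self, defaults):
        ks = hopf_ks_at_nu(defaults, 0.2)
        for k_root, k_ref in zip(ks, (7.42, 15.31)):
            assert k_root == pytest.approx(k_ref, rel=6e-3)

    def test_criticality_split_matches_find_bautin(self, defaults, bautins):
        gh1, gh2 = bautins
        for gh in (gh1, gh2):
            lo = hopf_from_equilibrium(
                mosaic_system(),
                interior_equilibrium(defaults.with_(k=gh.k - 1e-3, nu=hopf_locus_nu(gh.k - 1e-3, defaults))).state,
                defaults.with_(k=gh.k - 1e-3, nu=hopf_locus_nu(gh.k - 1e-3, defaults)),
            )
            hi = hopf_from_equilibrium(
                mosaic_system(),
                interior_equilibrium(defaults.with_(k=gh.k + 1e-3, nu=hopf_locus_nu(gh.k + 1e-3, defaults))).state,
                defaults.with_(k=gh.k + 1e-3, nu=hopf_locus_nu(gh.k + 1e-3, defaults)),
            )
            assert lo.l1 * hi.l1 < 0  # sign change within 1e-3 of the located point


class TestLpcCurves:
    def test_curves_terminate_at_bautin_points(self, defaults, bautins, lpc_seeds):
        gh1, gh2 = bautins
        for side, gh in (("low", gh1), ("high", gh2)):
            curve = trace_lpc_curve(lpc_seeds[side], defaults, (0.05, 3.0))
            end = np.array([curve.k[-1], curve.nu[-1]])
            assert np.hypot(end[0] - gh.k, end[1] - gh.nu) < 1e-3
            assert not curve.truncated

    def test_fold_amplitude_shrinks_toward_bautin(self, defaults, lpc_seeds):
        curve = trace_lpc_curve(lpc_seeds["low"], defaults, (0.05, 3.0))
        amp = curve.aux["amplitude"]
        assert amp[-1] < 0.05 * amp.max()


class TestRegimeClassification:
    @pytest.mark.parametrize(
        "k, nu, expected",
        [(20.0, 0.9, "I"), (10.0, 0.5, "II"), (6.0, 0.2, "III")],
    )
    def test_reference_points(self, k, nu, expected, defaults):
        assert classify_regime(k, nu, defaults) == expected

    def test_region_three_inventory(self, defaults):
        """At (k=6, nu=0.2) the attractor inventory is exactly a stable
        equilibrium plus an unstable and a stable limit cycle, with the
        unstable cycle enclosing the equilibrium."""
        p = defaults.with_(k=6.0, nu=0.2)
        eq = interior_equilibrium(p)
        assert eq.stability == "stable"
        cycles = search_cycles(p, n_seeds=6, rng=np.random.default_rng(3))
        stabs = sorted(c.stability for c in cycles)
        assert stabs == ["stable", "unstable"]
        unstable = next(c for c in cycles if c.stability == "unstable")
        stable = next(c for c in cycles if c.stability == "stable")
        assert unstable.contains(eq.state)
        assert stable.amplitude[0] > unstable.amplitude[0]

    def test_no_unstable_cycle_in_region_one(self, defaults):
        """Region I holds only the stable equilibrium: cycle searches from
        many seeds find nothing, including at points flanking the bell."""
        for (k, nu) in [(20.0, 0.9), (18.0, 2.5), (6.0, 2.8)]:
            assert classify_regime(k, nu, defaults) == "I"
            assert search_cycles(defaults.with_(k=k, nu=nu), n_seeds=4,
                                 rng=np.random.default_rng(11)) == []

    def test_no_region_three_above_the_larger_bautin_nu(self, defaults, bautins):
        gh1, _ = bautins
        rng = np.random.default_rng(5)
        for _ in range(12):
            k = rng.uniform(5.0, 20.0)
            nu = rng.uniform(gh1.nu + 0.02, 2.9)
            assert classify_regime(k, nu, defaults) in ("I", "II", "boundary")

    def test_bistability_width_shrinks_with_nu(self, defaults):
        """The range of cycle existence and of bistability narrows as the
        natural conversion rate nu grows."""
        from fgmosaic.codim2 import _lpc_k_at_nu

        key = defaults.with_(k=10.0, nu=1.0)
        widths = {}
        for nu in (0.2, 1.4):
            ks = hopf_ks_at_nu(defaults, nu)
            k_lpc = _lpc_k_at_nu(key, nu, "low_k")
            widths[nu] = ks[0] - k_lpc
        assert widths[0.2] > widths[1.4] > 0

    def test_boundary_band(self, defaults):
        nu_h = hopf_locus_nu(10.0, defaults)
        assert classify_regime(10.0, nu_h + 5e-4, defaults) == "boundary"
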