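"""Andronov-Hopf detection, first Lyapunov coefficient, Bautin points.

At a Hopf point the Jacobian has a purely imaginary pair +/- i omega (trace
zero, positive determinant).  Criticality is decided by the first Lyapunov
coefficient l1, computed from the normal-form reduction in complex
coordinates: with eigenvectors A q = i omega q and A^T p = -i omega p
normalised to <p, q> = 1, the quadratic/cubic Taylor coefficients are

    g20 = <p, B(q, q)>,  g11 = <p, B(q, conj q)>,  g21 = <p, C(q, q, conj q)>

and, for a planar system (the whole plane is the centre manifold),

    l1 = Re(i g20 g11 + omega g21) / (2 omega^2).

The sign convention follows the dynamics: l1 < 0 means a supercritical Hopf
(stable emerging cycle), l1 > 0 subcritical.  Only the sign and the zero
location of l1 are meaningful; the magnitude is convention-dependent.

A Bautin (generalized Hopf) point is a zero of l1 along a Hopf curve.  For
the mosaic model the Hopf locus of the interior family has the closed form
nu_H(k) = c k e^(b-k) / (1 + e^(b-k))^2, obtained from trace = 0, i.e.
w'(1/2)/4 = nu; Bautin points are bracketed and refined on each side of the
locus peak at k = b.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any, Optional

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit

from .equilibria import Equilibrium, EquilibriumBranch, interior_equilibrium, newton_equilibrium
from .model import ParameterSet
from .systems import PlanarSystem, get_param, mosaic_system, set_param

__all__ = [
    "HopfPoint",
    "BautinPoint",
    "BAUTIN_TOL",
    "first_lyapunov_coefficient",
    "hopf_locus_nu",
    "hopf_point_on_locus",
    "detect_hopf",
    "find_bautin",
]

#: |l1| below this is reported as degenerate (candidate Bautin point).
BAUTIN_TOL = 1e-8

#: |trace| refinement target when locating Hopf points along a branch.
TRACE_TOL = 1e-9


@dataclass
class HopfPoint:
    """A refined Hopf bifurcation with its normal-form quantities."""

    state: np.ndarray
    params: Any
    omega: float
    l1: float
    criticality: str  # "supercritical" | "subcritical" | "degenerate"
    param_name: str = ""

    @property
    def param_value(self) -> float:
        return get_param(self.params, self.param_name) if self.param_name else np.nan


@dataclass
class BautinPoint:
    """A generalized Hopf point: l1 = 0 on the Hopf locus."""

    f: float
    x: float
    k: float
    nu: float
    omega: float
    l1_residual: float


def _criticality(l1: float, tol: float = BAUTIN_TOL) -> str:
    if abs(l1) < tol:
        return "degenerate"
    return "supercritical" if l1 < 0 else "subcritical"


def first_lyapunov_coefficient(bundle) -> float:
    """l1 from a DerivativeBundle evaluated at a Hopf equilibrium.

    Requires trace approximately 0 and determinant > 0; raises otherwise.
    """
    A = bundle.jacobian
    det = float(np.linalg.det(A))
    if det <= 0:
        raise ValueError(f"not a Hopf point: Jacobian determinant {det} <= 0")
    omega = np.sqrt(det)
    a11, a12 = A[0]
    a21, a22 = A[1]
    # right eigenvector A q = i omega q
    if abs(a12) >= abs(a21):
        q = np.array([a12, 1j * omega - a11], dtype=complex)
    else:
        q = np.array([1j * omega - a22, a21], dtype=complex)
    # adjoint eigenvector A^T p = -i omega p
    if abs(a21) >= abs(a12):
        p = np.array([a21, -(a11 + 1j * omega)], dtype=complex)
    else:
        p = np.array([-(a22 + 1j * omega), a12], dtype=complex)
    d = np.vdot(p, q)
    if d == 0:
        raise ValueError("eigenvector normalisation failed")
    p = p / np.conj(d)
    g20 = np.vdot(p, bundle.B(q, q))
    g11 = np.vdot(p, bundle.B(q, np.conj(q)))
    g21 = np.vdot(p, bundle.C(q, q, np.conj(q)))
    return float(np.real(1j * g20 * g11 + omega * g21) / (2.0 * omega**2))


def hopf_from_equilibrium(system: PlanarSystem, state: np.ndarray, params: Any, param_name: str = "") -> HopfPoint:
    """Build a HopfPoint (omega, l1, criticality) at a trace-zero equilibrium."""
    bundle = system.derivatives(state, params)
    tr = float(np.trace(bundle.jacobian))
    det = float(np.linalg.det(bundle.jacobian))
    if det <= 0:
        raise ValueError(f"determinant {det} <= 0: eigenvalues are real, not a Hopf candidate")
    if abs(tr) > 1e-6:
        raise ValueError(f"trace {tr} not at zero: not on the Hopf locus")
    l1 = first_lyapunov_coefficient(bundle)
    return HopfPoint(
        state=np.asarray(state, float),
        params=params,
        omega=float(np.sqrt(det)),
        l1=l1,
        criticality=_criticality(l1),
        param_name=param_name,
    )


# -- mosaic-model closed forms ------------------------------------------------


def hopf_locus_nu(k: float, p: ParameterSet) -> float:
    """nu on the Hopf locus of the interior family at steepness k.

    Zero trace means nu = w'(1/2)/4 = c k e^(b-k) / (1 + e^(b-k))^2, written
    here via the logistic function for overflow safety.
    """
    sig = expit(k - p.b)
    return p.c * k * sig * (1.0 - sig)


def hopf_point_on_locus(k: float, p: ParameterSet) -> HopfPoint:
    """The interior-family Hopf point at steepness k (nu set by the locus)."""
    pk = p.with_(k=k, nu=hopf_locus_nu(k, p))
    eq = interior_equilibrium(pk)
    if eq is None:
        raise ValueError(f"interior equilibrium leaves (0,1) on the Hopf locus at k={k}")
    return hopf_from_equilibrium(mosaic_system(), eq.state, pk, param_name="k")


def detect_hopf(branch: EquilibriumBranch, refine_tol: float = TRACE_TOL) -> list[HopfPoint]:
    """Hopf points along an equilibrium branch.

    Sign changes of the Jacobian trace between consecutive branch points with
    positive determinant are bracketed in the branch parameter and refined by
    bisection on the trace of the re-solved equilibrium.  Brackets where the
    complex pair becomes real (determinant <= 0) are discarded.
    """
    system = branch.system
    name = branch.param_name
    traces = branch.traces
    out: list[HopfPoint] = []
    for i in range(len(traces) - 1):
        t0, t1 = traces[i], traces[i + 1]
        if not t0 * t1 < 0:
            continue
        e0, e1 = branch.points[i], branch.points[i + 1]
        lam0 = get_param(e0.params, name)
        lam1 = get_param(e1.params, name)
        if lam0 == lam1:
            continue

        def trace_at(lam: float) -> float:
            frac = (lam - lam0) / (lam1 - lam0)
            guess = (1 - frac) * e0.state + frac * e1.state
            eq = newton_equilibrium(system, guess, set_param(e0.params, name, lam))
            return float(np.trace(system.jac(eq.state, eq.params)))

        try:
            lam_star = brentq(trace_at, lam0, lam1, xtol=refine_tol, rtol=8.9e-16)
        except ValueError:
            continue
        params = set_param(e0.params, name, lam_star)
        frac = (lam_star - lam0) / (lam1 - lam0)
        eq = newton_equilibrium(system, (1 - frac) * e0.state + frac * e1.state, params)
        det = float(np.linalg.det(system.jac(eq.state, params)))
        if det <= 0:
            continue  # pair became real: not a Hopf candidate
        out.append(hopf_from_equilibrium(system, eq.state, params, param_name=name))
    return out


def _l1_on_locus(k: float, p: ParameterSet) -> float:
    return hopf_point_on_locus(k, p).l1


def find_bautin(
    p: ParameterSet,
    branch_side: str = "low_k",
    k_bracket: Optional[tuple[float, float]] = None,
    n_scan: int = 200,
    k_tol: float = 1e-13,
) -> Optional[BautinPoint]:
    """Locate the Bautin point on one side of the interior Hopf locus.

    The first Lyapunov coefficient is scanned along the one-parameter Hopf
    curve (nu = nu_H(k)); its sign change on the requested side of the locus
    peak k = b is bracketed and refined by bisection.  Returns ``None`` when
    l1 does not change sign on that side.
    """
    if branch_side not in ("low_k", "high_k"):
        raise ValueError("branch_side must be 'low_k' or 'high_k'")
    if k_bracket is None:
        if branch_side == "low_k":
            k_bracket = (max(0.05, p.b - 9.0), p.b - 1e-3)
        else:
            k_bracket = (p.b + 1e-3, p.b + 9.0)
    ks = np.linspace(k_bracket[0], k_bracket[1], n_scan)
    vals = np.full(ks.shape, np.nan)
    for i, k in enumerate(ks):
        try:
            vals[i] = _l1_on_locus(float(k), p)
        except (ValueError, RuntimeError):
            continue
    good = np.isfinite(vals)
    idx = np.nonzero(good[:-1] & good[1:] & (vals[:-1] * vals[1:] < 0))[0]
    if len(idx) == 0:
        return None
    i = idx[0]
    k_star = brentq(lambda k: _l1_on_locus(k, p), ks[i], ks[i + 1], xtol=k_tol)
    hp = hopf_point_on_locus(k_star, p)
    return BautinPoint(
        f=float(hp.state[0]),
        x=float(hp.state[1]),
        k=float(k_star),
        nu=float(get_param(hp.params, "nu")),
        omega=hp.omega,
        l1_residual=hp.l1,
    )
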