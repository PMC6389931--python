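"""Normal-form benchmark systems with analytically known bifurcation structure.

Both fixtures are rotationally symmetric planar fields

    dx/dt = A(rho) * x - omega * y,   dy/dt = omega * x + A(rho) * y,
    rho = x^2 + y^2,

whose radial dynamics decouple as r' = A(r^2) * r.  With
``A(rho) = mu + sign * rho`` this is the Hopf normal form (cycle radius
sqrt(mu) for sign = -1, mu > 0); with ``A(rho) = beta1 + beta2*rho - rho^2``
it is the Bautin unfolding, whose Hopf line is beta1 = 0, whose Bautin point
sits at the origin of the (beta1, beta2) plane, and whose fold-of-cycles
curve is beta1 = -beta2^2/4 (beta2 > 0).  Every ground truth is a closed
form, so each numerical stage of the pipeline can be validated exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any, Callable

import numpy as np

from .model import DerivativeBundle
from .systems import PlanarSystem

__all__ = [
    "HopfNFParams",
    "BautinNFParams",
    "NormalFormSystem",
    "hopf_normal_form",
    "bautin_normal_form",
]


@dataclass(frozen=True)
class HopfNFParams:
    mu: float = 0.0
    omega: float = 1.0
    sign: float = -1.0


@dataclass(frozen=True)
class BautinNFParams:
    beta1: float = 0.0
    beta2: float = 1.0
    omega: float = 1.0


@dataclass(frozen=True)
class NormalFormSystem(PlanarSystem):
    """A benchmark system bundling closed-form ground truths.

    ``ground_truth`` maps names like ``"cycle_radius"`` or ``"lpc_curve"``
    to callables of the parameters.
    """

    ground_truth: dict[str, Callable] | None = None


def _radial_coeffs(p: Any) -> tuple[float, float, float, float]:
    """(a0, a1, a2, omega) for A(rho) = a0 + a1*rho + a2*rho^2."""
    if isinstance(p, HopfNFParams):
        return p.mu, p.sign, 0.0, p.omega
    if isinstance(p, BautinNFParams):
        return p.beta1, p.beta2, -1.0, p.omega
    raise TypeError(f"unsupported normal-form parameters: {p!r}")


def _radial_rhs(y, p) -> np.ndarray:
    a0, a1, a2, omega = _radial_coeffs(p)
    x, v = y
    rho = x * x + v * v
    A = a0 + a1 * rho + a2 * rho * rho
    return np.array([A * x - omega * v, omega * x + A * v])


def _radial_derivatives(y, p) -> DerivativeBundle:
    # Tensors of F = A(rho) (x, y) + omega (-y, x) via A'(rho), A''(rho).
    a0, a1, a2, omega = _radial_coeffs(p)
    x, v = y
    rho = x * x + v * v
    A = a0 + a1 * rho + a2 * rho * rho
    A1 = a1 + 2.0 * a2 * rho
    A2 = 2.0 * a2

    val = np.array([A * x - omega * v, omega * x + A * v])
    jac = np.array(
        [
            [A + 2.0 * A1 * x * x, -omega + 2.0 * A1 * x * v],
            [omega + 2.0 * A1 * x * v, A + 2.0 * A1 * v * v],
        ]
    )

    B = np.zeros((2, 2, 2))
    B[0, 0, 0] = 6.0 * A1 * x + 4.0 * A2 * x**3
    B[0, 0, 1] = B[0, 1, 0] = 2.0 * A1 * v + 4.0 * A2 * x * x * v
    B[0, 1, 1] = 2.0 * A1 * x + 4.0 * A2 * x * v * v
    B[1, 1, 1] = 6.0 * A1 * v + 4.0 * A2 * v**3
    B[1, 0, 1] = B[1, 1, 0] = 2.0 * A1 * x + 4.0 * A2 * v * v * x
    B[1, 0, 0] = 2.0 * A1 * v + 4.0 * A2 * x * x * v

    C = np.zeros((2, 2, 2, 2))
    c_xxx = 6.0 * A1 + 24.0 * A2 * x * x
    c_xxy = 12.0 * A2 * x * v
    c_xyy = 2.0 * A1 + 4.0 * A2 * (x * x + v * v)
    c_yyy = 12.0 * A2 * x * v
    # First component: derivatives of A(rho)*x
    C[0, 0, 0, 0] = c_xxx
    C[0, 0, 0, 1] = C[0, 0, 1, 0] = C[0, 1, 0, 0] = c_xxy
    C[0, 0, 1, 1] = C[0, 1, 0, 1] = C[0, 1, 1, 0] = c_xyy
    C[0, 1, 1, 1] = c_yyy
    # Second component: same with x and y swapped
    C[1, 1, 1, 1] = 6.0 * A1 + 24.0 * A2 * v * v
    C[1, 1, 1, 0] = C[1, 1, 0, 1] = C[1, 0, 1, 1] = 12.0 * A2 * x * v
    C[1, 1, 0, 0] = C[1, 0, 1, 0] = C[1, 0, 0, 1] = 2.0 * A1 + 4.0 * A2 * (x * x + v * v)
    C[1, 0, 0, 0] = 12.0 * A2 * x * v
    return DerivativeBundle(value=val, jacobian=jac, second_order=B, third_order=C)


def hopf_normal_form(mu: float = 0.0, omega: float = 1.0, cubic_sign: float = -1.0) -> tuple[NormalFormSystem, HopfNFParams]:
    """Hopf normal form with equilibrium at the origin, eigenvalues mu +/- i omega.

    For ``cubic_sign = -1`` (supercritical) and mu > 0 the stable cycle has
    radius sqrt(mu) and period 2 pi / omega.
    """
    if omega <= 0:
        raise ValueError("omega must be positive")
    if cubic_sign not in (-1.0, 1.0, -1, 1):
        raise ValueError("cubic_sign must be -1 or +1")
    params = HopfNFParams(mu=mu, omega=omega, sign=float(cubic_sign))
    truth = {
        "l1_sign": lambda p: p.sign,
        "cycle_radius": lambda p: np.sqrt(p.mu / -p.sign) if p.mu / -p.sign > 0 else np.nan,
        "period": lambda p: 2.0 * np.pi / p.omega,
        "hopf_mu": lambda p: 0.0,
    }
    system = NormalFormSystem(
        name="hopf_nf",
        rhs=_radial_rhs,
        derivatives=_radial_derivatives,
        jacobian=None,
        ground_truth=truth,
    )
    return system, params


def bautin_normal_form(beta1: float = 0.0, beta2: float = 1.0, omega: float = 1.0) -> tuple[NormalFormSystem, BautinNFParams]:
    """Bautin unfolding with radial part r' = beta1 r + beta2 r^3 - r^5.

    Ground truths: Hopf line beta1 = 0 with l1 sign = sign(beta2); Bautin
    point at (beta1, beta2) = (0, 0); cycle radii r^2 = (beta2 +/-
    sqrt(beta2^2 + 4 beta1))/2; fold of cycles at beta1 = -beta2^2/4 with
    fold radius^2 = beta2/2 (beta2 > 0).
    """

    def _radii(p):
        disc = p.beta2**2 + 4.0 * p.beta1
        if disc < 0:
            return ()
        root = np.sqrt(disc)
        out = []
        for sgn in (+1.0, -1.0):
            r2 = (p.beta2 + sgn * root) / 2.0
            if r2 > 0:
                out.append(np.sqrt(r2))
        return tuple(sorted(out, reverse=True))

    params = BautinNFParams(beta1=beta1, beta2=beta2, omega=omega)
    truth = {
        "hopf_beta1": lambda p: 0.0,
        "l1_sign_on_hopf_line": lambda p: np.sign(p.beta2),
        "bautin_point": lambda p: (0.0, 0.0),
        "cycle_radii": _radii,
        "lpc_beta1": lambda p: -p.beta2**2 / 4.0,
        "lpc_radius": lambda p: np.sqrt(p.beta2 / 2.0) if p.beta2 > 0 else np.nan,
        "period": lambda p: 2.0 * np.pi / p.omega,
    }
    system = NormalFormSystem(
        name="bautin_nf",
        rhs=_radial_rhs,
        derivatives=_radial_derivatives,
        jacobian=None,
        ground_truth=truth,
    )
    return system, params
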