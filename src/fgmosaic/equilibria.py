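"""Equilibria of the mosaic model: location, continuation and stability.

With the symmetric perceived-value function (u(1/2) = 0) the coupled model
has an interior equilibrium family pinned at f = 1/2 with

    x* = 1/2 + (nu/2 - w(1/2)/4) / (2 h),

whose Jacobian has trace tau = w'(1/2)/4 - nu and determinant
Delta = 4 h s x*(1 - x*) > 0.  The positive determinant means the interior
equilibrium is never a saddle: it loses stability only through the trace,
i.e. through an Andronov-Hopf bifurcation.  Branches in one parameter are
traced by pseudo-arclength continuation with a Newton corrector.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Optional

import numpy as np

from .model import ParameterSet, recruitment_rate
from .systems import PlanarSystem, get_param, mosaic_system, set_param

__all__ = [
    "Equilibrium",
    "EquilibriumBranch",
    "NEWTON_TOL",
    "newton_equilibrium",
    "interior_equilibrium",
    "boundary_equilibria",
    "classify_stability",
    "continue_branch",
]

#: Default absolute/relative Newton tolerance for all corrector iterations.
NEWTON_TOL = 1e-6

#: Below this margin on |Re(lambda)| stability is flagged "marginal".
MARGINAL_TOL = 1e-9


@dataclass
class Equilibrium:
    """A converged steady state with its linearisation."""

    state: np.ndarray
    params: Any
    eigenvalues: np.ndarray
    stability: str  # "stable" | "unstable" | "marginal"
    kind: str = "generic"  # "interior" | "boundary-x0" | "boundary-x1" | "generic"
    residual: float = 0.0

    @property
    def trace(self) -> float:
        return float(np.sum(self.eigenvalues.real))

    @property
    def determinant(self) -> float:
        return float(np.prod(self.eigenvalues).real)


def _stability_label(eigs: np.ndarray) -> str:
    re = eigs.real
    if np.max(np.abs(re)) < MARGINAL_TOL:
        return "marginal"
    if np.any(np.abs(re) < MARGINAL_TOL):
        return "marginal"
    return "stable" if np.all(re < 0) else "unstable"


def classify_stability(system: PlanarSystem, state: np.ndarray, params: Any) -> tuple[str, np.ndarray]:
    """Stability label and eigenvalues of the analytic Jacobian at ``state``."""
    eigs = np.linalg.eigvals(system.jac(state, params))
    # order: ascending real part, then imaginary
    order = np.lexsort((eigs.imag, eigs.real))
    eigs = eigs[order]
    return _stability_label(eigs), eigs


def _make_equilibrium(system, state, params, kind="generic") -> Equilibrium:
    stab, eigs = classify_stability(system, state, params)
    res = float(np.linalg.norm(system.rhs(state, params)))
    return Equilibrium(np.asarray(state, float), params, eigs, stab, kind, res)


def newton_equilibrium(
    system: PlanarSystem,
    guess: np.ndarray,
    params: Any,
    tol: float = NEWTON_TOL,
    max_iter: int = 50,
    kind: str = "generic",
) -> Equilibrium:
    """Solve rhs(y) = 0 by damped Newton from ``guess``."""
    y = np.asarray(guess, dtype=float).copy()
    for _ in range(max_iter):
        F = system.rhs(y, params)
        if np.linalg.norm(F) < 1e-4 * tol:
            break
        J = system.jac(y, params)
        try:
            step = np.linalg.solve(J, -F)
        except np.linalg.LinAlgError as exc:
            raise RuntimeError(f"singular Jacobian at {y}") from exc
        lam = 1.0
        for _ in range(8):
            y_new = y + lam * step
            try:
                F_new = system.rhs(y_new, params)
            except ValueError:
                lam *= 0.5
                continue
            if np.linalg.norm(F_new) < np.linalg.norm(F) or lam < 0.1:
                break
            lam *= 0.5
        y = y + lam * step
        if np.linalg.norm(lam * step) < 1e-4 * tol and np.linalg.norm(system.rhs(y, params)) < tol:
            break
    if np.linalg.norm(system.rhs(y, params)) > tol:
        raise RuntimeError(f"Newton failed to converge from {guess} at {params}")
    return _make_equilibrium(system, y, params, kind)


def interior_equilibrium(p: ParameterSet) -> Optional[Equilibrium]:
    """Closed-form interior equilibrium (f = 1/2, x* from the feedback balance).

    Requires the symmetric preference function u(1/2) = 0 and h > 0; returns
    ``None`` when x* falls outside (0, 1), i.e. the human feedback cannot
    balance the net forest loss at f = 1/2.
    """
    if not p.symmetric_preference:
        raise ValueError(
            "interior_equilibrium requires u(1/2) = 0 (symmetric preference); "
            "use newton_equilibrium with an explicit guess otherwise"
        )
    if p.h <= 0:
        raise ValueError("interior equilibrium needs h > 0 to pin x*")
    w_half = recruitment_rate(0.5, p)
    x_star = 0.5 + (p.nu / 2.0 - w_half / 4.0) / (2.0 * p.h)
    if not 0.0 < x_star < 1.0:
        return None
    return _make_equilibrium(mosaic_system(), np.array([0.5, x_star]), p, kind="interior")


def boundary_equilibria(p: ParameterSet, n_grid: int = 10_000) -> list[Equilibrium]:
    """Steady states on the invariant lines x = 0 and x = 1.

    On those lines dx/dt = 0 identically and the forest equation reduces to
    w(f) f (1-f) - nu f -+ h; roots are found by a sign scan over a uniform
    grid followed by bisection.
    """
    from scipy.optimize import brentq

    system = mosaic_system()
    out: list[Equilibrium] = []
    fs = np.linspace(0.0, 1.0 - 1e-6, n_grid)
    for x_line, kind in ((0.0, "boundary-x0"), (1.0, "boundary-x1")):
        res = np.array([system.rhs(np.array([f, x_line]), p)[0] for f in fs])
        for i in np.nonzero(np.diff(np.sign(res)) != 0)[0]:
            if res[i] == 0.0:
                root = fs[i]
            else:
                root = brentq(
                    lambda f: system.rhs(np.array([f, x_line]), p)[0],
                    fs[i],
                    fs[i + 1],
                    xtol=1e-12,
                )
            out.append(_make_equilibrium(system, np.array([root, x_line]), p, kind))
        # f = 0 root that the sign scan misses when the residual leaves zero tangentially
        if abs(res[0]) < 1e-12 and not any(abs(e.state[0]) < 1e-9 and e.kind == kind for e in out):
            out.append(_make_equilibrium(system, np.array([0.0, x_line]), p, kind))
    return out


@dataclass
class EquilibriumBranch:
    """Ordered equilibrium family from one-parameter continuation."""

    param_name: str
    points: list[Equilibrium] = field(default_factory=list)
    arclength: list[float] = field(default_factory=list)
    system: PlanarSystem = field(default_factory=mosaic_system)
    truncated: bool = False
    truncation_reason: str = ""

    @property
    def param_values(self) -> np.ndarray:
        return np.array([get_param(e.params, self.param_name) for e in self.points])

    @property
    def states(self) -> np.ndarray:
        return np.array([e.state for e in self.points])

    @property
    def traces(self) -> np.ndarray:
        return np.array([e.trace for e in self.points])

    @property
    def determinants(self) -> np.ndarray:
        return np.array([e.determinant for e in self.points])

    def to_dataframe(self):
        import pandas as pd

        rows = []
        for s, e in zip(self.arclength, self.points):
            l1_, l2_ = e.eigenvalues
            rows.append(
                {
                    "arclength": s,
                    "param": get_param(e.params, self.param_name),
                    "f": e.state[0],
                    "x": e.state[1],
                    "re_lambda1": l1_.real,
                    "im_lambda1": l1_.imag,
                    "re_lambda2": l2_.real,
                    "im_lambda2": l2_.imag,
                    "stability": e.stability,
                }
            )
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def _param_derivative(system, y, params, name, scale=1e-7):
    lam = get_param(params, name)
    d = scale * max(1.0, abs(lam))
    fp = system.rhs(y, set_param(params, name, lam + d))
    fm = system.rhs(y, set_param(params, name, lam - d))
    return (fp - fm) / (2.0 * d)


def _extended_jacobian(system, y, params, name):
    J = system.jac(y, params)
    dF = _param_derivative(system, y, params, name)
    return np.column_stack([J, dF])


def _tangent(system, y, params, name, prev_tangent):
    Jext = _extended_jacobian(system, y, params, name)
    A = np.vstack([Jext, prev_tangent])
    rhs_vec = np.array([0.0, 0.0, 1.0])
    try:
        t = np.linalg.solve(A, rhs_vec)
    except np.linalg.LinAlgError:
        # fall back to the nullspace direction closest to the previous tangent
        _, _, vt = np.linalg.svd(Jext)
        t = vt[-1]
        if np.dot(t, prev_tangent) < 0:
            t = -t
    return t / np.linalg.norm(t)


def _corrector(system, z_pred, params0, name, tangent, tol, max_iter=12):
    """Newton on [rhs; tangent . (z - z_pred)] in (y, lambda) space."""
    z = z_pred.copy()
    for _ in range(max_iter):
        params = set_param(params0, name, z[2])
        F = system.rhs(z[:2], params)
        g = np.dot(tangent, z - z_pred)
        R = np.array([F[0], F[1], g])
        if np.linalg.norm(R) < 1e-4 * tol:
            break
        Jext = _extended_jacobian(system, z[:2], params, name)
        A = np.vstack([Jext, tangent])
        try:
            step = np.linalg.solve(A, -R)
        except np.linalg.LinAlgError:
            return None
        z = z + step
        if not np.all(np.isfinite(z)):
            return None
    params = set_param(params0, name, z[2])
    try:
        if np.linalg.norm(system.rhs(z[:2], params)) > tol:
            return None
    except ValueError:
        return None
    return z


def continue_branch(
    start: Equilibrium,
    param_name: str,
    param_range: tuple[float, float],
    step: float = 0.01,
    max_step: float = 0.1,
    min_step: float = 1e-8,
    max_points: int = 5000,
    system: PlanarSystem | None = None,
    tol: float = NEWTON_TOL,
    direction: int = +1,
) -> EquilibriumBranch:
    """Pseudo-arclength continuation of an equilibrium in one parameter.

    The branch is traced from ``start`` in the ``direction`` of increasing
    (+1) or decreasing (-1) parameter until it leaves ``param_range`` or the
    corrector fails after step-halving (the branch is then truncated at the
    last converged point).
    """
    if system is None:
        system = mosaic_system()
    lo, hi = param_range
    lam0 = get_param(start.params, param_name)
    if not lo <= lam0 <= hi:
        raise ValueError(f"start parameter {lam0} outside range {param_range}")

    branch = EquilibriumBranch(param_name=param_name, system=system)
    branch.points.append(start)
    branch.arclength.append(0.0)

    prev_t = np.array([0.0, 0.0, float(direction)])
    z = np.array([start.state[0], start.state[1], lam0])
    ds = step
    s = 0.0
    kind = start.kind

    while len(branch.points) < max_points:
        params = set_param(start.params, param_name, z[2])
        t = _tangent(system, z[:2], params, param_name, prev_t)
        if np.dot(t, prev_t) < 0:
            t = -t
        z_new = None
        while ds >= min_step:
            z_pred = z + ds * t
            z_new = _corrector(system, z_pred, start.params, param_name, t, tol)
            if z_new is not None:
                break
            ds *= 0.5
        if z_new is None:
            branch.truncated = True
            branch.truncation_reason = "corrector failed after step-halving"
            break
        if not lo <= z_new[2] <= hi:
            # land exactly on the range boundary with a natural-parameter solve
            bound = lo if z_new[2] < lo else hi
            try:
                eq = newton_equilibrium(
                    system, z_new[:2], set_param(start.params, param_name, bound), tol=tol, kind=kind
                )
                s += np.linalg.norm(np.array([*eq.state, bound]) - z)
                branch.points.append(eq)
                branch.arclength.append(s)
            except RuntimeError:
                pass
            break
        s += np.linalg.norm(z_new - z)
        prev_t = t
        z = z_new
        eq = _make_equilibrium(system, z[:2], set_param(start.params, param_name, z[2]), kind)
        branch.points.append(eq)
        branch.arclength.append(s)
        ds = min(ds * 1.3, max_step)
    return branch
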