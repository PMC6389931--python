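"""Periodic orbits: shooting, continuation, Floquet multipliers, LPC detection.

A limit cycle is solved as a periodic boundary-value problem by single
shooting: unknowns (y0, T) with residuals phi_T(y0) - y0 = 0 and an anchored
phase condition F(y_a) . (y0 - y_a) = 0 (the correction is orthogonal to the
flow at the anchor, which removes the time-shift degeneracy).  The monodromy
matrix M comes from integrating the variational equations over one period;
its eigenvalues are the Floquet multipliers.  For a planar autonomous system
the multipliers are {1, m} with m = det M = exp of the integral of the
Jacobian trace over the period (Abel/Liouville), so folds of cycles (LPC)
are zeros of log det M and cycle stability is |det M| < 1.

Branches in one parameter are traced by pseudo-arclength continuation on
(y0, T, lambda); LPC points are sign changes of d lambda along the branch,
refined by Newton on the extended system with the fold condition
log det M = 0 appended.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Optional

import numpy as np
from scipy.integrate import solve_ivp

from .hopf import HopfPoint
from .systems import PlanarSystem, get_param, set_param

__all__ = [
    "LimitCycle",
    "CycleBranch",
    "LPCPoint",
    "CYCLE_TOL",
    "LPC_TOL",
    "shoot",
    "solve_cycle",
    "initial_cycle_from_hopf",
    "continue_cycle_branch",
    "floquet_multipliers",
    "detect_lpc",
]

#: Closure tolerance on the periodicity residual.
CYCLE_TOL = 1e-8

#: Distance of the nontrivial multiplier to +1 accepted at a fold of cycles.
LPC_TOL = 1e-3

#: Integrator tolerances for all cycle computations.
_RTOL = 1e-10
_ATOL = 1e-10

_N_MESH = 201


@dataclass
class LimitCycle:
    """A converged periodic orbit with its Floquet data."""

    y0: np.ndarray
    period: float
    params: Any
    multipliers: np.ndarray
    stability: str  # "stable" | "unstable"
    mesh_t: np.ndarray
    mesh: np.ndarray  # (N, 2) states over one period
    closure_residual: float

    @property
    def amplitude(self) -> np.ndarray:
        """(max - min) of each state component over the orbit."""
        return self.mesh.max(axis=0) - self.mesh.min(axis=0)

    @property
    def amplitude_f(self) -> float:
        return float(self.amplitude[0])

    @property
    def nontrivial_multiplier(self) -> float:
        """det M: the product of multipliers with the trivial one ~ 1."""
        return float(np.prod(self.multipliers).real)

    def contains(self, point) -> bool:
        """Winding-number test: is ``point`` enclosed by the orbit polygon?"""
        path = self.mesh - np.asarray(point)
        ang = np.arctan2(path[:, 1], path[:, 0])
        dang = np.diff(ang)
        dang = (dang + np.pi) % (2 * np.pi) - np.pi
        return abs(dang.sum()) > np.pi


@dataclass
class CycleBranch:
    """Ordered cycle family from one-parameter continuation."""

    param_name: str
    cycles: list[LimitCycle] = field(default_factory=list)
    arclength: list[float] = field(default_factory=list)
    termination: str = ""

    @property
    def param_values(self) -> np.ndarray:
        return np.array([get_param(c.params, self.param_name) for c in self.cycles])

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "param": self.param_values,
                "period": [c.period for c in self.cycles],
                "amplitude_f": [c.amplitude[0] for c in self.cycles],
                "amplitude_x": [c.amplitude[1] for c in self.cycles],
                "stability": [c.stability for c in self.cycles],
            }
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


@dataclass
class LPCPoint:
    """Fold (turning point) of limit cycles."""

    cycle: LimitCycle
    param_name: str
    side: str = ""  # which branch segments meet, e.g. "unstable/stable"

    @property
    def param_value(self) -> float:
        return get_param(self.cycle.params, self.param_name)


def _flow(system: PlanarSystem, params, y0, T, variational=False, logdet=False, t_eval=None):
    """Integrate the flow, optionally with variational equations and log det M.

    Returns (yT, M or None, q or None, sol) where q = integral of trace J dt.
    """
    n_extra = (4 if variational else 0) + (1 if logdet else 0)

    def rhs_aug(t, z):
        y = z[:2]
        if not np.isfinite(y).all() or np.abs(y).max() > 5.0:
            raise ValueError("state left the admissible region during shooting")
        f = system.rhs(y, params)
        if n_extra == 0:
            return f
        out = np.empty(2 + n_extra)
        out[:2] = f
        J = system.jac(y, params)
        idx = 2
        if variational:
            Phi = z[2:6].reshape(2, 2)
            out[2:6] = (J @ Phi).ravel()
            idx = 6
        if logdet:
            out[idx] = J[0, 0] + J[1, 1]
        return out

    z0 = np.concatenate([np.asarray(y0, float), np.eye(2).ravel() if variational else [], [0.0] if logdet else []])
    sol = solve_ivp(
        rhs_aug,
        (0.0, T),
        z0,
        method="DOP853",
        rtol=_RTOL,
        atol=_ATOL,
        t_eval=t_eval,
        dense_output=False,
    )
    if not sol.success:
        raise RuntimeError(f"monodromy integration failed at t={sol.t[-1]}: {sol.message}")
    zT = sol.y[:, -1]
    M = zT[2:6].reshape(2, 2) if variational else None
    q = zT[-1] if logdet else None
    return zT[:2], M, q, sol


def shoot(system: PlanarSystem, params, y0, T):
    """(phi_T(y0), monodromy M)."""
    yT, M, _, _ = _flow(system, params, y0, T, variational=True)
    return yT, M


def floquet_multipliers(c: LimitCycle, system: PlanarSystem) -> np.ndarray:
    """Eigenvalues of the monodromy matrix, trivial (closest to 1) first."""
    _, M = shoot(system, c.params, c.y0, c.period)
    mults = np.linalg.eigvals(M)
    order = np.argsort(np.abs(mults - 1.0))
    return mults[order]


def _finish_cycle(system, params, y0, T, residual) -> LimitCycle:
    t_eval = np.linspace(0.0, T, _N_MESH)
    _, M, _, sol = _flow(system, params, y0, T, variational=True, t_eval=t_eval)
    mults = np.linalg.eigvals(M)
    order = np.argsort(np.abs(mults - 1.0))
    mults = mults[order]
    nontrivial = float(np.linalg.det(M))
    stability = "stable" if abs(nontrivial) < 1.0 else "unstable"
    return LimitCycle(
        y0=np.asarray(y0, float),
        period=float(T),
        params=params,
        multipliers=mults,
        stability=stability,
        mesh_t=t_eval,
        mesh=sol.y[:2].T.copy(),
        closure_residual=float(residual),
    )


def solve_cycle(
    system: PlanarSystem,
    params,
    y0_guess,
    T_guess: float,
    anchor=None,
    tol: float = CYCLE_TOL,
    max_iter: int = 40,
) -> LimitCycle:
    """Newton/single-shooting solve of a periodic orbit near the guess.

    Damped Newton with residual backtracking: a step is halved until the
    periodicity-plus-phase residual decreases (or the domain/period stays
    valid), which keeps the iteration inside the basin even from crude seeds.
    """
    y0 = np.asarray(y0_guess, float).copy()
    T = float(T_guess)
    if anchor is None:
        anchor = y0.copy()
    Fa = system.rhs(anchor, params)
    reanchors = 0

    def residual_and_monodromy(y, Tc):
        yT, M = shoot(system, params, y, Tc)
        return np.array([yT[0] - y[0], yT[1] - y[1], Fa @ (y - anchor)]), M, yT

    R, M, yT = residual_and_monodromy(y0, T)
    for _ in range(max_iter):
        if np.linalg.norm(R[:2]) < tol and abs(R[2]) < tol:
            return _finish_cycle(system, params, y0, T, np.linalg.norm(R[:2]))
        FT = system.rhs(yT, params)
        A = np.zeros((3, 3))
        A[:2, :2] = M - np.eye(2)
        A[:2, 2] = FT
        A[2, :2] = Fa
        try:
            step = np.linalg.solve(A, -R)
        except np.linalg.LinAlgError as exc:
            raise RuntimeError("singular shooting Jacobian (orbit may have collapsed)") from exc
        norm_old = np.linalg.norm(R)
        damp = 1.0
        accepted = False
        for _ in range(6):
            y_new = y0 + damp * step[:2]
            T_new = T + damp * step[2]
            if not 0.05 * T_guess < T_new < 20.0 * T_guess or not np.all(np.isfinite(y_new)):
                damp *= 0.5
                continue
            try:
                R_new, M_new, yT_new = residual_and_monodromy(y_new, T_new)
            except (ValueError, RuntimeError):
                damp *= 0.5
                continue
            if np.linalg.norm(R_new) < norm_old or np.linalg.norm(R_new[:2]) < tol:
                y0, T, R, M, yT = y_new, T_new, R_new, M_new, yT_new
                accepted = True
                break
            damp *= 0.5
        if not accepted:
            # a seed far from the orbit can leave the anchored phase plane
            # outside the cycle: move the anchor to the current iterate
            if reanchors < 5:
                reanchors += 1
                anchor = y0.copy()
                Fa = system.rhs(anchor, params)
                R, M, yT = residual_and_monodromy(y0, T)
                continue
            raise RuntimeError(
                f"cycle shooting stalled (residual {np.linalg.norm(R[:2]):.2e})"
            )
    raise RuntimeError(f"cycle shooting failed to converge (last residual {np.linalg.norm(R[:2]):.2e})")


def _equilibrium_at(system, params, guess):
    from .equilibria import newton_equilibrium

    return newton_equilibrium(system, guess, params)


def initial_cycle_from_hopf(
    system: PlanarSystem,
    hp: HopfPoint,
    offset: float = 1e-3,
    param_name: Optional[str] = None,
    max_retries: int = 3,
) -> LimitCycle:
    """A small converged cycle just off a Hopf point.

    The continuation parameter is displaced by ``offset`` onto the
    cycle-existence side (decided by the sign of l1 and of d trace / d lambda),
    the orbit is seeded on the linear eigenplane with the normal-form radius
    estimate, and corrected by shooting.  On failure the offset is doubled up
    to ``max_retries`` times.
    """
    name = param_name or hp.param_name
    if not name:
        raise ValueError("initial_cycle_from_hopf needs the Hopf point's parameter name")
    lam0 = get_param(hp.params, name)

    # d(trace)/d lambda along the equilibrium family, by central differences
    d = 1e-5 * max(1.0, abs(lam0))
    trs = []
    for lam in (lam0 - d, lam0 + d):
        eq = _equilibrium_at(system, set_param(hp.params, name, lam), hp.state)
        trs.append(float(np.trace(system.jac(eq.state, eq.params))))
    dtr = (trs[1] - trs[0]) / (2.0 * d)
    if dtr == 0.0:
        raise RuntimeError("trace does not vary with the parameter: cannot pick a side")
    # supercritical (l1<0): cycle where the equilibrium is unstable (trace>0);
    # subcritical (l1>0): cycle where it is stable (trace<0)
    side = np.sign(dtr) * (1.0 if hp.l1 < 0 else -1.0)

    dlam = abs(offset)
    last_err: Exception | None = None
    for _ in range(max_retries + 1):
        lam_c = lam0 + side * dlam
        params = set_param(hp.params, name, lam_c)
        try:
            eq = _equilibrium_at(system, params, hp.state)
            J = system.jac(eq.state, params)
            det = float(np.linalg.det(J))
            omega = np.sqrt(max(det, 1e-12))
            # eigenplane basis from the complex eigenvector
            a11, a12 = J[0]
            q = np.array([a12, 0.5 * (J[1, 1] - a11) + 1j * omega], dtype=complex)
            vr = np.real(q)
            vr /= np.linalg.norm(vr)
            tr_c = float(np.trace(J))
            r_nf = np.sqrt(abs(tr_c / (2.0 * hp.l1))) if hp.l1 != 0 else 0.0
            radii = [r for r in (r_nf, 2 * r_nf, 4 * r_nf, 0.5 * r_nf) if r > 0]
            radii += [1e-3, 3e-3, 1e-2, 3e-2]
            for r0 in radii:
                try:
                    cyc = solve_cycle(system, params, eq.state + r0 * vr, 2.0 * np.pi / omega)
                except RuntimeError as exc:
                    last_err = exc
                    continue
                amp = cyc.amplitude.max()
                # reject the degenerate equilibrium solution (zero amplitude) and
                # convergence onto a distant large cycle from a tiny seed
                if max(1e-5, 0.3 * r0) < amp < max(60 * r0, 1e-2):
                    return cyc
                last_err = RuntimeError(f"shooting collapsed to amplitude {amp:.2e} from seed radius {r0:.2e}")
        except RuntimeError as exc:
            last_err = exc
        dlam *= 2.0
    raise RuntimeError(f"no cycle found near the Hopf point after {max_retries + 1} offsets: {last_err}")


def _cycle_residual(system, p0, name, z, anchor, Fa, logdet=False):
    """Residuals [periodicity(2); phase; (log det M)] at z = (y0, T, lambda)."""
    params = set_param(p0, name, z[3])
    yT, M, q, _ = _flow(system, params, z[:2], z[2], variational=True, logdet=logdet)
    out = [yT[0] - z[0], yT[1] - z[1], Fa @ (z[:2] - anchor)]
    if logdet:
        out.append(q)
    return np.array(out), M, params


def _branch_jacobian(system, p0, name, z, anchor, Fa):
    """3x4 Jacobian of the periodicity+phase residuals at z = (y0, T, lambda)."""
    params = set_param(p0, name, z[3])
    yT, M = shoot(system, params, z[:2], z[2])
    FT = system.rhs(yT, params)
    d = 1e-6 * max(1.0, abs(z[3]))
    yp, _, _, _ = _flow(system, set_param(p0, name, z[3] + d), z[:2], z[2])
    ym, _, _, _ = _flow(system, set_param(p0, name, z[3] - d), z[:2], z[2])
    dphi = (yp - ym) / (2.0 * d)
    A = np.zeros((3, 4))
    A[:2, :2] = M - np.eye(2)
    A[:2, 2] = FT
    A[:2, 3] = dphi
    A[2, :2] = Fa
    R = np.array([yT[0] - z[0], yT[1] - z[1], Fa @ (z[:2] - anchor)])
    return A, R


def continue_cycle_branch(
    system: PlanarSystem,
    c0: LimitCycle,
    param_name: str,
    param_range: tuple[float, float],
    step: float = 0.05,
    max_step: float = 0.5,
    min_step: float = 1e-7,
    max_points: int = 800,
    amp_min: float = 1e-4,
    period_max: float = 500.0,
    direction: int = +1,
    tol: float = CYCLE_TOL,
    hopf_ends: tuple[float, ...] = (),
    hopf_end_amp: float = 2e-2,
    max_param_reversals: int | None = None,
    points_after_reversal: int = 3,
) -> CycleBranch:
    """Pseudo-arclength continuation of the periodic BVP in one parameter.

    The period is an unknown; each accepted cycle carries Floquet multipliers
    and stability.  The branch terminates with a labelled reason when the
    amplitude collapses (Hopf end), the period blows up, the parameter leaves
    ``param_range`` or the corrector fails at the minimum step.  ``hopf_ends``
    lists parameter values of known Hopf points: the branch stops when it
    shrinks below ``hopf_end_amp`` close to one of them, instead of squeezing
    through the zero-amplitude neck and retracing itself.  When
    ``max_param_reversals`` is set, the branch stops ``points_after_reversal``
    accepted points after that many folds in the continuation parameter
    (cheap when only the first fold location is wanted).

    The corrector uses a frozen shooting Jacobian refreshed only on slow
    convergence, so each Newton sweep costs plain (non-variational) flows.
    """
    lo, hi = param_range
    branch = CycleBranch(param_name=param_name)
    branch.cycles.append(c0)
    branch.arclength.append(0.0)

    lam0 = get_param(c0.params, param_name)
    z = np.array([c0.y0[0], c0.y0[1], c0.period, lam0])
    prev_t = np.array([0.0, 0.0, 0.0, float(direction)])
    ds = step
    s = 0.0
    p0 = c0.params
    A_cache: np.ndarray | None = None
    anchor = z[:2].copy()
    Fa = system.rhs(anchor, set_param(p0, param_name, z[3]))
    n_reversals = 0
    last_dlam_sign = 0.0
    countdown: int | None = None

    def plain_residual(zz):
        params = set_param(p0, param_name, zz[3])
        yT, _, _, _ = _flow(system, params, zz[:2], zz[2])
        return np.array([yT[0] - zz[0], yT[1] - zz[1], Fa @ (zz[:2] - anchor)])

    while len(branch.cycles) < max_points:
        anchor = z[:2].copy()
        Fa = system.rhs(anchor, set_param(p0, param_name, z[3]))
        try:
            if A_cache is None:
                A_cache, _ = _branch_jacobian(system, p0, param_name, z, anchor, Fa)
            else:
                A_cache[2, :2] = Fa  # phase row moves with the anchor
        except (RuntimeError, ValueError) as exc:
            branch.termination = f"jacobian failure: {exc}"
            break
        Afull = np.vstack([A_cache, prev_t])
        try:
            t = np.linalg.solve(Afull, np.array([0.0, 0.0, 0.0, 1.0]))
        except np.linalg.LinAlgError:
            _, _, vt = np.linalg.svd(A_cache)
            t = vt[-1]
        if np.dot(t, prev_t) < 0:
            t = -t
        t = t / np.linalg.norm(t)

        z_new = None
        while ds >= min_step:
            z_pred = z + ds * t
            z_try = z_pred.copy()
            A = A_cache
            ok = False
            for it in range(15):
                try:
                    Ri = plain_residual(z_try)
                except (RuntimeError, ValueError):
                    break
                R = np.append(Ri, t @ (z_try - z_pred))
                if np.linalg.norm(R) < tol:
                    ok = True
                    break
                if it == 5:  # slow: refresh the Jacobian at the current iterate
                    try:
                        A, _ = _branch_jacobian(system, p0, param_name, z_try, anchor, Fa)
                    except (RuntimeError, ValueError):
                        break
                Aext = np.vstack([A, t])
                try:
                    stp = np.linalg.solve(Aext, -R)
                except np.linalg.LinAlgError:
                    break
                z_try = z_try + stp
                if not np.all(np.isfinite(z_try)) or z_try[2] <= 0:
                    break
            if ok:
                z_new = z_try
                break
            ds *= 0.5
        if z_new is None:
            branch.termination = "corrector failed at minimum step"
            break

        s += np.linalg.norm(z_new - z)
        prev_t = t
        z = z_new
        params = set_param(p0, param_name, z[3])
        try:
            A_cache, _ = _branch_jacobian(system, p0, param_name, z, z[:2], system.rhs(z[:2], params))
            M = A_cache[:2, :2] + np.eye(2)
            t_eval = np.linspace(0.0, z[2], _N_MESH)
            _, _, _, sol = _flow(system, params, z[:2], z[2], t_eval=t_eval)
            mults = np.linalg.eigvals(M)
            mults = mults[np.argsort(np.abs(mults - 1.0))]
            nontrivial = float(np.linalg.det(M))
            cyc = LimitCycle(
                y0=z[:2].copy(),
                period=float(z[2]),
                params=params,
                multipliers=mults,
                stability="stable" if abs(nontrivial) < 1.0 else "unstable",
                mesh_t=t_eval,
                mesh=sol.y[:2].T.copy(),
                closure_residual=0.0,
            )
        except (RuntimeError, ValueError) as exc:
            branch.termination = f"postprocessing failure: {exc}"
            break
        branch.cycles.append(cyc)
        branch.arclength.append(s)
        ds = min(ds * 1.3, max_step)

        amp = cyc.amplitude.max()
        if amp < 5.0 * hopf_end_amp:
            ds = min(ds, 0.05)  # resolve the shrinking neck near a Hopf endpoint
        if not lo <= z[3] <= hi:
            branch.termination = "parameter left range"
            break
        if amp < amp_min:
            branch.termination = "amplitude -> 0 (Hopf point reached)"
            break
        prev_amp = branch.cycles[-2].amplitude.max() if len(branch.cycles) >= 2 else 0.0
        if (
            amp < hopf_end_amp
            and amp < 0.98 * prev_amp  # shrinking, i.e. not just emerging from a Hopf
            and any(abs(z[3] - lh) < 0.2 for lh in hopf_ends)
        ):
            branch.termination = "amplitude -> 0 (Hopf point reached)"
            break
        if cyc.period > period_max:
            branch.termination = "period -> infinity"
            break
        if max_param_reversals is not None:
            dlam_sign = np.sign(t[3])
            if last_dlam_sign != 0.0 and dlam_sign != 0.0 and dlam_sign != last_dlam_sign:
                n_reversals += 1
                if n_reversals >= max_param_reversals and countdown is None:
                    countdown = points_after_reversal
            if dlam_sign != 0.0:
                last_dlam_sign = dlam_sign
            if countdown is not None:
                countdown -= 1
                if countdown <= 0:
                    branch.termination = "stopped after parameter fold"
                    break
    return branch


def refine_lpc(
    system: PlanarSystem,
    guess: LimitCycle,
    param_name: str,
    tol: float = 1e-9,
    max_iter: int = 25,
    min_amplitude: float = 1e-3,
) -> LimitCycle:
    """Newton solve of the extended fold-of-cycles system near ``guess``.

    Unknowns (y0, T, lambda); residuals: periodicity, phase anchored at the
    guess, and the fold condition log det M = 0 (nontrivial multiplier +1).
    The finite-difference Jacobian is frozen and refreshed only when the
    residual stalls.
    """
    p0 = guess.params
    anchor = guess.y0.copy()
    Fa = system.rhs(anchor, p0)
    z = np.array([guess.y0[0], guess.y0[1], guess.period, get_param(p0, param_name)])

    def residual(zz):
        R, _, _ = _cycle_residual(system, p0, param_name, zz, anchor, Fa, logdet=True)
        return R

    def fd_jacobian(zz, Rz):
        J = np.zeros((4, 4))
        for j in range(4):
            d = 1e-6 * max(1.0, abs(zz[j]))
            zp = zz.copy()
            zp[j] += d
            J[:, j] = (residual(zp) - Rz) / d
        return J

    R = residual(z)
    J = None
    prev_norm = np.inf
    for _ in range(max_iter):
        norm = np.linalg.norm(R)
        if np.linalg.norm(R[:3]) < tol and abs(R[3]) < 1e-8:
            break
        if J is None or norm > 0.2 * prev_norm:
            J = fd_jacobian(z, R)  # refresh whenever convergence is not fast
        prev_norm = norm
        try:
            step = np.linalg.solve(J, -R)
        except np.linalg.LinAlgError as exc:
            raise RuntimeError("singular extended-system Jacobian at LPC refinement") from exc
        z = z + step
        if not np.all(np.isfinite(z)) or z[2] <= 0:
            raise RuntimeError("LPC refinement diverged")
        R = residual(z)
    else:
        raise RuntimeError(f"LPC refinement did not converge (residual {np.linalg.norm(R):.2e})")
    params = set_param(p0, param_name, z[3])
    cyc = _finish_cycle(system, params, z[:2], z[2], np.linalg.norm(R[:2]))
    if cyc.amplitude.max() < min_amplitude:
        raise RuntimeError("fold refinement collapsed onto the degenerate Hopf family")
    return cyc


def detect_lpc(branch: CycleBranch, system: PlanarSystem) -> list[LPCPoint]:
    """Folds of the cycle branch: parameter-tangent sign changes, Newton-refined."""
    lams = branch.param_values
    if len(lams) < 3:
        return []
    dl = np.diff(lams)
    out: list[LPCPoint] = []
    for i in range(len(dl) - 1):
        if dl[i] * dl[i + 1] < 0:
            guess = branch.cycles[i + 1]
            if guess.amplitude.max() < 2e-3:
                continue  # zero-amplitude neck at a Hopf endpoint, not a fold
            try:
                cyc = refine_lpc(system, guess, branch.param_name)
            except RuntimeError:
                cyc = guess
            if abs(abs(cyc.nontrivial_multiplier) - 1.0) > LPC_TOL:
                continue
            side = f"{branch.cycles[i].stability}/{branch.cycles[i + 2].stability}"
            out.append(LPCPoint(cycle=cyc, param_name=branch.param_name, side=side))
    return out
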