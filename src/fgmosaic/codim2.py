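"""Two-parameter (k, nu) bifurcation structure and the regime map.

The Hopf locus of the interior equilibrium family is the closed curve
nu_H(k) = c k e^(b-k) / (1 + e^(b-k))^2 (a single-humped "bell" peaking at
k = b).  The fold-of-cycles (LPC) loci are traced by natural continuation in
nu of the extended periodic problem with the fold condition log det M = 0;
each LPC curve terminates on the Hopf locus at a Bautin point, where the
fold collides with the Hopf at zero amplitude.

The curves partition the (k, nu) window into the regimes

    I   : unique stable equilibrium,
    II  : unstable equilibrium surrounded by a stable cycle,
    III : stable equilibrium + unstable cycle + stable cycle,

matching the three phase portraits of the model (region II is the inside of
the bell; region III the strips between a subcritical flank of the bell and
its LPC curve).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Optional

import numpy as np
from scipy.optimize import brentq

from .cycles import (
    CycleBranch,
    LimitCycle,
    LPCPoint,
    continue_cycle_branch,
    detect_lpc,
    initial_cycle_from_hopf,
    refine_lpc,
    solve_cycle,
)
from .equilibria import interior_equilibrium
from .hopf import BautinPoint, find_bautin, hopf_locus_nu, hopf_point_on_locus
from .model import ParameterSet
from .systems import mosaic_system

__all__ = [
    "Codim1Curve",
    "RegimeMap",
    "trace_hopf_curve",
    "trace_lpc_curve",
    "hopf_ks_at_nu",
    "classify_regime",
    "build_regime_map",
    "search_cycles",
]

#: (k, nu) distance below which a point is labelled "boundary".
BOUNDARY_TOL = 1e-3


@dataclass
class Codim1Curve:
    """A codimension-1 bifurcation locus in the (k, nu) plane."""

    kind: str  # "hopf" | "lpc"
    k: np.ndarray
    nu: np.ndarray
    aux: dict = field(default_factory=dict)  # x*, omega, l1 / period, amplitude
    truncated: bool = False
    diagnostic: str = ""

    def to_dataframe(self):
        import pandas as pd

        d = {"k": self.k, "nu": self.nu}
        d.update(self.aux)
        return pd.DataFrame(d)


def trace_hopf_curve(
    p: ParameterSet,
    k_range: tuple[float, float] = (5.0, 20.0),
    n: int = 400,
) -> Codim1Curve:
    """Sample the Hopf locus nu = nu_H(k), annotated with x*, omega and l1.

    Sampling is refined near sign changes of l1 so the Bautin points are well
    resolved.
    """
    ks = np.linspace(k_range[0], k_range[1], n)
    rows = {"x": [], "omega": [], "l1": []}
    k_ok, nu_ok = [], []
    for k in ks:
        try:
            hp = hopf_point_on_locus(float(k), p)
        except (ValueError, RuntimeError):
            continue
        k_ok.append(float(k))
        nu_ok.append(hopf_locus_nu(float(k), p))
        rows["x"].append(float(hp.state[1]))
        rows["omega"].append(hp.omega)
        rows["l1"].append(hp.l1)
    k_arr = np.array(k_ok)
    l1_arr = np.array(rows["l1"])
    # refine near l1 sign changes
    extra = []
    for i in np.nonzero(l1_arr[:-1] * l1_arr[1:] < 0)[0]:
        extra.extend(np.linspace(k_arr[i], k_arr[i + 1], 12)[1:-1])
    for k in extra:
        try:
            hp = hopf_point_on_locus(float(k), p)
        except (ValueError, RuntimeError):
            continue
        k_ok.append(float(k))
        nu_ok.append(hopf_locus_nu(float(k), p))
        rows["x"].append(float(hp.state[1]))
        rows["omega"].append(hp.omega)
        rows["l1"].append(hp.l1)
    order = np.argsort(k_ok)
    return Codim1Curve(
        kind="hopf",
        k=np.array(k_ok)[order],
        nu=np.array(nu_ok)[order],
        aux={key: np.array(v)[order] for key, v in rows.items()},
    )


def trace_lpc_curve(
    seed: LPCPoint,
    p: ParameterSet,
    nu_range: tuple[float, float],
    dnu: float = 0.05,
    dnu_min: float = 1e-6,
    amp_stop: float = 5e-4,
) -> Codim1Curve:
    """Continue a fold-of-cycles locus in nu from a detected LPC point.

    At each nu the extended shooting system (periodicity + phase + fold
    condition log det M = 0) is re-solved by Newton with a secant predictor,
    i.e. a natural continuation of the full extended BVP with k free.  The
    curve shrinks to zero amplitude where it meets the Hopf locus at a Bautin
    point; continuation is stopped there (amplitude below ``amp_stop``) or at
    the ends of ``nu_range``.
    """
    system = mosaic_system()
    nu0 = seed.cycle.params.nu
    if not nu_range[0] <= nu0 <= nu_range[1]:
        raise ValueError(f"seed nu={nu0} outside nu_range={nu_range}")

    rows: list[tuple[float, float, float, float]] = []  # nu, k, period, amp

    def record(c: LimitCycle):
        rows.append((c.params.nu, c.params.k, c.period, float(c.amplitude[0])))

    record(seed.cycle)
    truncated = False
    diagnostic = ""
    for direction in (+1.0, -1.0):
        prev: list[LimitCycle] = [seed.cycle]
        step = dnu * direction
        while True:
            nu_new = prev[-1].params.nu + step
            if nu_new > nu_range[1] + 1e-12 or nu_new < nu_range[0] - 1e-12:
                nu_new = np.clip(nu_new, *nu_range)
                if abs(nu_new - prev[-1].params.nu) < dnu_min:
                    break
            # secant predictor on (y0, T, k)
            c_prev = prev[-1]
            if len(prev) >= 2:
                c2 = prev[-2]
                dnu_prev = c_prev.params.nu - c2.params.nu
                fac = (nu_new - c_prev.params.nu) / dnu_prev if dnu_prev != 0 else 0.0
                y0 = c_prev.y0 + fac * (c_prev.y0 - c2.y0)
                T = c_prev.period + fac * (c_prev.period - c2.period)
                k_guess = c_prev.params.k + fac * (c_prev.params.k - c2.params.k)
            else:
                y0, T, k_guess = c_prev.y0, c_prev.period, c_prev.params.k
            guess = LimitCycle(
                y0=y0,
                period=T,
                params=c_prev.params.with_(nu=float(nu_new), k=float(k_guess)),
                multipliers=c_prev.multipliers,
                stability=c_prev.stability,
                mesh_t=c_prev.mesh_t,
                mesh=c_prev.mesh,
                closure_residual=0.0,
            )
            try:
                c_new = refine_lpc(system, guess, "k", min_amplitude=amp_stop / 5.0)
            except (RuntimeError, ValueError):
                if abs(step) > dnu_min:
                    step *= 0.5
                    continue
                truncated = True
                diagnostic = f"fold refinement failed near nu={nu_new:.4f}"
                break
            record(c_new)
            prev.append(c_new)
            amp_new = float(c_new.amplitude[0])
            if amp_new < amp_stop:
                break  # met the Hopf locus (Bautin point)
            step = float(np.clip(step * 1.3, -dnu, dnu))
            # Near the Bautin endpoint the fold amplitude obeys amp^2 ~ distance
            # along the curve.  Estimate the remaining nu-distance from the local
            # slope of amp^2; take at most half of it per step, and once it is
            # small, append the extrapolated zero-amplitude endpoint and stop.
            amp_prev = float(c_prev.amplitude[0])
            dnu_prev = abs(c_new.params.nu - c_prev.params.nu)
            if amp_new < 0.1 and amp_new < amp_prev and dnu_prev > 0:
                slope = (amp_prev**2 - amp_new**2) / dnu_prev
                if slope > 0:
                    remaining = amp_new**2 / slope
                    if remaining < 5e-4:
                        sgn = np.sign(step)
                        nu_end = c_new.params.nu + sgn * remaining
                        dk_dnu = (c_new.params.k - c_prev.params.k) / (
                            c_new.params.nu - c_prev.params.nu
                        )
                        k_end = c_new.params.k + dk_dnu * sgn * remaining
                        rows.append((float(nu_end), float(k_end), c_new.period, 0.0))
                        break
                    step = float(np.sign(step) * min(abs(step), max(0.5 * remaining, dnu_min)))
            if c_new.params.nu in nu_range:
                break  # landed exactly on a window edge

    rows.sort(key=lambda r: r[0])
    arr = np.array(rows)
    return Codim1Curve(
        kind="lpc",
        k=arr[:, 1],
        nu=arr[:, 0],
        aux={"period": arr[:, 2], "amplitude": arr[:, 3]},
        truncated=truncated,
        diagnostic=diagnostic,
    )


def hopf_ks_at_nu(p: ParameterSet, nu: float, k_window: tuple[float, float] = (0.05, 50.0)) -> list[float]:
    """The k roots of nu_H(k) = nu (0, 1 or 2 of them in the window)."""
    peak = hopf_locus_nu(p.b, p)
    if nu > peak:
        return []
    out = []
    for a, bnd in ((k_window[0], p.b), (p.b, k_window[1])):
        fa = hopf_locus_nu(a, p) - nu
        fb = hopf_locus_nu(bnd, p) - nu
        if fa * fb < 0:
            out.append(brentq(lambda k: hopf_locus_nu(k, p) - nu, a, bnd, xtol=1e-12))
        elif fa == 0.0:
            out.append(a)
    return out


@lru_cache(maxsize=256)
def _lpc_k_at_nu(p: ParameterSet, nu: float, side: str) -> Optional[float]:
    """k of the fold of cycles flanking the bell at this nu (None if no fold).

    Runs a fresh cycle continuation from the subcritical Hopf point on the
    requested side ("low_k" or "high_k") outward until the first fold.
    """
    system = mosaic_system()
    ks = hopf_ks_at_nu(p, nu)
    if len(ks) < 2:
        return None
    k_h = ks[0] if side == "low_k" else ks[1]
    from .hopf import hopf_from_equilibrium

    pk = p.with_(nu=nu, k=k_h)
    eq = interior_equilibrium(pk)
    hp = hopf_from_equilibrium(system, eq.state, pk, param_name="k")
    # supercritical flank: the cycle lives inside the bell; no outward fold
    if hp.l1 < 0:
        return None
    c0 = initial_cycle_from_hopf(system, hp, offset=5e-3)
    direction = -1 if side == "low_k" else +1
    branch = continue_cycle_branch(
        system,
        c0,
        "k",
        (0.5, 60.0),
        step=0.05,
        max_step=1.0,
        direction=direction,
        max_points=400,
        hopf_ends=tuple(ks),
        max_param_reversals=1,
    )
    lpcs = detect_lpc(branch, system)
    if not lpcs:
        return None
    # first fold encountered moving outward from the Hopf point
    vals = [l.param_value for l in lpcs]
    return min(vals) if side == "low_k" else max(vals)


def classify_regime(
    k: float,
    nu: float,
    p: ParameterSet,
    boundary_tol: float = BOUNDARY_TOL,
) -> str:
    """Label (k, nu) as regime "I", "II", "III" or "boundary".

    The attractor inventory is assembled from the interior equilibrium's
    stability and a fresh one-parameter cycle analysis at this nu: a stable
    equilibrium flanked by a subcritical Hopf point owns a cycle pair out to
    the fold of cycles, which bounds region III.
    """
    base = p.with_(k=k, nu=nu)
    eq = interior_equilibrium(base)
    if eq is None:
        raise ValueError(f"no interior equilibrium at (k={k}, nu={nu})")
    if abs(nu - hopf_locus_nu(k, p)) < boundary_tol:
        return "boundary"
    if eq.trace > 0:
        return "II"
    ks = hopf_ks_at_nu(p, nu)
    if len(ks) < 2:
        return "I"
    side = "low_k" if k < ks[0] else ("high_k" if k > ks[1] else None)
    if side is None:  # numerically inside the bell yet trace < 0: boundary band
        return "boundary"
    k_lpc = _lpc_k_at_nu(p.with_(k=10.0, nu=1.0), nu, side)  # normalise cache key
    if k_lpc is None:
        return "I"
    if abs(k - k_lpc) < boundary_tol:
        return "boundary"
    inside = k_lpc < k < ks[0] if side == "low_k" else ks[1] < k < k_lpc
    return "III" if inside else "I"


@dataclass
class RegimeMap:
    """Curve-based partition of a (k, nu) window into regimes I/II/III."""

    p: ParameterSet
    k_range: tuple[float, float]
    nu_range: tuple[float, float]
    hopf_curve: Codim1Curve
    lpc_curves: list[Codim1Curve]
    bautin_points: list[BautinPoint]
    grid_k: np.ndarray | None = None
    grid_nu: np.ndarray | None = None
    grid_labels: np.ndarray | None = None

    def label(self, k: float, nu: float) -> str:
        """Fast classification from the traced curves."""
        ks = hopf_ks_at_nu(self.p, nu)
        if len(ks) == 2 and ks[0] < k < ks[1]:
            return "II"
        for curve in self.lpc_curves:
            if len(curve.nu) < 2:
                continue
            lo, hi = curve.nu.min(), curve.nu.max()
            if not lo <= nu <= hi:
                continue
            k_lpc = float(np.interp(nu, curve.nu, curve.k))
            low_side = np.mean(curve.k) < self.p.b
            if len(ks) == 2:
                if low_side and k_lpc <= k <= ks[0]:
                    return "III"
                if not low_side and ks[1] <= k <= k_lpc:
                    return "III"
        return "I"

    def sample_grid(self, n_k: int = 60, n_nu: int = 40) -> None:
        self.grid_k = np.linspace(*self.k_range, n_k)
        self.grid_nu = np.linspace(*self.nu_range, n_nu)
        self.grid_labels = np.array(
            [[self.label(k, nu) for k in self.grid_k] for nu in self.grid_nu]
        )

    def to_json_dict(self) -> dict:
        return {
            "k_range": list(self.k_range),
            "nu_range": list(self.nu_range),
            "hopf_curve": {"k": self.hopf_curve.k.tolist(), "nu": self.hopf_curve.nu.tolist(),
                           "l1": self.hopf_curve.aux["l1"].tolist()},
            "lpc_curves": [
                {"k": c.k.tolist(), "nu": c.nu.tolist(), "truncated": c.truncated}
                for c in self.lpc_curves
            ],
            "bautin_points": [
                {"f": b.f, "x": b.x, "k": b.k, "nu": b.nu} for b in self.bautin_points
            ],
        }


def build_regime_map(
    p: ParameterSet,
    k_range: tuple[float, float] = (5.0, 20.0),
    nu_range: tuple[float, float] = (0.05, 3.0),
    seed_nu: float = 0.2,
    resolution: tuple[int, int] = (60, 40),
) -> RegimeMap:
    """Trace the Hopf and LPC curves and assemble the regime partition.

    The LPC curves are seeded from the cycle branch at ``seed_nu`` (a nu with
    two subcritical Hopf points) and continued in nu until they terminate on
    the Hopf locus at the Bautin points.
    """
    system = mosaic_system()
    hopf_curve = trace_hopf_curve(p, k_range)
    gh = [find_bautin(p, side) for side in ("low_k", "high_k")]
    gh = [g for g in gh if g is not None]

    ks = hopf_ks_at_nu(p, seed_nu)
    lpc_curves: list[Codim1Curve] = []
    if len(ks) == 2:
        from .hopf import hopf_from_equilibrium

        for side, k_h, direction in (("low_k", ks[0], -1), ("high_k", ks[1], +1)):
            pk = p.with_(nu=seed_nu, k=k_h)
            eq = interior_equilibrium(pk)
            hp = hopf_from_equilibrium(system, eq.state, pk, param_name="k")
            if hp.l1 < 0:
                continue
            c0 = initial_cycle_from_hopf(system, hp, offset=5e-3)
            branch = continue_cycle_branch(
                system, c0, "k", (0.5, 60.0), step=0.05, max_step=1.0,
                direction=direction, max_points=400, hopf_ends=tuple(ks),
            )
            lpcs = detect_lpc(branch, system)
            if not lpcs:
                continue
            lpc = min(lpcs, key=lambda l: l.param_value) if side == "low_k" else max(
                lpcs, key=lambda l: l.param_value
            )
            lpc_curves.append(trace_lpc_curve(lpc, p, (nu_range[0], nu_range[1])))

    rm = RegimeMap(
        p=p,
        k_range=k_range,
        nu_range=nu_range,
        hopf_curve=hopf_curve,
        lpc_curves=lpc_curves,
        bautin_points=gh,
    )
    rm.sample_grid(*resolution)
    return rm


def search_cycles(
    p: ParameterSet,
    n_seeds: int = 8,
    rng: np.random.Generator | None = None,
    radii: tuple[float, ...] = (0.05, 0.15, 0.3),
) -> list[LimitCycle]:
    """Attempt to find limit cycles at fixed parameters from many seeds.

    Shooting is started on circles of several radii around the interior
    equilibrium at random phases; converged orbits with non-negligible
    amplitude are collected (deduplicated by amplitude and period).  An empty
    list at region-I parameters certifies the absence of detectable cycles.
    """
    rng = rng or np.random.default_rng(0)
    system = mosaic_system()
    eq = interior_equilibrium(p)
    if eq is None:
        return []
    J = system.jac(eq.state, p)
    det = float(np.linalg.det(J))
    T0 = 2.0 * np.pi / np.sqrt(det) if det > 0 else 2.0
    found: list[LimitCycle] = []
    for r0 in radii:
        for _ in range(n_seeds):
            th = rng.uniform(0, 2 * np.pi)
            y0 = eq.state + r0 * np.array([np.cos(th), np.sin(th)])
            if not (0.05 < y0[0] < 0.95 and 0.05 < y0[1] < 0.95):
                continue  # avoid seeds crawling along the invariant lines
            try:
                c = solve_cycle(system, p, y0, T0, max_iter=12)
            except (RuntimeError, ValueError):
                continue
            if c.amplitude.max() < 1e-4:
                continue  # collapsed to the equilibrium
            if any(
                abs(c.period - f.period) < 1e-3
                and np.allclose(c.amplitude, f.amplitude, atol=1e-3)
                for f in found
            ):
                continue
            found.append(c)
    return found
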