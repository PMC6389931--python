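"""Time integration, shift experiments and basin membership.

The shift experiments reproduce the two qualitatively different transitions
the model supports: a *catastrophic* shift, where a state kick across the
separatrix (the unstable cycle) or a parameter step past a subcritical Hopf
or fold-of-cycles throws the system onto a distant large-amplitude
attractor, and a *smooth* shift, where the attractor amplitude deforms
continuously as the parameter moves through a supercritical Hopf.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Optional

import numpy as np
from scipy.integrate import solve_ivp

from .model import F_DOMAIN_MAX, ParameterSet
from .systems import PlanarSystem, get_param, mosaic_system, set_param

__all__ = [
    "Trajectory",
    "ShiftProtocol",
    "ShiftResult",
    "integrate",
    "asymptotic_amplitude",
    "shift_experiment",
    "basin_membership",
]

_RTOL = 1e-10
_ATOL = 1e-10

#: Default horizon (years) for attractor settling.
T_MAX = 2000.0

#: Post/pre amplitude ratio above which a shift is called catastrophic.
AMPLITUDE_JUMP_RATIO = 5.0

#: Amplitude floor (in f units) so that near-zero pre-shift amplitudes do not
#: make every emerging oscillation look like a jump.
AMPLITUDE_FLOOR = 0.05


@dataclass
class Trajectory:
    """An integrated orbit with its integrator settings recorded."""

    t: np.ndarray
    states: np.ndarray  # (n, 2)
    params: Any
    rtol: float = _RTOL
    atol: float = _ATOL
    domain_exit: bool = False

    @property
    def f(self) -> np.ndarray:
        return self.states[:, 0]

    @property
    def x(self) -> np.ndarray:
        return self.states[:, 1]

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame({"t": self.t, "f": self.f, "x": self.x})

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def integrate(
    state0,
    p: Any,
    t_span: tuple[float, float],
    system: PlanarSystem | None = None,
    n_out: int = 2000,
    rtol: float = _RTOL,
    atol: float = _ATOL,
) -> Trajectory:
    """Adaptive integration with dense output; terminates on domain exit (f -> 1)."""
    system = system or mosaic_system()

    def exit_high(t, y):
        return F_DOMAIN_MAX - y[0]

    def exit_low(t, y):
        # deforestation (-J > 0 reversed) can push f through 0: leave the domain
        return y[0]

    exit_high.terminal = True
    exit_high.direction = -1
    exit_low.terminal = True
    exit_low.direction = -1

    if system.name == "mosaic":
        from .model import _rhs_unchecked

        fun = lambda t, y: _rhs_unchecked(y, p)  # tolerant to trial steps past f=0
        events = [exit_high, exit_low]
    else:
        fun = lambda t, y: system.rhs(y, p)
        events = None
    sol = solve_ivp(
        fun,
        t_span,
        np.asarray(state0, float),
        method="DOP853",
        rtol=rtol,
        atol=atol,
        t_eval=np.linspace(t_span[0], t_span[1], n_out),
        events=events,
    )
    return Trajectory(
        t=sol.t,
        states=sol.y.T.copy(),
        params=p,
        rtol=rtol,
        atol=atol,
        domain_exit=(sol.status == 1),
    )


def asymptotic_amplitude(traj: Trajectory, tail_frac: float = 0.2, component: int = 0) -> float:
    """Peak-to-peak amplitude over the trailing fraction of a trajectory."""
    n = len(traj.t)
    tail = traj.states[int((1 - tail_frac) * n):, component]
    return float(tail.max() - tail.min())


def _settle(state0, p, system, t_max=T_MAX, block=100.0, amp_tol=1e-4):
    """Integrate in blocks until the amplitude is steady, return final block."""
    y = np.asarray(state0, float)
    t = 0.0
    prev_amp = None
    traj = None
    while t < t_max:
        traj = integrate(y, p, (0.0, block), system=system, n_out=500)
        if traj.domain_exit:
            return traj, float("nan"), False
        y = traj.states[-1]
        t += block
        amp = asymptotic_amplitude(traj, tail_frac=1.0)
        if prev_amp is not None and abs(amp - prev_amp) < amp_tol:
            return traj, amp, True
        prev_amp = amp
    return traj, prev_amp if prev_amp is not None else 0.0, False


@dataclass
class ShiftProtocol:
    """One perturbation applied at t_perturb: a state kick or a parameter step."""

    params: ParameterSet
    t_perturb: float = 100.0
    state_kick: Optional[tuple[float, float]] = None
    param_step: Optional[tuple[str, float]] = None  # (name, new value)
    initial_state: Optional[tuple[float, float]] = None

    def __post_init__(self):
        if self.t_perturb <= 0:
            raise ValueError("t_perturb must be positive")
        if (self.state_kick is None) == (self.param_step is None):
            # exactly one perturbation kind; a zero-magnitude kick still counts
            raise ValueError("specify exactly one of state_kick or param_step")


@dataclass
class ShiftResult:
    classification: str  # "smooth" | "catastrophic" | "undecided"
    pre_amplitude: float
    post_amplitude: float
    amplitude_trace: np.ndarray  # (n, 2): time, running amplitude
    trajectory: Trajectory


def _quasi_static_amplitudes(p, name, old, new, start_state, system, n_steps=16):
    """Settled amplitudes along a gradual parameter path old -> new."""
    amps = []
    y = np.asarray(start_state, float)
    for lam in np.linspace(old, new, n_steps + 1)[1:]:
        pp = set_param(p, name, float(lam))
        traj, amp, _ = _settle(y, pp, system, t_max=600.0)
        y = traj.states[-1]
        amps.append(amp)
    return np.array(amps)


def shift_experiment(
    protocol: ShiftProtocol,
    system: PlanarSystem | None = None,
    t_max: float = T_MAX,
) -> ShiftResult:
    """Run a perturbation experiment and classify the induced transition.

    The system is settled on its attractor before ``t_perturb``; the
    perturbation is applied; the post-perturbation attractor is settled.  A
    state kick is catastrophic when the asymptotic amplitude jumps by more
    than the threshold ratio over the pre-perturbation attractor.  A
    parameter step is judged by re-running the path quasi-statically: the
    shift is smooth when the settled amplitude deforms continuously
    (no adjacent jump beyond the threshold) along the gradual path, and
    catastrophic otherwise.
    """
    system = system or mosaic_system()
    p = protocol.params
    eq_guess = protocol.initial_state
    if eq_guess is None:
        from .equilibria import interior_equilibrium

        eq = interior_equilibrium(p)
        eq_guess = eq.state + np.array([1e-3, 1e-3]) if eq is not None else np.array([0.6, 0.6])
    pre = integrate(eq_guess, p, (0.0, protocol.t_perturb), system=system)
    if pre.domain_exit:
        return ShiftResult("undecided", np.nan, np.nan, np.empty((0, 2)), pre)
    pre_amp = asymptotic_amplitude(pre, tail_frac=0.2)
    y_perturb = pre.states[-1].copy()

    if protocol.state_kick is not None:
        y_perturb = y_perturb + np.asarray(protocol.state_kick, float)
        y_perturb = np.clip(y_perturb, [0.0, 0.0], [F_DOMAIN_MAX - 1e-6, 1.0])
        p_post = p
    else:
        name, new = protocol.param_step
        p_post = set_param(p, name, float(new))

    post, post_amp, settled = _settle(y_perturb, p_post, system, t_max=t_max)
    if not settled and not np.isfinite(post_amp):
        return ShiftResult("undecided", pre_amp, post_amp, np.empty((0, 2)), post)

    denom = max(pre_amp, AMPLITUDE_FLOOR)
    if protocol.state_kick is not None:
        if np.allclose(protocol.state_kick, 0.0):
            cls = "smooth"
        else:
            cls = "catastrophic" if post_amp / denom > AMPLITUDE_JUMP_RATIO else "smooth"
    else:
        name, new = protocol.param_step
        amps = _quasi_static_amplitudes(p, name, get_param(p, name), new, pre.states[-1], system)
        path = np.concatenate([[pre_amp], amps])
        jumps = np.abs(np.diff(path))
        base = np.maximum(path[:-1], AMPLITUDE_FLOOR)
        cls = "catastrophic" if np.any(jumps / base > AMPLITUDE_JUMP_RATIO - 1.0) else "smooth"

    n = len(post.t)
    win = max(n // 20, 2)
    amp_trace = np.array(
        [
            [post.t[i], post.states[max(0, i - win): i + 1, 0].max() - post.states[max(0, i - win): i + 1, 0].min()]
            for i in range(win, n, win)
        ]
    )
    return ShiftResult(cls, pre_amp, post_amp, amp_trace, post)


def basin_membership(
    state0,
    p: ParameterSet,
    system: PlanarSystem | None = None,
    t_max: float = T_MAX,
    eq_tol: float = 1e-4,
) -> str:
    """Decide whether an orbit settles on the equilibrium or the stable cycle.

    Meaningful in the bistable regime III, where the unstable cycle separates
    the two basins.  Returns "equilibrium", "cycle" or "undecided".
    """
    from .equilibria import interior_equilibrium

    system = system or mosaic_system()
    eq = interior_equilibrium(p)
    traj, amp, settled = _settle(state0, p, system, t_max=t_max)
    if traj.domain_exit or not settled:
        return "undecided"
    final = traj.states[-1]
    if eq is not None and np.linalg.norm(final - eq.state) < eq_tol and amp < eq_tol:
        return "equilibrium"
    if amp > 1e-3:
        return "cycle"
    return "undecided"
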