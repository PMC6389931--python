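"""Matplotlib rendering of 1D bifurcation diagrams and the regime map.

Conventions: solid/dashed lines are stable/unstable equilibria; filled/empty
circles are stable/unstable limit cycles; H marks Hopf points, LPC folds of
cycles, GH Bautin points.
"""

from __future__ import annotations

import numpy as np

from .codim2 import RegimeMap
from .cycles import CycleBranch, LPCPoint
from .equilibria import EquilibriumBranch
from .hopf import HopfPoint


def plot_branch_diagram(
    branch: EquilibriumBranch,
    cycle_branches: list[CycleBranch] | None = None,
    hopf_points: list[HopfPoint] | None = None,
    lpc_points: list[LPCPoint] | None = None,
    component: int = 1,
    ax=None,
):
    """1D bifurcation diagram: state component vs continuation parameter."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 5))
    lam = branch.param_values
    y = branch.states[:, component]
    stable = np.array([e.stability == "stable" for e in branch.points])
    for seg_stable, style in ((True, "-"), (False, "--")):
        ym = np.where(stable == seg_stable, y, np.nan)
        ax.plot(lam, ym, "k" + style, lw=1.5,
                label="stable equilibrium" if seg_stable else "unstable equilibrium")
    for cb in cycle_branches or []:
        for c in cb.cycles:
            lo, hi = c.mesh[:, component].min(), c.mesh[:, component].max()
            mfc = "tab:green" if c.stability == "stable" else "none"
            ax.plot([getattr(c.params, cb.param_name)] * 2, [lo, hi], marker="o",
                    color="tab:green", mfc=mfc, ms=4, lw=0)
    for hp in hopf_points or []:
        ax.plot(hp.param_value, hp.state[component], "rs", ms=7)
        ax.annotate("H", (hp.param_value, hp.state[component]), textcoords="offset points",
                    xytext=(4, 6), color="r")
    for lp in lpc_points or []:
        yv = lp.cycle.mesh[:, component].max()
        ax.plot(lp.param_value, yv, "b^", ms=7)
        ax.annotate("LPC", (lp.param_value, yv), textcoords="offset points",
                    xytext=(4, 6), color="b")
    ax.set_xlabel(branch.param_name)
    ax.set_ylabel(["f", "x"][component])
    ax.legend(loc="best", fontsize=8)
    return ax


def plot_regime_map(rm: RegimeMap, ax=None):
    """(k, nu) diagram: Hopf bell, LPC side curves, Bautin points, region labels."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 5))
    hc = rm.hopf_curve
    sup = hc.aux["l1"] < 0
    ax.plot(hc.k, np.where(~sup, hc.nu, np.nan), "r-", lw=1.5, label="Hopf (subcritical)")
    ax.plot(hc.k, np.where(sup, hc.nu, np.nan), "r--", lw=1.5, label="Hopf (supercritical)")
    for i, c in enumerate(rm.lpc_curves):
        ax.plot(c.k, c.nu, "b-", lw=1.2, label="LPC" if i == 0 else None)
    for g in rm.bautin_points:
        ax.plot(g.k, g.nu, "ko", ms=7)
        ax.annotate("GH", (g.k, g.nu), textcoords="offset points", xytext=(5, 5))
    if rm.grid_labels is not None:
        for lab, (fx, fy) in (("I", (0.85, 0.5)), ("II", (0.45, 0.2)), ("III", (0.1, 0.08))):
            ax.text(
                rm.k_range[0] + fx * (rm.k_range[1] - rm.k_range[0]),
                rm.nu_range[0] + fy * (rm.nu_range[1] - rm.nu_range[0]),
                lab, fontsize=13, ha="center",
            )
    ax.set_xlabel("k")
    ax.set_ylabel("nu")
    ax.set_xlim(*rm.k_range)
    ax.set_ylim(*rm.nu_range)
    ax.legend(loc="upper right", fontsize=8)
    return ax
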