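"""Optional rendering: phase portraits with nullclines, and time series."""

from __future__ import annotations

import numpy as np

from .dynamics import Trajectory
from .equilibria import find_equilibria
from .model import ModelParams, Variant, nullclines

__all__ = ["plot_phase_portrait", "plot_time_series"]


def plot_phase_portrait(trajectory: Trajectory, ax=None, n_null: int = 400):
    """Trajectory in the (W, Z) plane; autonomous runs get nullclines and equilibria."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    params: ModelParams = trajectory.params
    ax.plot(trajectory.W, trajectory.Z, lw=0.8, color="C0", label="trajectory")
    if params.variant is Variant.AUTONOMOUS:
        pad = 0.08 * (np.ptp(trajectory.W) or 1.0)
        Wg = np.linspace(trajectory.W.min() - pad, trajectory.W.max() + pad, n_null)
        zc_W, zc_Z = nullclines(params, Wg)
        ax.plot(Wg, zc_W, "--", color="C1", lw=1, label="W-nullcline")
        ax.plot(Wg, zc_Z, "--", color="C2", lw=1, label="Z-nullcline")
        for eq in find_equilibria(params):
            marker = "o" if eq.stability.is_stable else "x"
            ax.plot([eq.W], [eq.Z], marker, color="k", ms=6)
        ax.set_ylim(
            min(trajectory.Z.min(), 0) - pad,
            trajectory.Z.max() + 10 * pad,
        )
    ax.set_xlabel("W (membrane potential)")
    ax.set_ylabel("Z (recovery)")
    ax.legend(loc="best", fontsize="small")
    return ax


def plot_time_series(trajectory: Trajectory, ax=None):
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(trajectory.times, trajectory.W, lw=0.8)
    ax.set_xlabel("t")
    ax.set_ylabel("W (membrane potential)")
    return ax
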