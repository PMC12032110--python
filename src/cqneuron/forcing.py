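"""Periodically forced dynamics: Lyapunov exponents, sweeps, firing regimes.

With the drive ``E(t) = F sin(omega t) + 70`` the rescaled model becomes a
nonautonomous planar flow; time enters as an explicit phase, and the
largest Lyapunov exponent (LLE) is estimated with the two-trajectory
Benettin scheme — a fiducial orbit and a companion offset by ``d0`` in
the (W, Z) plane, renormalised back to ``d0`` at fixed intervals while
accumulating log stretch factors.  Because the companion shares the
fiducial's clock, neutral growth along the forcing phase never enters
the estimate.

Regimes are labelled from the spike train: upward crossings of ``W = 2``
(re-armed below ``W = 0``; the spikes of this model top out near W = 6
and rest near W = -4).  No spikes is quiescent; a converged positive LLE
is chaotic; a bimodal interspike-interval (ISI) distribution — largest
ISI gap ratio >= 3, separating intra-burst from inter-burst intervals —
is bursting; anything else is tonic spiking.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import _kernels
from .dynamics import Trajectory
from .model import DivergenceError, ModelParams, State, Variant

__all__ = [
    "LyapunovSettings",
    "LyapunovEstimate",
    "Regime",
    "RegimeLabel",
    "SweepSettings",
    "SweepDiagram",
    "SPIKE_THRESHOLD",
    "SPIKE_REARM",
    "forced_params",
    "forced_simulate",
    "largest_lyapunov",
    "sweep_diagram",
    "spike_times",
    "classify_regime",
]

SPIKE_THRESHOLD = 2.0
SPIKE_REARM = 0.0


def forced_params(F: float, omega: float) -> ModelParams:
    return ModelParams(variant=Variant.FORCED, F=F, omega=omega)


def forced_simulate(
    F: float,
    omega: float,
    initial: State = State(0.0, 0.0),
    t_end: float = 200.0,
    dt: float = 5.0e-4,
    *,
    sample_stride: int = 1,
) -> Trajectory:
    """Integrate the forced model (fixed-step RK4); deterministic."""
    from .dynamics import integrate

    return integrate(
        forced_params(F, omega), initial, t_end, dt, sample_stride=sample_stride
    )


@dataclass(frozen=True)
class LyapunovSettings:
    """Benettin-estimate knobs (all in model time units)."""

    transient: float = 200.0
    horizon: float = 2000.0
    dt: float = 5.0e-4
    renorm_interval: float = 0.5
    d0: float = 1.0e-8
    direction: tuple[float, float] = (1.0, 0.0)
    initial: tuple[float, float] = (0.5, 0.5)
    #: converged when the final 20% of the running estimate has spread
    #: below this fraction of max(1, |value|)
    convergence_band: float = 0.05


@dataclass
class LyapunovEstimate:
    """LLE value (per unit model time) with its convergence trace."""

    value: float
    convergence_series: np.ndarray
    converged: bool
    settings: LyapunovSettings

    @property
    def spread(self) -> float:
        k = max(1, len(self.convergence_series) // 5)
        tail = self.convergence_series[-k:]
        return float(np.max(tail) - np.min(tail))


def largest_lyapunov(
    F: float, omega: float, settings: LyapunovSettings | None = None
) -> LyapunovEstimate:
    """Largest Lyapunov exponent of the forced flow at (F, omega)."""
    if F < 0 or omega <= 0:
        raise ValueError("require F >= 0 and omega > 0")
    s = settings or LyapunovSettings()
    dirW, dirZ = s.direction
    norm = float(np.hypot(dirW, dirZ))
    running, _, _, diverged = _kernels.benettin_forced(
        float(F), float(omega), s.initial[0], s.initial[1],
        s.transient, s.horizon, s.dt, s.renorm_interval, s.d0,
        dirW / norm, dirZ / norm,
    )
    if diverged:
        raise DivergenceError("forced trajectory diverged during LLE estimation")
    value = float(running[-1])
    k = max(1, len(running) // 5)
    tail = running[-k:]
    converged = bool(
        np.max(tail) - np.min(tail) < s.convergence_band * max(1.0, abs(value))
    )
    return LyapunovEstimate(value, running, converged, s)


class Regime(str, enum.Enum):
    QUIESCENT = "quiescent"
    SPIKING = "spiking"
    BURSTING = "bursting"
    CHAOTIC = "chaotic"


@dataclass
class RegimeLabel:
    """Categorical firing regime with the evidence it was read from."""

    label: Regime
    evidence: dict = field(default_factory=dict)


def spike_times(
    trajectory: Trajectory,
    threshold: float = SPIKE_THRESHOLD,
    rearm: float = SPIKE_REARM,
) -> np.ndarray:
    """Upward threshold crossings with hysteresis (re-arm below ``rearm``)."""
    W = trajectory.W
    t = trajectory.times
    armed = W[0] < threshold
    out = []
    for i in range(1, len(W)):
        if armed and W[i] >= threshold and W[i - 1] < threshold:
            frac = (threshold - W[i - 1]) / (W[i] - W[i - 1])
            out.append(t[i - 1] + frac * (t[i] - t[i - 1]))
            armed = False
        elif not armed and W[i] < rearm:
            armed = True
    return np.asarray(out)


def classify_regime(
    trajectory: Trajectory,
    lle: LyapunovEstimate | None = None,
    *,
    burst_gap_ratio: float = 3.0,
) -> RegimeLabel:
    """Label a post-transient forced trajectory.

    Precedence: no spikes -> quiescent; converged positive LLE ->
    chaotic; bimodal ISIs (largest consecutive gap ratio in the sorted
    ISIs >= ``burst_gap_ratio``) -> bursting; otherwise spiking.
    Raises ``ValueError`` when the trajectory spans fewer than ten
    forcing periods — too little evidence to call a regime.
    """
    params = trajectory.params
    if params.variant is not Variant.FORCED:
        raise ValueError("regime classification applies to forced trajectories")
    span = trajectory.times[-1] - trajectory.times[0]
    if span < 10.0 * 2.0 * np.pi / params.omega:
        raise ValueError("trajectory shorter than 10 forcing periods")

    spikes = spike_times(trajectory)
    isi = np.diff(spikes)
    evidence: dict = {"n_spikes": int(spikes.size)}
    if spikes.size == 0:
        return RegimeLabel(Regime.QUIESCENT, evidence)
    if isi.size:
        evidence["isi_mean"] = float(np.mean(isi))
        evidence["isi_cv"] = float(np.std(isi) / np.mean(isi))
    if lle is not None:
        evidence["lle"] = lle.value
        evidence["lle_converged"] = lle.converged
        if lle.converged and lle.value > lle.spread:
            return RegimeLabel(Regime.CHAOTIC, evidence)
    if isi.size >= 3:
        s = np.sort(isi)
        ratios = s[1:] / np.maximum(s[:-1], 1.0e-12)
        evidence["isi_gap_ratio"] = float(np.max(ratios))
        if np.max(ratios) >= burst_gap_ratio:
            return RegimeLabel(Regime.BURSTING, evidence)
    return RegimeLabel(Regime.SPIKING, evidence)


@dataclass(frozen=True)
class SweepSettings:
    """Per-grid-point budgets of a forcing-parameter sweep.

    The sweep warm-starts each grid point from the previous point's
    final state (continuation), discards a transient, then records
    stroboscopic samples ``W(2 pi k / omega)`` and a Benettin LLE with a
    shorter horizon than the stand-alone estimator.
    """

    transient: float = 100.0
    n_strobe: int = 200
    dt: float = 1.0e-3
    lyapunov: LyapunovSettings = field(
        default_factory=lambda: LyapunovSettings(transient=100.0, horizon=400.0, dt=1.0e-3)
    )


@dataclass
class SweepDiagram:
    """Stroboscopic bifurcation diagram plus LLE along a parameter grid."""

    parameter: str  # "F" or "omega"
    grid: np.ndarray
    strobe: list[np.ndarray]  # per grid point, W at forcing-period multiples
    lle: np.ndarray
    diverged: np.ndarray  # bool per grid point

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for p, samples, lle in zip(self.grid, self.strobe, self.lle):
            for i, w in enumerate(samples):
                rows.append(
                    {self.parameter: p, "sample_index": i, "W_sample": w, "lle": lle}
                )
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def n_distinct(self, i: int, tol: float = 1.0e-3) -> int:
        """Number of distinct stroboscopic values at grid point ``i``."""
        s = np.sort(self.strobe[i])
        if s.size == 0:
            return 0
        return int(1 + np.sum(np.diff(s) > tol * max(1.0, float(np.ptp(s) or 1.0))))


def sweep_diagram(
    sweep: str,
    fixed_other: float,
    grid,
    settings: SweepSettings | None = None,
) -> SweepDiagram:
    """Sweep ``F`` (at fixed omega) or ``omega`` (at fixed F) over ``grid``."""
    if sweep not in ("F", "omega"):
        raise ValueError("sweep must be 'F' or 'omega'")
    s = settings or SweepSettings()
    grid = np.asarray(grid, dtype=float)
    if np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be strictly increasing")

    strobe: list[np.ndarray] = []
    lles = np.full(grid.size, np.nan)
    diverged = np.zeros(grid.size, dtype=bool)
    W, Z = 0.5, 0.5
    for i, p in enumerate(grid):
        F, omega = (p, fixed_other) if sweep == "F" else (fixed_other, p)
        if omega <= 0:
            raise ValueError("omega must be > 0 throughout the grid")
        T = 2.0 * np.pi / omega
        steps_per_period = max(4, int(np.ceil(T / s.dt)))
        n_tr = max(1, int(np.ceil(s.transient / T)))
        _, W1, Z1, div_tr = _kernels.strobe_forced(
            float(F), float(omega), W, Z, 0.0, n_tr, steps_per_period
        )
        if div_tr:
            diverged[i] = True
            strobe.append(np.empty(0))
            W, Z = 0.5, 0.5  # reseed after blow-up
            continue
        samples, W2, Z2, div = _kernels.strobe_forced(
            float(F), float(omega), W1, Z1, n_tr * T, s.n_strobe, steps_per_period
        )
        strobe.append(np.asarray(samples))
        diverged[i] = bool(div)
        if not div:
            W, Z = float(W2), float(Z2)  # continuation warm start
            ls = replace(s.lyapunov, initial=(W, Z))
            try:
                lles[i] = largest_lyapunov(F, omega, ls).value
            except DivergenceError:
                diverged[i] = True
        else:
            W, Z = 0.5, 0.5
    return SweepDiagram(sweep, grid, strobe, lles, diverged)
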