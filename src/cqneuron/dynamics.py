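"""Trajectories, limit cycles, trapping regions and global saddle-node type.

The default integrator is fixed-step RK4 at ``dt = 1e-3``: the fastest
contraction rate observed along the equilibrium branches is |Re lambda| of
a few hundred, which keeps the scheme comfortably inside its stability
region, and a fixed step makes every run bit-reproducible.  An adaptive
mode (SciPy RK45) is available for stiff settings such as very small tau.

Limit cycles are measured on a Poincare section: the vertical line
``W = W_section`` (an equilibrium abscissa by default), crossed with W
increasing.  Crossing times are refined by linear interpolation, the
period is the spacing of successive crossings, and the cycle is accepted
as converged once the last few periods agree to a relative tolerance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .bifurcation import BifurcationPoint
from .equilibria import find_equilibria
from .model import DivergenceError, ModelParams, State, Variant

__all__ = [
    "Trajectory",
    "LimitCycle",
    "CycleSettings",
    "TrappingReport",
    "STANDARD_INITIAL_CONDITIONS",
    "integrate",
    "detect_limit_cycle",
    "verify_trapping_region",
    "classify_saddle_node_globality",
]

#: Initial-condition fixture used wherever "all initial conditions" is meant;
#: the ten points straddle both attraction basins of the bistable regime.
STANDARD_INITIAL_CONDITIONS: tuple[tuple[float, float], ...] = (
    (-6.0, 0.0),
    (-3.0, 0.0),
    (0.0, 0.0),
    (3.0, 0.0),
    (6.0, 0.0),
    (0.0, 50.0),
    (0.0, 150.0),
    (3.0, 150.0),
    (-3.0, 100.0),
    (5.0, 100.0),
)


@dataclass
class Trajectory:
    """A time-stamped (W, Z) path and the inputs that produced it."""

    times: np.ndarray
    W: np.ndarray
    Z: np.ndarray
    params: ModelParams
    initial_state: State
    integrator_meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if not (len(self.times) == len(self.W) == len(self.Z)):
            raise ValueError("times, W, Z must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if not (
            np.all(np.isfinite(self.W)) and np.all(np.isfinite(self.Z))
        ):
            raise ValueError("non-finite trajectory samples")

    @property
    def final_state(self) -> State:
        return State(float(self.W[-1]), float(self.Z[-1]), float(self.times[-1]))

    def after(self, t: float) -> "Trajectory":
        """The portion of the trajectory with ``times >= t``."""
        i = int(np.searchsorted(self.times, t))
        return Trajectory(
            self.times[i:], self.W[i:], self.Z[i:],
            self.params, self.initial_state, self.integrator_meta,
        )

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame({"t": self.times, "W": self.W, "Z": self.Z}).to_csv(
            path, index=False
        )


def integrate(
    params: ModelParams,
    initial: State,
    t_end: float,
    dt: float = 1.0e-3,
    *,
    method: str = "rk4",
    sample_stride: int = 1,
) -> Trajectory:
    """Integrate from ``initial`` for ``t_end`` time units.

    ``method='rk4'`` (default) is the fixed-step compiled kernel;
    ``method='adaptive'`` uses SciPy's RK45 with tight tolerances.
    Blow-up (|W| > 1e3) raises :class:`DivergenceError` carrying the last
    finite state.
    """
    if dt <= 0 or t_end < 0:
        raise ValueError("dt must be > 0 and t_end >= 0")
    if t_end == 0:
        return Trajectory(
            np.array([initial.t]),
            np.array([initial.W]),
            np.array([initial.Z]),
            params,
            initial,
            {"method": method, "dt": dt},
        )
    n_steps = int(round(t_end / dt))
    if method == "rk4":
        if params.variant is Variant.FORCED:
            ts, Ws, Zs, div = _kernels.rk4_forced(
                params.F, params.omega, initial.W, initial.Z,
                initial.t, n_steps, dt, sample_stride,
            )
        else:
            ts, Ws, Zs, div = _kernels.rk4_autonomous(
                params.E, params.v, params.tau, initial.W, initial.Z,
                initial.t, n_steps, dt, sample_stride,
            )
        if div >= 0:
            raise DivergenceError(
                f"trajectory diverged near t={ts[div]:.4g}",
                State(float(Ws[div]), float(Zs[div]), float(ts[div])),
            )
        meta = {"method": "rk4", "dt": dt, "stride": sample_stride}
        return Trajectory(ts, Ws, Zs, params, initial, meta)
    if method == "adaptive":
        from scipy.integrate import solve_ivp

        from .model import vector_field

        def rhs(t, y):
            return vector_field(State(y[0], y[1], t), params)

        t_eval = initial.t + np.arange(n_steps // sample_stride + 1) * dt * sample_stride
        sol = solve_ivp(
            rhs, (initial.t, initial.t + t_end), [initial.W, initial.Z],
            t_eval=t_eval, rtol=1.0e-9, atol=1.0e-11, method="RK45",
        )
        if not sol.success or np.max(np.abs(sol.y[0])) > _kernels.BLOWUP:
            k = int(np.argmax(np.abs(sol.y[0]) > _kernels.BLOWUP)) or -1
            raise DivergenceError(
                "adaptive integration diverged",
                State(float(sol.y[0][k]), float(sol.y[1][k]), float(sol.t[k])),
            )
        meta = {"method": "adaptive", "dt": dt, "rtol": 1.0e-9, "atol": 1.0e-11}
        return Trajectory(sol.t, sol.y[0], sol.y[1], params, initial, meta)
    raise ValueError(f"unknown method {method!r}")


@dataclass
class LimitCycle:
    """A detected stable periodic orbit."""

    period: float
    W_min: float
    W_max: float
    mean_orbit: np.ndarray  # (n, 2) samples of one cycle
    converged: bool
    section_W: float
    n_crossings: int

    @property
    def amplitude(self) -> float:
        return self.W_max - self.W_min

    def encloses(self, W: float, Z: float) -> bool:
        """Winding-number test: does the closed orbit wind once around (W, Z)?"""
        x = self.mean_orbit[:, 0] - W
        y = self.mean_orbit[:, 1] - Z
        ang = np.unwrap(np.arctan2(y, x))
        return abs((ang[-1] - ang[0]) / (2.0 * np.pi)) > 0.5

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "period": self.period,
                    "W_min": self.W_min,
                    "W_max": self.W_max,
                    "converged": self.converged,
                    "section_W": self.section_W,
                    "n_crossings": self.n_crossings,
                },
                fh,
                indent=2,
            )


@dataclass(frozen=True)
class CycleSettings:
    """Knobs of the Poincare-section cycle detector."""

    t_end: float = 200.0
    dt: float = 1.0e-3
    transient_fraction: float = 0.5
    period_rtol: float = 1.0e-4
    min_crossings: int = 4
    section_W: float | None = None  # default: an equilibrium abscissa
    method: str = "rk4"


def _upward_crossings(t: np.ndarray, W: np.ndarray, level: float) -> np.ndarray:
    below = W[:-1] < level
    above = W[1:] >= level
    idx = np.flatnonzero(below & above)
    if idx.size == 0:
        return np.empty(0)
    frac = (level - W[idx]) / (W[idx + 1] - W[idx])
    return t[idx] + frac * (t[idx + 1] - t[idx])


def detect_limit_cycle(
    params: ModelParams,
    initial: State,
    settings: CycleSettings | None = None,
) -> LimitCycle | None:
    """Detect a stable limit cycle reached from ``initial``.

    Returns ``None`` when the trajectory settles to an equilibrium
    (section crossings stop or the orbit collapses) or when the crossing
    periods never repeat to tolerance within the horizon.
    """
    if params.variant is not Variant.AUTONOMOUS:
        raise ValueError("limit-cycle detection applies to the autonomous variant")
    s = settings or CycleSettings()

    if s.section_W is not None:
        section = s.section_W
    else:
        eqs = find_equilibria(params)
        # section through the most unstable equilibrium: a stable cycle,
        # if present, must enclose a repelling point
        section = max(eqs, key=lambda e: e.eigenvalues[0].real).W

    traj = integrate(params, initial, s.t_end, s.dt, method=s.method)
    tail = traj.after(traj.times[0] + s.transient_fraction * s.t_end)

    crossings = _upward_crossings(tail.times, tail.W, section)
    if crossings.size < s.min_crossings:
        return None
    periods = np.diff(crossings)
    # crossings must persist to the end of the horizon
    if tail.times[-1] - crossings[-1] > 2.0 * periods[-1]:
        return None
    last = periods[-3:]
    period = float(np.mean(last))
    converged = bool(np.max(np.abs(last - period)) <= s.period_rtol * period)
    if not converged and np.max(np.abs(np.diff(periods) / periods[:-1])) > 0.2:
        return None  # wandering crossing spacing: not a periodic orbit

    # one final cycle, sampled between the last two crossings
    i0 = int(np.searchsorted(tail.times, crossings[-2]))
    i1 = int(np.searchsorted(tail.times, crossings[-1])) + 1
    orbit = np.column_stack([tail.W[i0:i1], tail.Z[i0:i1]])
    if np.ptp(orbit[:, 0]) < 1.0e-6:
        return None  # collapsed onto the equilibrium
    return LimitCycle(
        period=period,
        W_min=float(orbit[:, 0].min()),
        W_max=float(orbit[:, 0].max()),
        mean_orbit=orbit,
        converged=converged,
        section_W=float(section),
        n_crossings=int(crossings.size),
    )


@dataclass
class TrappingReport:
    """Numerical check of the three stable-limit-cycle conditions.

    (i) the region contains exactly one equilibrium and it is unstable;
    (ii) the vector field points strictly inward on the boundary;
    (iii) no equilibrium sits on the boundary.  ``inward_margin`` is the
    worst-case (largest) outward component over the boundary samples —
    negative means strictly inward everywhere.
    """

    unique_unstable_inside: bool
    inward_everywhere: bool
    boundary_clear: bool
    n_inside: int
    inward_margin: float
    boundary_distance: float

    @property
    def passed(self) -> bool:
        return (
            self.unique_unstable_inside
            and self.inward_everywhere
            and self.boundary_clear
        )


def verify_trapping_region(
    params: ModelParams,
    region: tuple[float, float, float, float],
    n_boundary_samples: int = 400,
) -> TrappingReport:
    """Check that ``region = (W_lo, W_hi, Z_lo, Z_hi)`` traps the flow.

    A closed rectangle satisfying the report's three conditions contains
    a stable limit cycle by the Poincare-Bendixson argument.  A region
    with no interior equilibrium (including a degenerate rectangle) is
    reported as a condition-(i) failure rather than an error.
    """
    if params.variant is not Variant.AUTONOMOUS:
        raise ValueError("trapping regions apply to the autonomous variant")
    W_lo, W_hi, Z_lo, Z_hi = map(float, region)
    from .model import vector_field

    eqs = find_equilibria(params)
    inside = [
        e for e in eqs if W_lo < e.W < W_hi and Z_lo < e.Z < Z_hi
    ]
    edge_tol = 1.0e-9 * max(1.0, abs(W_hi - W_lo), abs(Z_hi - Z_lo))
    on_boundary = [
        e
        for e in eqs
        if (W_lo - edge_tol <= e.W <= W_hi + edge_tol
            and Z_lo - edge_tol <= e.Z <= Z_hi + edge_tol)
        and not (W_lo + edge_tol < e.W < W_hi - edge_tol
                 and Z_lo + edge_tol < e.Z < Z_hi - edge_tol)
    ]
    unique_unstable = (
        len(inside) == 1 and not inside[0].stability.is_stable
        and W_hi > W_lo and Z_hi > Z_lo
    )

    n_side = max(1, n_boundary_samples // 4)
    worst = -np.inf
    sides = [
        (np.linspace(W_lo, W_hi, n_side), np.full(n_side, Z_lo), (0.0, -1.0)),
        (np.linspace(W_lo, W_hi, n_side), np.full(n_side, Z_hi), (0.0, 1.0)),
        (np.full(n_side, W_lo), np.linspace(Z_lo, Z_hi, n_side), (-1.0, 0.0)),
        (np.full(n_side, W_hi), np.linspace(Z_lo, Z_hi, n_side), (1.0, 0.0)),
    ]
    for Ws, Zs, normal in sides:
        for W, Z in zip(Ws, Zs):
            dW, dZ = vector_field(State(W, Z), params)
            worst = max(worst, dW * normal[0] + dZ * normal[1])
    b_dist = min(
        (
            min(abs(e.W - W_lo), abs(e.W - W_hi), abs(e.Z - Z_lo), abs(e.Z - Z_hi))
            for e in eqs
        ),
        default=np.inf,
    )
    return TrappingReport(
        unique_unstable_inside=unique_unstable,
        inward_everywhere=bool(worst < 0),
        boundary_clear=len(on_boundary) == 0,
        n_inside=len(inside),
        inward_margin=float(worst),
        boundary_distance=float(b_dist),
    )


@dataclass
class GlobalityReport:
    """Evidence behind a SNIC vs off-cycle saddle-node classification."""

    label: str  # "on_invariant_circle" | "off_cycle" | "inconclusive"
    ghost_distance: float | None
    cycle_past: LimitCycle | None
    coexisting_stable_equilibrium: bool
    cycle_before: bool


#: Neighbourhood radius for ghost passage, in (W, Z/30) scaled coordinates
#: (Z spans roughly thirty times the W range on the relevant orbits).
SNIC_RADIUS = 0.5
_Z_SCALE = 30.0


def classify_saddle_node_globality(
    fixed: ModelParams,
    critical: BifurcationPoint,
    *,
    offset: float = 1.0e-2,
    t_end: float = 400.0,
    dt: float = 1.0e-3,
    radius: float = SNIC_RADIUS,
) -> GlobalityReport:
    """Decide whether a saddle-node lies on an invariant circle.

    Just past the critical parameter (on the side where the equilibrium
    pair has vanished) the flow is integrated from near the former
    saddle-node.  The point is classified ``on_invariant_circle`` when
    the resulting attractor is a periodic orbit that passes through the
    ghost neighbourhood AND no other attractor survives: a stable
    equilibrium coexisting with the cycle, or a cycle already present
    before the bifurcation, means the saddle-node happened off the
    cycle.  With no periodic attractor at all the report is
    ``inconclusive``.
    """
    p_name = critical.parameter
    p_c = critical.critical_value

    def n_roots(p):
        from .equilibria import steady_state_roots

        return sum(r.multiplicity for r in steady_state_roots(fixed.with_(**{p_name: p})))

    sign = +1.0 if n_roots(p_c + offset) < n_roots(p_c - offset) else -1.0
    past = fixed.with_(**{p_name: p_c + sign * offset})
    before = fixed.with_(**{p_name: p_c - sign * offset})

    start = State(critical.W_star + 0.1, critical.Z_star)
    settings = CycleSettings(t_end=t_end, dt=dt, period_rtol=1.0e-3)
    cycle = detect_limit_cycle(past, start, settings)
    if cycle is None:
        return GlobalityReport("inconclusive", None, None, False, False)

    scaled = np.column_stack(
        [
            cycle.mean_orbit[:, 0] - critical.W_star,
            (cycle.mean_orbit[:, 1] - critical.Z_star) / _Z_SCALE,
        ]
    )
    ghost_distance = float(np.min(np.hypot(scaled[:, 0], scaled[:, 1])))

    coexisting_stable = any(
        e.stability.is_stable for e in find_equilibria(past)
    )
    cycle_before = any(
        detect_limit_cycle(before, State(W, Z), settings) is not None
        for W, Z in STANDARD_INITIAL_CONDITIONS
    )

    if ghost_distance <= radius and not coexisting_stable and not cycle_before:
        label = "on_invariant_circle"
    else:
        label = "off_cycle"
    return GlobalityReport(
        label, ghost_distance, cycle, coexisting_stable, cycle_before
    )
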