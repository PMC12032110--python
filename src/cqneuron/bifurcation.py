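"""Codimension-1 bifurcation detection along one-parameter sweeps.

Three kinds of critical point are located along sweeps in ``v`` or ``E``:

* saddle-node — simultaneous zeros of the steady-state cubic ``h`` and
  its derivative ``h'`` (a node and a saddle merge and annihilate);
* Andronov-Hopf — the Jacobian trace vanishes on an equilibrium branch
  while the determinant stays positive, so a conjugate eigenvalue pair
  crosses the imaginary axis.  At ``tau = 1`` the trace is
  ``-3 W^2 + 29``, pinning the Hopf abscissa to ``W = ±sqrt(29/3)``;
* focus/node boundary — the eigenvalue discriminant
  ``tr(J)^2 - 4 det(J)`` vanishes along a branch (eigenvalues switch
  between real and complex without any stability change).

Saddle-node candidates are bracketed by sign changes of the cubic's
discriminant on a dense parameter grid, refined by bisection, then
polished by a 2-D Newton solve of ``h = h' = 0``.  Whether a saddle-node
sits on an invariant circle is a global question and is decided by
:func:`cqneuron.dynamics.classify_saddle_node_globality`, not here.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq, fsolve

from .equilibria import (
    Stability,
    classify_stability,
    eigenvalues_at,
    find_equilibria,
    steady_state_cubic,
)
from .model import ModelParams, Variant

__all__ = [
    "BifurcationKind",
    "BifurcationPoint",
    "BranchDiagram",
    "find_saddle_node",
    "find_hopf",
    "find_focus_node_boundary",
    "branch_diagram",
]


class BifurcationKind(str, enum.Enum):
    SADDLE_NODE = "saddle_node"
    SNIC = "saddle_node_on_invariant_circle"
    HOPF = "hopf"
    FOCUS_NODE_BOUNDARY = "focus_node_boundary"


@dataclass(frozen=True)
class BifurcationPoint:
    """A critical parameter value with the degenerate equilibrium location.

    ``conditions`` records the numerically checked residuals: for a
    saddle-node the non-hyperbolicity residuals ``|h|``, ``|h'|`` and the
    zero eigenvalue, the non-degeneracy value ``h''/2`` and the
    transversality value ``dh/dparam``, all evaluated at the critical
    point; for a Hopf the trace residual, determinant and the parameter
    derivative of the trace along the branch; for a focus/node boundary
    the discriminant residual and branch index.
    """

    kind: BifurcationKind
    parameter: str  # "v" or "E"
    critical_value: float
    W_star: float
    Z_star: float
    conditions: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "kind": self.kind.value,
            "parameter": self.parameter,
            "critical_value": self.critical_value,
            "W_star": self.W_star,
            "Z_star": self.Z_star,
            "conditions": self.conditions,
        }


def _check_sweep(sweep: str, fixed: ModelParams):
    if sweep not in ("v", "E"):
        raise ValueError(f"sweep must be 'v' or 'E', got {sweep!r}")
    if fixed.variant is not Variant.AUTONOMOUS:
        raise ValueError("bifurcation sweeps require the autonomous variant")


def _at(fixed: ModelParams, sweep: str, p: float) -> ModelParams:
    return fixed.with_(**{sweep: float(p)})


def _cubic_discriminant(params: ModelParams) -> float:
    c0, c1, c2, c3 = steady_state_cubic(params).coeffs
    a, b, c, d = c3, c2, c1, c0
    return (
        18.0 * a * b * c * d
        - 4.0 * b**3 * d
        + b**2 * c**2
        - 4.0 * a * c**3
        - 27.0 * a**2 * d**2
    )


def find_saddle_node(
    sweep: str,
    fixed: ModelParams,
    bracket: tuple[float, float],
    *,
    n_scan: int = 2001,
) -> list[BifurcationPoint]:
    """All saddle-node points (h = h' = 0) in the bracket, sorted.

    Sign changes of the cubic discriminant over a dense scan bracket each
    root-count change; a bracket containing none returns an empty list.
    """
    _check_sweep(sweep, fixed)
    lo, hi = map(float, bracket)
    grid = np.linspace(lo, hi, n_scan)
    disc = np.array([_cubic_discriminant(_at(fixed, sweep, p)) for p in grid])

    points: list[BifurcationPoint] = []
    for i in np.flatnonzero(np.sign(disc[:-1]) != np.sign(disc[1:])):
        p_c = brentq(
            lambda p: _cubic_discriminant(_at(fixed, sweep, p)),
            grid[i],
            grid[i + 1],
            xtol=1.0e-12,
        )
        h = steady_state_cubic(_at(fixed, sweep, p_c))
        # double root is among the zeros of h' (a quadratic)
        cand = np.roots([3.0 * h.coeffs[3], 2.0 * h.coeffs[2], h.coeffs[1]])
        W_guess = float(min(cand.real, key=lambda W: abs(h(W))))

        def system(x):
            hh = steady_state_cubic(_at(fixed, sweep, x[1]))
            return [hh(x[0]), hh.derivative(x[0])]

        (W_star, p_star), info, ok, _ = fsolve(
            system, [W_guess, p_c], full_output=True
        )
        if ok != 1:
            W_star, p_star = W_guess, p_c
        points.append(_saddle_node_point(sweep, fixed, float(p_star), float(W_star)))

    points.sort(key=lambda bp: bp.critical_value)
    # dedupe points found from adjacent scan cells
    deduped: list[BifurcationPoint] = []
    for bp in points:
        if deduped and abs(bp.critical_value - deduped[-1].critical_value) < 1.0e-8:
            continue
        deduped.append(bp)
    return deduped


def _saddle_node_point(
    sweep: str, fixed: ModelParams, p_star: float, W_star: float
) -> BifurcationPoint:
    params = _at(fixed, sweep, p_star)
    h = steady_state_cubic(params)
    Z_star = 5.0 * (W_star + params.v) ** 2
    eigs = eigenvalues_at(W_star, params)
    zero_eig = min(eigs, key=lambda l: abs(l))
    other_eig = max(eigs, key=lambda l: abs(l))
    if sweep == "E":
        dh_dp = 1.0
    else:
        dh_dp = -10.0 * W_star - 10.0 * params.v
    return BifurcationPoint(
        kind=BifurcationKind.SADDLE_NODE,
        parameter=sweep,
        critical_value=p_star,
        W_star=W_star,
        Z_star=Z_star,
        conditions={
            "h_residual": float(abs(h(W_star))),
            "dh_dW_residual": float(abs(h.derivative(W_star))),
            "zero_eigenvalue": float(abs(zero_eig)),
            "other_eigenvalue": float(other_eig.real),
            "nondegeneracy_half_d2h": float(0.5 * h.second_derivative(W_star)),
            "transversality_dh_dparam": float(dh_dp),
        },
    )


def hopf_abscissas(tau: float) -> list[float]:
    """W values where the Jacobian trace vanishes: ``±sqrt((30 - 1/tau)/3)``."""
    s = (30.0 - 1.0 / tau) / 3.0
    if s <= 0:
        return []
    W = float(np.sqrt(s))
    return [-W, W]


def find_hopf(
    sweep: str, fixed: ModelParams, bracket: tuple[float, float]
) -> list[BifurcationPoint]:
    """Hopf points (trace zero with positive determinant) in the bracket.

    The trace depends on the parameters only through W, so the candidate
    abscissas are known in closed form and the sweep parameter is
    recovered by solving ``h(W*, p) = 0`` (linear in E, quadratic in v).
    """
    _check_sweep(sweep, fixed)
    lo, hi = map(float, bracket)
    points: list[BifurcationPoint] = []
    for W in hopf_abscissas(fixed.tau):
        if sweep == "E":
            # h = 0  =>  E = W^3 + 5 W^2 - (30 - 10 v) W + 5 v^2
            v = fixed.v
            cands = [W**3 + 5.0 * W**2 - (30.0 - 10.0 * v) * W + 5.0 * v**2]
        else:
            # -5 v^2 - 10 W v + (-W^3 - 5 W^2 + 30 W + E) = 0
            cands = [
                float(r.real)
                for r in np.roots(
                    [-5.0, -10.0 * W, -(W**3) - 5.0 * W**2 + 30.0 * W + fixed.E]
                )
                if abs(r.imag) < 1.0e-10
            ]
        for p in cands:
            if not (lo <= p <= hi):
                continue
            params = _at(fixed, sweep, p)
            det = (3.0 * W**2 + 10.0 * W - 30.0 + 10.0 * params.v) / params.tau
            if det <= 0:
                continue  # trace zero on a saddle branch is not a Hopf
            h = steady_state_cubic(params)
            # transversality: d tr/dp along the branch, via implicit dW/dp
            dh_dW = h.derivative(W)
            dh_dp = 1.0 if sweep == "E" else (-10.0 * W - 10.0 * params.v)
            dW_dp = -dh_dp / dh_dW if dh_dW != 0 else np.inf
            dtr_dp = -6.0 * W * dW_dp
            points.append(
                BifurcationPoint(
                    kind=BifurcationKind.HOPF,
                    parameter=sweep,
                    critical_value=float(p),
                    W_star=float(W),
                    Z_star=float(5.0 * (W + params.v) ** 2),
                    conditions={
                        "trace_residual": float(abs(-3.0 * W**2 + 30.0 - 1.0 / params.tau)),
                        "determinant": float(det),
                        "dtrace_dparam": float(dtr_dp),
                        "h_residual": float(abs(h(W))),
                    },
                )
            )
    points.sort(key=lambda bp: bp.critical_value)
    return points


def _branch_discriminant(params: ModelParams, branch: int, n_branches: int):
    eqs = find_equilibria(params)
    if len(eqs) != n_branches:
        return None
    W = eqs[branch].W
    tr = (-3.0 * W**2 + 30.0) - 1.0 / params.tau
    det = (3.0 * W**2 + 10.0 * W - 30.0 + 10.0 * params.v) / params.tau
    return tr * tr - 4.0 * det


def find_focus_node_boundary(
    sweep: str,
    fixed: ModelParams,
    bracket: tuple[float, float],
    *,
    n_scan: int = 601,
) -> list[BifurcationPoint]:
    """Discriminant zeros (node <-> focus transitions) along every branch.

    Branches are tracked by ascending-W index on segments of the scan
    where the equilibrium count is constant; each returned point records
    its branch index in ``conditions``.
    """
    _check_sweep(sweep, fixed)
    lo, hi = map(float, bracket)
    grid = np.linspace(lo, hi, n_scan)
    counts = []
    discs = []
    for p in grid:
        eqs = find_equilibria(_at(fixed, sweep, p))
        counts.append(len(eqs))
        row = []
        for eq in eqs:
            tr = (-3.0 * eq.W**2 + 30.0) - 1.0 / fixed.tau
            det = (3.0 * eq.W**2 + 10.0 * eq.W - 30.0 + 10.0 * _at(fixed, sweep, p).v) / fixed.tau
            row.append(tr * tr - 4.0 * det)
        discs.append(row)

    points: list[BifurcationPoint] = []
    for i in range(len(grid) - 1):
        if counts[i] != counts[i + 1]:
            continue
        nb = counts[i]
        for b in range(nb):
            d0, d1 = discs[i][b], discs[i + 1][b]
            if np.sign(d0) == np.sign(d1) or d0 == d1:
                continue

            def f(p, b=b, nb=nb):
                val = _branch_discriminant(_at(fixed, sweep, p), b, nb)
                return val if val is not None else np.nan

            try:
                p_c = brentq(f, grid[i], grid[i + 1], xtol=1.0e-12)
            except ValueError:
                continue
            params = _at(fixed, sweep, p_c)
            eqs = find_equilibria(params)
            eq = eqs[b] if len(eqs) == nb else min(eqs, key=lambda e: abs(e.W))
            points.append(
                BifurcationPoint(
                    kind=BifurcationKind.FOCUS_NODE_BOUNDARY,
                    parameter=sweep,
                    critical_value=float(p_c),
                    W_star=float(eq.W),
                    Z_star=float(eq.Z),
                    conditions={
                        "discriminant_residual": float(abs(f(p_c, b, nb))),
                        "branch_index": b,
                        "n_branches": nb,
                    },
                )
            )
    points.sort(key=lambda bp: bp.critical_value)
    return points


@dataclass
class BranchDiagram:
    """Equilibrium branches sampled on a parameter grid, with detected points."""

    parameter: str
    grid: np.ndarray
    samples: pd.DataFrame  # columns: parameter value, branch, W, Z, stability
    points: list[BifurcationPoint]

    def branch_counts(self) -> np.ndarray:
        return (
            self.samples.groupby(self.parameter, sort=True)["W"]
            .count()
            .reindex(self.grid)
            .to_numpy()
        )

    def to_csv(self, path) -> None:
        self.samples.to_csv(path, index=False)

    def points_to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump([bp.to_dict() for bp in self.points], fh, indent=2)


def branch_diagram(
    sweep: str, fixed: ModelParams, grid
) -> BranchDiagram:
    """Sample equilibria over ``grid`` and attach all detected bifurcations."""
    _check_sweep(sweep, fixed)
    grid = np.asarray(grid, dtype=float)
    if np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be sorted strictly ascending")
    rows = []
    for p in grid:
        params = _at(fixed, sweep, p)
        for b, eq in enumerate(find_equilibria(params)):
            rows.append(
                {
                    sweep: p,
                    "branch": b,
                    "W": eq.W,
                    "Z": eq.Z,
                    "stability": eq.stability.value,
                }
            )
    bracket = (float(grid[0]), float(grid[-1]))
    points = (
        find_saddle_node(sweep, fixed, bracket)
        + find_hopf(sweep, fixed, bracket)
        + find_focus_node_boundary(sweep, fixed, bracket)
    )
    points.sort(key=lambda bp: bp.critical_value)
    return BranchDiagram(
        parameter=sweep, grid=grid, samples=pd.DataFrame(rows), points=points
    )
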