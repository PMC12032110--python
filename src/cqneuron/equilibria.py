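"""Steady states of the autonomous C-Q model and their linear stability.

Setting both nullclines equal eliminates ``Z`` and leaves the steady-state
cubic

    h(W) = -W^3 - 5 W^2 + (30 - 10 v) W + (E - 5 v^2) = 0,

so the model has one to three equilibria ``(W, 5 (W + v)^2)``.  Roots are
found numerically (companion-matrix eigenvalues via ``numpy.roots``, then
polished by Newton steps) rather than through the closed-form radical
expressions, which are numerically fragile; the test-suite holds the two
routes to agreement.  Stability is read off the Jacobian eigenvalues,
computed from trace and determinant so that conjugate symmetry is exact.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd

from .model import ModelParams, State, Variant, jacobian

__all__ = [
    "Stability",
    "CubicRoot",
    "SteadyStateCubic",
    "Equilibrium",
    "steady_state_cubic",
    "steady_state_roots",
    "eigenvalues_at",
    "classify_stability",
    "find_equilibria",
    "equilibria_table",
]


class Stability(str, enum.Enum):
    STABLE_NODE = "stable_node"
    UNSTABLE_NODE = "unstable_node"
    STABLE_FOCUS = "stable_focus"
    UNSTABLE_FOCUS = "unstable_focus"
    SADDLE = "saddle"
    NON_HYPERBOLIC = "non_hyperbolic"

    @property
    def is_stable(self) -> bool:
        return self in (Stability.STABLE_NODE, Stability.STABLE_FOCUS)


class CubicRoot(NamedTuple):
    W: float
    multiplicity: int


@dataclass(frozen=True)
class SteadyStateCubic:
    """Coefficients of h(W) in ascending degree order; leading term is -1.

    ``alpha = E + 45`` is the shifted input used when sweeping E at fixed
    v = 3, where the cubic reduces to ``-W^3 - 5 W^2 + alpha - 45``.
    """

    coeffs: tuple[float, float, float, float]
    alpha: float

    def __call__(self, W):
        c0, c1, c2, c3 = self.coeffs
        return c0 + W * (c1 + W * (c2 + W * c3))

    def derivative(self, W):
        c0, c1, c2, c3 = self.coeffs
        return c1 + W * (2.0 * c2 + W * 3.0 * c3)

    def second_derivative(self, W):
        _, _, c2, c3 = self.coeffs
        return 2.0 * c2 + 6.0 * c3 * np.asarray(W, dtype=float)


def steady_state_cubic(params: ModelParams) -> SteadyStateCubic:
    """Build h(W) for the given autonomous parameter set."""
    if params.variant is not Variant.AUTONOMOUS:
        raise ValueError("steady-state cubic is defined for the autonomous variant")
    E, v = params.E, params.v
    return SteadyStateCubic(
        coeffs=(E - 5.0 * v**2, 30.0 - 10.0 * v, -5.0, -1.0),
        alpha=E + 45.0,
    )


def _scale(h: SteadyStateCubic) -> float:
    # magnitude scale of the cubic coefficients, for relative tolerances
    return max(1.0, max(abs(c) for c in h.coeffs))


def steady_state_roots(
    params: ModelParams, *, double_root_tol: float = 1.0e-6
) -> list[CubicRoot]:
    """All real roots of h(W), ascending, double roots reported once.

    A root where ``|h'(W)|`` is below ``double_root_tol`` (scaled by the
    coefficient magnitude) is flagged with multiplicity 2; at the
    tolerance boundary the generic distinct-root reading wins.  A cubic
    always has at least one real root, so the result is never empty.
    """
    h = steady_state_cubic(params)
    c0, c1, c2, c3 = h.coeffs
    raw = np.roots([c3, c2, c1, c0])
    scale = _scale(h)
    real_tol = 1.0e-7 * max(1.0, float(np.max(np.abs(raw))))
    dp_tol = double_root_tol * scale

    # real candidates: strictly real roots, plus conjugate pairs split off
    # a fold by roundoff (tiny imaginary part AND h' nearly zero there)
    singles: list[float] = []
    doubles: list[float] = []
    for r in raw:
        is_real = abs(r.imag) <= real_tol
        near_fold = abs(h.derivative(r.real)) < dp_tol
        if is_real and not near_fold:
            singles.append(_polish(h, float(r.real)))
        elif near_fold and (
            is_real or abs(r.imag) <= 1.0e-3 * max(1.0, abs(r))
        ):
            doubles.append(_polish_double(h, float(r.real)))
    # the two members of a split pair land on the same fold: keep one
    doubles.sort()
    merged: list[float] = []
    for W in doubles:
        if merged and abs(W - merged[-1]) < 1.0e-6 * max(1.0, abs(W)):
            continue
        merged.append(W)

    out = [CubicRoot(W, 1) for W in singles] + [CubicRoot(W, 2) for W in merged]
    if not out:  # unreachable for an exact cubic, but never return empty
        r = raw[np.argmin(np.abs(raw.imag))]
        out = [CubicRoot(_polish(h, float(r.real)), 1)]
    out.sort(key=lambda root: root.W)
    return out


def _polish(h: SteadyStateCubic, W: float, iters: int = 3) -> float:
    for _ in range(iters):
        d = h.derivative(W)
        if d == 0.0:
            break
        step = h(W) / d
        if not np.isfinite(step):
            break
        W -= step
    return W


def _polish_double(h: SteadyStateCubic, W: float, iters: int = 10) -> float:
    # a double root of h is a simple root of h'
    for _ in range(iters):
        d2 = float(h.second_derivative(W))
        if d2 == 0.0:
            break
        W -= h.derivative(W) / d2
    return W


def eigenvalues_at(W: float, params: ModelParams) -> tuple[complex, complex]:
    """Jacobian eigenvalues at abscissa ``W`` via the trace/determinant quadratic.

    Ordered by descending real part, then descending imaginary part, so a
    conjugate pair comes back as ``(a + bi, a - bi)`` with ``b >= 0``.
    """
    tr = (-3.0 * W**2 + 30.0) - 1.0 / params.tau
    det = (3.0 * W**2 + 10.0 * W - 30.0 + 10.0 * params.v) / params.tau
    disc = tr * tr - 4.0 * det
    if disc >= 0.0:
        s = np.sqrt(disc)
        lam1, lam2 = (tr + s) / 2.0, (tr - s) / 2.0
        return complex(lam1), complex(lam2)
    s = np.sqrt(-disc) / 2.0
    return complex(tr / 2.0, s), complex(tr / 2.0, -s)


def classify_stability(
    eigenvalues: tuple[complex, complex], zero_tol: float = 1.0e-6
) -> Stability:
    """Linear stability class of a 2x2 real matrix from its eigenvalue pair.

    Any eigenvalue whose real part lies within ``zero_tol`` of zero makes
    the equilibrium non-hyperbolic.  Complex eigenvalues must form a
    conjugate pair.
    """
    l1, l2 = complex(eigenvalues[0]), complex(eigenvalues[1])
    if l1.imag != 0.0 or l2.imag != 0.0:
        if not np.isclose(l1.real, l2.real) or not np.isclose(l1.imag, -l2.imag):
            raise ValueError(f"non-conjugate complex pair: {l1}, {l2}")
        if abs(l1.real) <= zero_tol:
            return Stability.NON_HYPERBOLIC
        return Stability.STABLE_FOCUS if l1.real < 0 else Stability.UNSTABLE_FOCUS
    r1, r2 = l1.real, l2.real
    if abs(r1) <= zero_tol or abs(r2) <= zero_tol:
        return Stability.NON_HYPERBOLIC
    if r1 * r2 < 0:
        return Stability.SADDLE
    return Stability.STABLE_NODE if r1 < 0 else Stability.UNSTABLE_NODE


@dataclass(frozen=True)
class Equilibrium:
    """A fixed point of the autonomous model with its linearisation."""

    W: float
    Z: float
    eigenvalues: tuple[complex, complex]
    stability: Stability
    params: ModelParams
    multiplicity: int = 1

    @property
    def state(self) -> State:
        return State(self.W, self.Z)

    def jacobian(self) -> np.ndarray:
        return jacobian(self.state, self.params)


def find_equilibria(
    params: ModelParams, *, zero_tol: float = 1.0e-6
) -> list[Equilibrium]:
    """All equilibria of the autonomous model, ascending in W."""
    out = []
    for root in steady_state_roots(params):
        Z = 5.0 * (root.W + params.v) ** 2
        eigs = eigenvalues_at(root.W, params)
        out.append(
            Equilibrium(
                W=root.W,
                Z=Z,
                eigenvalues=eigs,
                stability=classify_stability(eigs, zero_tol),
                params=params,
                multiplicity=root.multiplicity,
            )
        )
    return out


def equilibria_table(equilibria: list[Equilibrium]) -> pd.DataFrame:
    """Tabulate equilibria for CSV export."""
    rows = []
    for eq in equilibria:
        l1, l2 = eq.eigenvalues
        rows.append(
            {
                "E": eq.params.E,
                "v": eq.params.v,
                "tau": eq.params.tau,
                "W": eq.W,
                "Z": eq.Z,
                "re_lambda1": l1.real,
                "im_lambda1": l1.imag,
                "re_lambda2": l2.real,
                "im_lambda2": l2.imag,
                "stability": eq.stability.value,
            }
        )
    return pd.DataFrame(rows)
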