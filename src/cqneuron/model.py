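"""Vector fields, nullclines and Jacobian of the cubic-quadratic (C-Q) neuron model.

The autonomous model is the planar system

    dW/dt = -W^3 + 30 W - Z + E
    tau dZ/dt = 5 (W + v)^2 - Z

where ``W`` is the membrane potential, ``Z`` the recovery variable, ``E``
the external input current, ``v`` a recovery-offset parameter shifting the
quadratic nullcline horizontally, and ``tau > 0`` the recovery time
constant.  The cubic term caps the voltage and drives the spike upstroke;
the quadratic recovery term models the opening of repolarising channels.

The forced variant is a rescaled version of the same dynamics with the
recovery offset fixed at ``v = 3`` and a sinusoidal drive
``E(t) = F sin(omega t) + 70``:

    dW/dt = -W^3 + 30 W - 10 Z + (E(t) - 70)
    dZ/dt = 5 (W + 3)^2 - 10 Z - 70

The recovery variable here is the translated-and-scaled
``Z_resc = (Z - 70) / 10``; the translation absorbs the 70 baseline of
the input, which is why the drive enters the rescaled field as
``E(t) - 70 = F sin(omega t)``.  Writing the scaled second equation
without its 1/10 prefactor amounts to a tenfold recovery speed-up, so
the forced variant is the original field at ``v = 3`` with
``tau(Z) = 0.1`` and input ``F sin(omega t) + 70`` — at ``F = 0`` it sits
on the tonic-spiking limit cycle of the ``E = 70`` regime, the baseline
state on which the periodic drive acts.  All quantities are
dimensionless.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Variant",
    "ModelParams",
    "State",
    "DivergenceError",
    "BASELINE_INPUT",
    "external_input",
    "vector_field",
    "nullclines",
    "jacobian",
]

#: Constant offset of the sinusoidal drive in the forced variant.
BASELINE_INPUT = 70.0


class Variant(str, enum.Enum):
    """Which vector field a :class:`ModelParams` describes."""

    AUTONOMOUS = "autonomous"
    FORCED = "forced"


class DivergenceError(RuntimeError):
    """A trajectory left the bounded region of phase space.

    Carries the last finite state seen by the integrator in
    ``last_state`` (may be ``None`` when divergence is detected on input).
    """

    def __init__(self, message: str, last_state: "State | None" = None):
        super().__init__(message)
        self.last_state = last_state


@dataclass(frozen=True)
class ModelParams:
    """Parameter set of the C-Q model.

    Parameters
    ----------
    E
        External input current (autonomous variant only; the forced
        variant builds its drive from ``F`` and ``omega``).
    v
        Recovery-offset parameter; shifts the quadratic nullcline.
    tau
        Recovery time constant, strictly positive.  The forced variant is
        defined without a time constant and requires ``tau == 1``.
    variant
        ``Variant.AUTONOMOUS`` or ``Variant.FORCED``.
    F, omega
        Forcing amplitude (>= 0) and angular frequency (> 0); required by
        the forced variant and disallowed (or zero) otherwise.
    """

    E: float = BASELINE_INPUT
    v: float = 3.0
    tau: float = 1.0
    variant: Variant = Variant.AUTONOMOUS
    F: float | None = None
    omega: float | None = None

    def __post_init__(self):
        object.__setattr__(self, "variant", Variant(self.variant))
        if not (self.tau > 0):
            raise ValueError(f"tau must be > 0, got {self.tau}")
        if self.variant is Variant.FORCED:
            if self.F is None or self.omega is None:
                raise ValueError("forced variant requires F and omega")
            if self.F < 0:
                raise ValueError(f"F must be >= 0, got {self.F}")
            if not (self.omega > 0):
                raise ValueError(f"omega must be > 0, got {self.omega}")
            if self.tau != 1.0:
                raise ValueError("the forced variant has no tau parameter")
            if self.v != 3.0:
                raise ValueError("the forced variant fixes v = 3")
        else:
            if self.F not in (None, 0, 0.0) or self.omega is not None:
                raise ValueError(
                    "autonomous variant takes no forcing parameters"
                )

    def with_(self, **changes) -> "ModelParams":
        """Return a copy with the given fields replaced."""
        from dataclasses import replace

        return replace(self, **changes)


@dataclass(frozen=True)
class State:
    """A point in phase space, with the time at which it was observed."""

    W: float
    Z: float
    t: float = 0.0

    def __post_init__(self):
        if not (math.isfinite(self.W) and math.isfinite(self.Z)):
            raise DivergenceError(
                f"non-finite state (W={self.W}, Z={self.Z})", None
            )


def external_input(t, F: float, omega: float):
    """Sinusoidal drive ``E(t) = F sin(omega t) + 70`` of the forced model."""
    return F * np.sin(omega * np.asarray(t, dtype=float)) + BASELINE_INPUT


def vector_field(state: State, params: ModelParams) -> tuple[float, float]:
    """Time derivatives ``(dW/dt, dZ/dt)`` at ``state``.

    Pure and deterministic.  Raises :class:`DivergenceError` for
    non-finite input (already enforced by :class:`State`) and
    ``ValueError`` for an invalid parameter set.
    """
    W, Z = state.W, state.Z
    if params.variant is Variant.FORCED:
        drive = float(external_input(state.t, params.F, params.omega)) - BASELINE_INPUT
        dW = -W**3 + 30.0 * W - 10.0 * Z + drive
        dZ = 5.0 * (W + 3.0) ** 2 - 10.0 * Z - 70.0
        return dW, dZ
    dW = -W**3 + 30.0 * W - Z + params.E
    dZ = (5.0 * (W + params.v) ** 2 - Z) / params.tau
    return dW, dZ


def nullclines(params: ModelParams, W_grid) -> tuple[np.ndarray, np.ndarray]:
    """Evaluate the two nullclines of the autonomous model on a W grid.

    Returns ``(Z_on_W_nullcline, Z_on_Z_nullcline)`` where the first is
    the cubic ``Z = -W^3 + 30 W + E`` (where dW/dt vanishes) and the
    second the parabola ``Z = 5 (W + v)^2`` (where dZ/dt vanishes).
    Intersections of the two curves are the equilibria.
    """
    if params.variant is not Variant.AUTONOMOUS:
        raise ValueError("nullclines are defined for the autonomous variant")
    W = np.asarray(W_grid, dtype=float)
    return -(W**3) + 30.0 * W + params.E, 5.0 * (W + params.v) ** 2


def jacobian(state: State, params: ModelParams) -> np.ndarray:
    """Jacobian matrix of the autonomous field at ``state``.

    ``[[-3 W^2 + 30, -1], [(10 W + 10 v)/tau, -1/tau]]`` — only the first
    column depends on the state, and only through ``W``.
    """
    if params.variant is not Variant.AUTONOMOUS:
        raise ValueError("jacobian is defined for the autonomous variant")
    W = state.W
    return np.array(
        [
            [-3.0 * W**2 + 30.0, -1.0],
            [(10.0 * W + 10.0 * params.v) / params.tau, -1.0 / params.tau],
        ]
    )
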