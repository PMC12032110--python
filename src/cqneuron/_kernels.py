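"""Compiled fixed-step RK4 integration kernels.

These are the hot loops behind :mod:`cqneuron.dynamics` and
:mod:`cqneuron.forcing`; everything else in the package stays in plain
NumPy/SciPy.  Each kernel returns a divergence index (``-1`` when the
trajectory stayed bounded, otherwise the sample index at which ``|W|``
first exceeded the blow-up threshold).
"""

from __future__ import annotations

import numpy as np
from numba import njit

BLOWUP = 1.0e3


@njit(cache=True)
def _auto_rhs(W, Z, E, v, inv_tau):
    dW = -W * W * W + 30.0 * W - Z + E
    dZ = (5.0 * (W + v) * (W + v) - Z) * inv_tau
    return dW, dZ


@njit(cache=True)
def rk4_autonomous(E, v, tau, W0, Z0, t0, n_steps, dt, stride):
    """Integrate the autonomous field; store every ``stride``-th sample.

    Returns ``(t, W, Z, diverged_at)`` with the initial state included as
    sample 0.
    """
    inv_tau = 1.0 / tau
    m = n_steps // stride + 1
    ts = np.empty(m + 1)
    Ws = np.empty(m + 1)
    Zs = np.empty(m + 1)
    W = W0
    Z = Z0
    ts[0] = t0
    Ws[0] = W0
    Zs[0] = Z0
    j = 1
    for i in range(n_steps):
        k1W, k1Z = _auto_rhs(W, Z, E, v, inv_tau)
        k2W, k2Z = _auto_rhs(W + 0.5 * dt * k1W, Z + 0.5 * dt * k1Z, E, v, inv_tau)
        k3W, k3Z = _auto_rhs(W + 0.5 * dt * k2W, Z + 0.5 * dt * k2Z, E, v, inv_tau)
        k4W, k4Z = _auto_rhs(W + dt * k3W, Z + dt * k3Z, E, v, inv_tau)
        W += dt / 6.0 * (k1W + 2.0 * k2W + 2.0 * k3W + k4W)
        Z += dt / 6.0 * (k1Z + 2.0 * k2Z + 2.0 * k3Z + k4Z)
        if abs(W) > BLOWUP or not (np.isfinite(W) and np.isfinite(Z)):
            return ts[:j], Ws[:j], Zs[:j], j - 1
        if (i + 1) % stride == 0:
            ts[j] = t0 + (i + 1) * dt
            Ws[j] = W
            Zs[j] = Z
            j += 1
    return ts[:j], Ws[:j], Zs[:j], -1


@njit(cache=True)
def _forced_rhs(W, Z, t, F, omega):
    # drive in rescaled coordinates: E(t) - 70 = F sin(omega t); the 70
    # baseline of the original-coordinate input is absorbed by the Z
    # translation that produced this field
    dW = -W * W * W + 30.0 * W - 10.0 * Z + F * np.sin(omega * t)
    dZ = 5.0 * (W + 3.0) * (W + 3.0) - 10.0 * Z - 70.0
    return dW, dZ


@njit(cache=True)
def _forced_step(W, Z, t, dt, F, omega):
    k1W, k1Z = _forced_rhs(W, Z, t, F, omega)
    k2W, k2Z = _forced_rhs(W + 0.5 * dt * k1W, Z + 0.5 * dt * k1Z, t + 0.5 * dt, F, omega)
    k3W, k3Z = _forced_rhs(W + 0.5 * dt * k2W, Z + 0.5 * dt * k2Z, t + 0.5 * dt, F, omega)
    k4W, k4Z = _forced_rhs(W + dt * k3W, Z + dt * k3Z, t + dt, F, omega)
    return (
        W + dt / 6.0 * (k1W + 2.0 * k2W + 2.0 * k3W + k4W),
        Z + dt / 6.0 * (k1Z + 2.0 * k2Z + 2.0 * k3Z + k4Z),
    )


@njit(cache=True)
def rk4_forced(F, omega, W0, Z0, t0, n_steps, dt, stride):
    """Integrate the forced field; same sampling contract as the autonomous kernel."""
    m = n_steps // stride + 1
    ts = np.empty(m + 1)
    Ws = np.empty(m + 1)
    Zs = np.empty(m + 1)
    W = W0
    Z = Z0
    ts[0] = t0
    Ws[0] = W0
    Zs[0] = Z0
    j = 1
    for i in range(n_steps):
        t = t0 + i * dt
        W, Z = _forced_step(W, Z, t, dt, F, omega)
        if abs(W) > BLOWUP or not (np.isfinite(W) and np.isfinite(Z)):
            return ts[:j], Ws[:j], Zs[:j], j - 1
        if (i + 1) % stride == 0:
            ts[j] = t0 + (i + 1) * dt
            Ws[j] = W
            Zs[j] = Z
            j += 1
    return ts[:j], Ws[:j], Zs[:j], -1


@njit(cache=True)
def benettin_forced(
    F, omega, W0, Z0, transient, horizon, dt, renorm_interval, d0, dirW, dirZ
):
    """Two-trajectory Benettin estimate of the largest Lyapunov exponent.

    The perturbation lives in the (W, Z) plane only; both trajectories
    share the same explicit time, so growth along the forcing phase is
    excluded by construction.  Returns ``(running, final_W, final_Z,
    diverged)`` where ``running`` is the running LLE estimate recorded at
    every renormalisation.
    """
    n_tr = int(round(transient / dt))
    W = W0
    Z = Z0
    t = 0.0
    for i in range(n_tr):
        W, Z = _forced_step(W, Z, t, dt, F, omega)
        t += dt
        if abs(W) > BLOWUP:
            return np.empty(0), W, Z, True
    Wp = W + d0 * dirW
    Zp = Z + d0 * dirZ
    steps_per_renorm = max(1, int(round(renorm_interval / dt)))
    n_renorm = int(round(horizon / (steps_per_renorm * dt)))
    running = np.empty(n_renorm)
    log_sum = 0.0
    elapsed = 0.0
    for k in range(n_renorm):
        for i in range(steps_per_renorm):
            W, Z = _forced_step(W, Z, t + i * dt, dt, F, omega)
            Wp, Zp = _forced_step(Wp, Zp, t + i * dt, dt, F, omega)
        t += steps_per_renorm * dt
        elapsed += steps_per_renorm * dt
        if abs(W) > BLOWUP or abs(Wp) > BLOWUP:
            return running[:k], W, Z, True
        dW = Wp - W
        dZ = Zp - Z
        d = np.sqrt(dW * dW + dZ * dZ)
        if d == 0.0:
            d = 1.0e-300
        log_sum += np.log(d / d0)
        running[k] = log_sum / elapsed
        scale = d0 / d
        Wp = W + dW * scale
        Zp = Z + dZ * scale
    return running, W, Z, False


@njit(cache=True)
def strobe_forced(F, omega, W0, Z0, t0, n_periods, steps_per_period):
    """Stroboscopic samples ``W(t_k)`` at ``t_k = t0 + 2 pi k / omega``.

    The step is ``T / steps_per_period`` so each forcing period lands
    exactly on a sample.  Returns ``(samples, final_W, final_Z, diverged)``.
    """
    T = 2.0 * np.pi / omega
    dt = T / steps_per_period
    W = W0
    Z = Z0
    out = np.empty(n_periods)
    for k in range(n_periods):
        for i in range(steps_per_period):
            t = t0 + k * T + i * dt
            W, Z = _forced_step(W, Z, t, dt, F, omega)
        if abs(W) > BLOWUP:
            return out[:k], W, Z, True
        out[k] = W
    return out, W, Z, False
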