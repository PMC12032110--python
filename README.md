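# cqneuron

Phase-plane, bifurcation and forced-chaos analysis of a **cubic–quadratic
(C-Q) planar spiking-neuron model** — a two-parameter phenomenological
model in the FitzHugh–Nagumo tradition, for computational neuroscientists
who want the full dynamical-systems workup of a minimal spiking model:
equilibria and their linear stability, automated detection of saddle-node,
SNIC and Andronov–Hopf bifurcations, limit-cycle diagnostics, and a
periodically forced mode with largest-Lyapunov-exponent estimation and
firing-regime classification.

## The model

The autonomous system couples a cubic voltage nullcline (spike upstroke)
to a quadratic recovery nullcline (repolarisation):

```
dW/dt       = -W³ + 30 W - Z + E
τ(Z) dZ/dt  = 5 (W + v)² - Z
```

`W` is the membrane potential, `Z` the recovery variable, `E` the external
input current, `v` a recovery offset shifting the parabola horizontally,
and `τ(Z) > 0` the recovery time constant (default 1).  Equilibria are the
real roots of the steady-state cubic

```
h(W) = -W³ - 5 W² + (30 - 10 v) W + (E - 5 v²) = 0,
```

so the model has one to three fixed points.  Saddle-node (fold)
bifurcations solve `h = h' = 0`; Andronov–Hopf points are trace zeros of
the Jacobian `[[-3W² + 30, -1], [(10W + 10v)/τ, -1/τ]]` with positive
determinant (at `τ = 1` the Hopf abscissa is `W* = ±√(29/3)`); whether a
fold sits on an invariant circle (SNIC — the class-1 excitability route)
is decided from the global flow.

The forced variant drives the `v = 3` regime with
`E(t) = F sin(ωt) + 70` through a translated-and-rescaled recovery
variable (see `docs/methods.md` for the exact field and why its drive
enters as `F sin(ωt)`).  Depending on the drive frequency the neuron
bursts, spikes tonically, or wanders on a quasiperiodic band attractor.

## Worked example

Resting state of the strongly offset regime, and the v-sweep bifurcation
structure at `E = 70`:

```console
$ cqneuron equilibria --v -10 --E 70
W=-15.3187 Z=3205.19 lambda=(-0.623998+0i, -674.368+0i) stable_node

$ cqneuron bifurcate --sweep v --E 70 --lo 0 --hi 6
saddle_node: v = 2.33036 at (W, Z) = (-3.90495, 12.3966)
focus_node_boundary: v = 2.68905 at (W, Z) = (2.36512, 127.724)
focus_node_boundary: v = 4.07332 at (W, Z) = (-2.82442, 7.79878)
hopf: v = 4.27369 at (W, Z) = (-3.10913, 6.7811)
focus_node_boundary: v = 4.86323 at (W, Z) = (-3.56825, 8.3849)
```

The single equilibrium at `v = -10` is a stable node (both eigenvalues
real and negative).  Sweeping `v` upward, three equilibria collide and
annihilate at the fold `v ≈ 2.3304` — a saddle-node on an invariant
circle that ignites large-amplitude tonic spiking — and the surviving
focus regains stability through a Hopf point at `v ≈ 4.2737`.

The tonic-spiking limit cycle at the benchmark operating point, and the
sleep/wake regimes of the forced model:

```console
$ cqneuron cycle --E 70 --v 3
period 6.46892, W in [-6.28834, 6.08805], converged=True

$ cqneuron classify --F 10 --omega 1.56
bursting  evidence={"n_spikes": 150, ..., "isi_gap_ratio": 3.085...}

$ cqneuron classify --F 10 --omega 5.75
spiking  evidence={"n_spikes": 183, "isi_cv": 1.4e-07, ...}
```

Slow drive (`ω = 1.56`) periodically pushes the input below the fold
value `E ≈ 63.52`, silencing the neuron between spike groups — the
interspike-interval distribution is bimodal (largest ISI gap ratio ≈ 3.1),
i.e. bursting, the sleep-like mode.  Faster drive (`ω = 5.75`) phase-locks
one spike per drive period (ISI coefficient of variation ≈ 0): tonic
spiking, the wake-like mode.

`cqneuron reproduce` reruns the whole benchmark catalogue (equilibria,
bifurcation values, cycles, SNIC classification, forced regimes) and
prints a pass/fail table; `cqneuron sweep --sweep F --fixed 15.02 --lo 0
--hi 20` builds the stroboscopic bifurcation diagram with its Lyapunov
trace.

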