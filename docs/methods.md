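# Methods

## Model and assumptions

The package analyses a planar phenomenological spiking-neuron model with
a cubic voltage nullcline and a quadratic recovery nullcline:

```
dW/dt      = -W³ + 30 W - Z + E
τ(Z) dZ/dt = 5 (W + v)² - Z
```

All quantities are dimensionless; no unit-conversion layer is provided.
The cubic `-W³ + 30W` bounds the voltage and produces the spike upstroke;
the parabola `5(W+v)²` models recovery (potassium-channel activation),
with `v` setting how far the recovery curve sits from the voltage
nullcline and `τ(Z)` its speed.  The model is deterministic, autonomous
(unless forced), and smooth, so all analysis reduces to standard
planar-flow theory: equilibria at nullcline intersections, stability from
the 2×2 Jacobian, limit cycles by Poincaré–Bendixson arguments.

`τ` enters only the recovery equation, as division; the Jacobian
generalises the `τ = 1` form by dividing its second row by `τ`.

## Parameters

| parameter | meaning | default | notes |
|---|---|---|---|
| `E` | input current | 70 | benchmark operating point |
| `v` | recovery offset | 3 | `(E,v) = (70,3)` has one unstable node and a stable limit cycle |
| `τ` | recovery time constant | 1 | `0.152` (fast) and `6.6` (slow) are benchmark variants |
| `F` | drive amplitude | — | forced variant, `F ≥ 0` |
| `ω` | drive angular frequency | — | forced variant, `ω > 0`; 1.56 / 5.75 / 15.02 are the benchmark sleep / wake / fast points |

## Equilibria

Steady states are the real roots of
`h(W) = -W³ - 5W² + (30-10v)W + (E-5v²)`, with `Z = 5(W+v)²`.  Roots are
computed from the companion matrix (`numpy.roots`) and polished with
Newton steps; the closed-form radical expressions are implemented only as
a test oracle, because they mix real and imaginary intermediates and are
numerically fragile near folds.  A root is reported with multiplicity 2
when `|h'(W)|` falls below `1e-6` (scaled by the largest cubic
coefficient); at the tolerance boundary the generic distinct-root reading
wins.  Conjugate root pairs whose imaginary part is below `1e-3` *and*
whose abscissa has `|h'| < 1e-6` (scaled) are folded back onto the real
axis — this is the roundoff signature of a double root, and double roots
are then polished on `h'` (Newton on the derivative), where they are
simple.

Eigenvalues come from the trace/determinant quadratic rather than a
general eigensolver, so conjugate symmetry is exact; they are ordered by
descending real part, then descending imaginary part.  Stability
classification uses `zero_tol = 1e-6` on the real part for the
non-hyperbolic call; bifurcation detection never relies on hitting an
exact zero (it brackets sign changes instead).

## Bifurcation detection

* **Saddle-node:** sign changes of the cubic discriminant along a dense
  parameter scan (2001 points) bracket each root-count change; bisection
  refines the parameter to `1e-12`, and a 2-D Newton solve of
  `h = h' = 0` polishes `(W*, p*)`.  Each point reports the
  back-substituted residuals, the non-degeneracy value `h''/2` and the
  transversality value `∂h/∂p` (`1` for `E`, `-10(W+v)` for `v`).
* **Hopf:** at fixed `τ` the Jacobian trace vanishes only at
  `W* = ±√((30 - 1/τ)/3)`, so the sweep parameter is recovered *exactly*
  by solving `h(W*, p) = 0` (linear in `E`, quadratic in `v`); candidates
  with non-positive determinant (trace zeros on a saddle branch) are
  rejected, and the trace's parameter derivative along the branch is
  reported as the transversality check.
* **Focus/node boundary:** the eigenvalue discriminant `tr² - 4 det` is
  tracked per branch (branches indexed by ascending `W` on scan segments
  of constant root count) and its sign changes are refined by bisection.

One structural subtlety: on the v-sweep at `E = 70` the upper equilibrium
branch destabilises at `v ≈ 2.053` through a *trace zero with positive
determinant* — a genuine Hopf point while three equilibria coexist — not
through a discriminant zero.  `find_hopf` therefore reports both
`v ≈ 2.053` and `v ≈ 4.2737`, while `find_focus_node_boundary` reports
only real↔complex transitions (e.g. `v ≈ 1.176`, `E ≈ 85.1`).

## Trajectories and limit cycles

The default integrator is fixed-step RK4 with `dt = 1e-3` (compiled with
numba).  The stiffest linearisation rates along the equilibrium branches
are a few hundred, which keeps `dt = 1e-3` inside the RK4 stability
region with a wide margin; bit-reproducibility motivated the fixed step.
An adaptive mode (SciPy RK45, `rtol 1e-9`) exists for small-`τ` regimes.
Trajectories that exceed `|W| > 1e3` raise a divergence error carrying
the last finite state.  A convergence-order test holds the observed RK4
order above 3.5.

Limit cycles are measured on the Poincaré section `W = W_eq` (the most
unstable equilibrium's abscissa, overridable), crossed with `W`
increasing; crossing times are interpolated linearly, the default run is
`t_end = 200` with the first half discarded as transient, and the cycle
is *converged* when the last three periods agree to `1e-4` relative.
Near folds the orbit lingers at the ghost (periods of 40–80 time units),
so those diagnostics use horizons of 500–1500.  The "all initial
conditions" fixture is the fixed 10-point set spanning both attraction
basins of the bistable regime: (-6,0), (-3,0), (0,0), (3,0), (6,0),
(0,50), (0,150), (3,150), (-3,100), (5,100).

`verify_trapping_region` checks the three stable-cycle conditions on a
closed rectangle numerically: exactly one (unstable) interior
equilibrium, strictly inward flow at all boundary samples, no equilibrium
on the boundary.  Note that an axis-aligned rectangle must clear the
recovery parabola with its top edge (`Z_hi > 5(W_hi+v)²`) while its left
edge requires `Z_hi < -W_lo³ + 30 W_lo + E`; at `(E,v) = (70,3)` the
rectangle `W ∈ [-9, 6.5]`, `Z ∈ [0, 500]` satisfies both and passes, with
the single tangency at `(-3, 0)` avoided by finite sampling.

## SNIC versus off-cycle saddle-node

Whether a fold lies on an invariant circle is a global question.  Just
past the critical parameter (offset `1e-2`, on the side where the
equilibrium pair vanished) the flow is integrated from near the former
fold; the classification is `on_invariant_circle` when the resulting
attractor is a periodic orbit that (a) passes within radius 0.5 of the
ghost in `(W, Z/30)` scaled coordinates (the recovery variable spans
roughly thirty times the voltage range on the relevant orbits), **and**
(b) is the only attractor — no stable equilibrium survives alongside it
and no cycle already existed just below the fold.  Condition (b) is the
discriminating one in this model: at `τ = 1` the surviving equilibrium is
unstable and the ghost-passing cycle is the global attractor (SNIC),
whereas at `τ = 0.152` the surviving focus is *stable* and coexists with
the cycle — the fold happens off a pre-existing excitation loop, even
though that loop also threads the ghost region.  A run with no periodic
attractor returns `inconclusive` rather than either label.

## Forced variant

The forced model drives the `v = 3` regime with
`E(t) = F sin(ωt) + 70` through a translated-and-rescaled recovery
variable `Z ↦ (Z - 70)/10`:

```
dW/dt = -W³ + 30 W - 10 Z + F sin(ωt)
dZ/dt = 5 (W + 3)² - 10 Z - 70
```

Two definitional points, fixed by self-consistency:

1. the translation by 70 absorbs the baseline of the input, so the drive
   entering the rescaled voltage equation is `E(t) - 70 = F sin(ωt)`.
   Re-adding the 70 would instead describe a baseline-140 system — a
   globally monostable damped oscillator (stable focus at `W ≈ 3.37`,
   leading exponent ≈ -7) that never spikes for `F ≤ 20` at any drive
   frequency, which is not the excitable regime of interest;
2. writing the rescaled recovery equation without a `1/10` prefactor is a
   tenfold recovery speed-up, i.e. the original field at `τ(Z) = 0.1`.
   The forced variant therefore has no separate `τ` parameter.

At `F = 0` the system sits on the tonic-spiking limit cycle of the
`(E, v) = (70, 3)` regime (fixed point `W ≈ 1.9030`, unstable), which is
the baseline state the drive modulates.  Slow drive (`ω = 1.56`)
periodically pushes the instantaneous input below the fold value
`≈ 63.52`, producing bursts; `ω = 5.75` phase-locks tonic spiking.

## Lyapunov exponents and regimes

The largest Lyapunov exponent uses the two-trajectory Benettin scheme on
the `(W, Z)` pair with shared explicit time: perturbation `1e-8` along a
fixed direction, renormalisation every 0.5 time units, transient 200,
horizon 2000, `dt = 5e-4` (all overridable; sweeps use transient 100 /
horizon 400 / `dt = 1e-3` per grid point).  Excluding the drive phase
from the perturbed state removes the neutral direction along the forcing.
The estimate is flagged converged when the final 20% of the running
series has spread below `0.05·max(1, |λ|)`.  Determinism is exact: same
settings, same bits.

Spikes are upward crossings of `W = 2` with re-arm below `W = 0` (orbit
geometry: spikes top out near `W ≈ 5-6`, rest sits near `-4`).  Regime
precedence: no spikes → quiescent; converged `λ > spread` → chaotic;
largest consecutive gap ratio in the sorted interspike intervals ≥ 3 →
bursting; else tonic spiking.  The gap-ratio rule is a stated convention,
as is the spike threshold.

A finding worth flagging: at the benchmark fast-drive point
`(F, ω) = (10, 15.02)` this system's attractor is **quasiperiodic**, not
chaotic — the running exponent decays toward zero as the horizon grows
(`+1.2e-3` at horizon 1000, `+6e-5` at 6000), the stroboscopic section is
a one-dimensional closed curve by box-count scaling, and fine scans of
`ω ∈ [14.6, 15.6]` and `F ∈ [9, 11]` find no positive-exponent window.
The amplitude sweep at `ω = 15.02` (step 0.1, stroboscopic samples at
multiples of the drive period, continuation warm starts) shows locked
windows with finitely many stroboscopic values and negative exponents
coexisting with band-filling quasiperiodic regions.  Genuinely chaotic
parameters do exist for faster recovery variants of the same field, but
are outside the model as defined here.

## Known limitations

* Bifurcation detection is numerical (bracketing + Newton); no
  normal-form coefficients (e.g. first Lyapunov coefficient) are
  computed, so sub- versus supercritical Hopf is inferred from simulated
  cycle onset, not proved.
* The SNIC classifier is a finite-horizon flow diagnostic with stated
  offsets and radii, not a proof of an invariant circle.
* The trapping-region check samples the boundary at finitely many points;
  margins are reported so users can judge robustness.
* Two-parameter (codimension-2) continuation, coupled networks and noise
  are out of scope.
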