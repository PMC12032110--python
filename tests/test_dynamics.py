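"""Integration, limit-cycle detection, trapping regions, SNIC classification."""

import numpy as np
import pytest

from cqneuron import (
    STANDARD_INITIAL_CONDITIONS,
    CycleSettings,
    DivergenceError,
    ModelParams,
    State,
    classify_saddle_node_globality,
    detect_limit_cycle,
    find_equilibria,
    find_saddle_node,
    integrate,
    verify_trapping_region,
)

PV3 = ModelParams(E=70.0, v=3.0)


class TestIntegrate:
    def test_equilibrium_is_invariant(self):
        p = ModelParams(E=70.0, v=-10.0)
        (eq,) = find_equilibria(p)
        traj = integrate(p, State(eq.W, eq.Z), 50.0, 1e-3, sample_stride=100)
        assert np.max(np.abs(traj.W - eq.W)) < 1e-3
        assert np.max(np.abs(traj.Z - eq.Z)) < 1e-3

    def test_zero_horizon_returns_initial_sample(self):
        traj = integrate(PV3, State(1.0, 2.0), 0.0)
        assert len(traj.times) == 1
        assert (traj.W[0], traj.Z[0]) == (1.0, 2.0)

    def test_rk4_convergence_order(self):
        initial = State(0.0, 0.0)
        ref = integrate(PV3, initial, 2.0, 5e-5).final_state
        errs = []
        for dt in (8e-4, 4e-4, 2e-4):
            fs = integrate(PV3, initial, 2.0, dt).final_state
            errs.append(np.hypot(fs.W - ref.W, fs.Z - ref.Z))
        orders = np.log2(np.array(errs[:-1]) / np.array(errs[1:]))
        assert np.all(orders >= 3.5)

    def test_divergence_reported_with_last_state(self):
        with pytest.raises(DivergenceError) as err:
            integrate(PV3, State(900.0, 0.0), 1.0, 1e-3)
        assert err.value.last_state is not None

    def test_adaptive_matches_fixed_step(self):
        initial = State(0.5, 10.0)
        a = integrate(PV3, initial, 5.0, 1e-3, method="adaptive", sample_stride=1000)
        b = integrate(PV3, initial, 5.0, 1e-4, sample_stride=10000)
        assert a.W[-1] == pytest.approx(b.W[-1], abs=1e-5)


class TestDetectLimitCycle:
    def test_stable_cycle_from_rest(self):
        cyc = detect_limit_cycle(PV3, State(0.0, 0.0))
        assert cyc is not None and cyc.converged
        assert cyc.period > 0
        assert cyc.W_max > 4 and cyc.W_min < -4  # full relaxation excursion

    def test_cycle_encloses_unstable_equilibrium(self):
        cyc = detect_limit_cycle(PV3, State(0.0, 0.0))
        assert cyc.encloses(1.903, 120.198)

    def test_no_cycle_beyond_hopf(self):
        p = ModelParams(E=70.0, v=4.3)
        for W, Z in STANDARD_INITIAL_CONDITIONS:
            assert detect_limit_cycle(p, State(W, Z)) is None

    def test_cycle_encloses_focus_in_monoinstable_window(self):
        # just past the fold the orbit lingers at the ghost (period ~37),
        # so give the detector a longer horizon
        p = ModelParams(E=70.0, v=2.35)
        cyc = detect_limit_cycle(p, State(0.0, 0.0), CycleSettings(t_end=500.0))
        assert cyc is not None
        assert cyc.encloses(2.7874, 131.9644)

    def test_period_invariant_under_dt_halving(self):
        a = detect_limit_cycle(PV3, State(0.0, 0.0), CycleSettings(dt=1e-3))
        b = detect_limit_cycle(PV3, State(0.0, 0.0), CycleSettings(dt=5e-4))
        assert a.period == pytest.approx(b.period, rel=1e-3)

    def test_cycle_amplitude_grows_past_hopf(self):
        # supercritical onset: cycles exist just below the Hopf value and
        # W-amplitude grows with the distance to it
        v_hopf = 4.2737
        amps = []
        for delta in (0.01, 0.05, 0.1):
            cyc = detect_limit_cycle(
                ModelParams(E=70.0, v=v_hopf - delta),
                State(-3.1, 6.8),
                CycleSettings(t_end=400.0),
            )
            assert cyc is not None
            amps.append(cyc.amplitude)
        assert amps[0] < amps[1] < amps[2]
        assert (
            detect_limit_cycle(
                ModelParams(E=70.0, v=v_hopf + 0.05),
                State(-3.1, 6.8),
                CycleSettings(t_end=400.0),
            )
            is None
        )

    def test_bistability_window(self):
        # excited and resting state coexist at v=1: the standard initial
        # conditions split between two distinct stable equilibria
        p = ModelParams(E=70.0, v=1.0)
        finals = set()
        for W, Z in STANDARD_INITIAL_CONDITIONS:
            traj = integrate(p, State(W, Z), 100.0, 1e-3, sample_stride=100)
            finals.add(round(traj.W[-1], 2))
        assert len(finals) == 2

    def test_growing_cycle_with_slow_recovery(self):
        # slow recovery (tau = 6.6): cycles from near the upper unstable
        # equilibrium, W-amplitude non-decreasing in v
        amps = []
        for v in (2.4, 2.5, 2.6, 2.7, 2.8):
            p = ModelParams(E=70.0, v=v, tau=6.6)
            upper = find_equilibria(p)[-1]
            cyc = detect_limit_cycle(
                # periods reach ~80 at the low end of the grid
                p, State(upper.W + 0.3, upper.Z), CycleSettings(t_end=1500.0)
            )
            assert cyc is not None
            amps.append(cyc.amplitude)
        assert all(b >= a - 1e-6 for a, b in zip(amps, amps[1:]))


class TestTrappingRegion:
    # a rectangle whose edges the flow crosses strictly inward; the top
    # edge must clear the recovery parabola (Z_hi > 5 (W_hi + 3)^2) while
    # the left edge requires Z_hi < -W_lo^3 + 30 W_lo + E
    REGION = (-9.0, 6.5, 0.0, 500.0)

    def test_region_traps_flow_around_unstable_equilibrium(self):
        rep = verify_trapping_region(PV3, self.REGION, 400)
        assert rep.passed
        assert rep.inward_margin < 0
        assert rep.n_inside == 1

    def test_fails_when_equilibrium_outside_and_stable(self):
        rep = verify_trapping_region(ModelParams(E=70.0, v=-10.0), self.REGION, 400)
        assert not rep.unique_unstable_inside
        assert not rep.passed

    def test_degenerate_rectangle_reports_condition_failure(self):
        rep = verify_trapping_region(PV3, (1.0, 1.0, 0.0, 0.0), 40)
        assert not rep.unique_unstable_inside
        assert not rep.passed


class TestSaddleNodeGlobality:
    def test_invariant_circle_at_default_recovery_rate(self):
        fixed = ModelParams(E=70.0, v=0.0, tau=1.0)
        sn = find_saddle_node("v", fixed, (0.0, 6.0))[0]
        rep = classify_saddle_node_globality(fixed, sn)
        assert rep.label == "on_invariant_circle"
        assert rep.ghost_distance < 0.5
        assert not rep.coexisting_stable_equilibrium

    def test_off_cycle_with_fast_recovery(self):
        # fast recovery (tau = 0.152): the cycle coexists with a stable
        # focus just past the fold, so the saddle-node is off the cycle
        fixed = ModelParams(E=70.0, v=0.0, tau=0.152)
        sn = find_saddle_node("v", fixed, (0.0, 6.0))[0]
        rep = classify_saddle_node_globality(fixed, sn)
        assert rep.label == "off_cycle"
        assert rep.coexisting_stable_equilibrium
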