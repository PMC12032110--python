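"""Steady-state roots, eigenvalues and stability classification."""

import cmath
import math

import numpy as np
import pytest
from scipy.linalg import eigvals

from cqneuron import (
    ModelParams,
    Stability,
    State,
    classify_stability,
    eigenvalues_at,
    find_equilibria,
    steady_state_cubic,
    steady_state_roots,
    vector_field,
)
from cqneuron.catalogue import EQUILIBRIUM_BENCHMARKS


def cardano_real_roots(c3, c2, c1, c0):
    """Closed-form cubic roots (test oracle, independent of the solver).

    Depressed-cubic substitution W = y - c2/(3 c3), then Cardano/trigonometric
    branches by discriminant sign.
    """
    a, b, c, d = c3, c2, c1, c0
    p = (3 * a * c - b**2) / (3 * a**2)
    q = (2 * b**3 - 9 * a * b * c + 27 * a**2 * d) / (27 * a**3)
    shift = -b / (3 * a)
    disc = (q / 2) ** 2 + (p / 3) ** 3
    if disc > 0:  # one real root
        u = np.cbrt(-q / 2 + math.sqrt(disc))
        v = np.cbrt(-q / 2 - math.sqrt(disc))
        return [u + v + shift]
    if abs(disc) < 1e-14 * max(1.0, q**2):  # double root boundary
        u = np.cbrt(-q / 2)
        return sorted([2 * u + shift, -u + shift])
    # three real roots: trigonometric form
    r = math.sqrt(-(p**3) / 27)
    phi = math.acos(max(-1.0, min(1.0, -q / (2 * r))))
    m = 2 * math.sqrt(-p / 3)
    return sorted(m * math.cos((phi + 2 * math.pi * k) / 3) + shift for k in range(3))


class TestSteadyStateRoots:
    def test_single_root_strong_negative_offset(self):
        roots = steady_state_roots(ModelParams(E=70.0, v=-10.0))
        assert len(roots) == 1
        assert roots[0].W == pytest.approx(-15.3187, abs=1e-4)

    def test_double_root_reported_with_multiplicity(self):
        roots = steady_state_roots(ModelParams(E=45.0, v=3.0))
        assert [(round(r.W, 6), r.multiplicity) for r in roots] == [(-5.0, 1), (0.0, 2)]

    def test_three_roots_ascending(self):
        roots = steady_state_roots(ModelParams(E=70.0, v=1.5))
        assert [r.W for r in roots] == pytest.approx(
            [-5.8469, -2.7745, 3.6215], abs=1e-4
        )

    def test_roots_annihilate_cubic(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            p = ModelParams(E=rng.uniform(0, 200), v=rng.uniform(-12, 6))
            h = steady_state_cubic(p)
            for r in steady_state_roots(p):
                assert abs(h(r.W)) < 1e-8 * max(1.0, max(abs(c) for c in h.coeffs))

    def test_agrees_with_companion_matrix(self):
        # independent oracle: explicit companion matrix + LAPACK eigenvalues
        rng = np.random.default_rng(2024)
        for _ in range(1000):
            p = ModelParams(E=rng.uniform(0, 200), v=rng.uniform(-12, 6))
            c0, c1, c2, c3 = steady_state_cubic(p).coeffs
            comp = np.array(
                [
                    [-c2 / c3, -c1 / c3, -c0 / c3],
                    [1.0, 0.0, 0.0],
                    [0.0, 1.0, 0.0],
                ]
            )
            lam = eigvals(comp)
            oracle = sorted(x.real for x in lam if abs(x.imag) < 1e-7 * max(1, abs(x)))
            ours = sorted(
                [r.W for r in steady_state_roots(p) for _ in range(r.multiplicity)]
            )
            assert len(ours) == len(oracle)
            assert np.allclose(ours, oracle, atol=1e-7)

    def test_agrees_with_cardano_closed_form(self):
        rng = np.random.default_rng(77)
        for _ in range(100):
            p = ModelParams(E=rng.uniform(0, 200), v=rng.uniform(-12, 6))
            c0, c1, c2, c3 = steady_state_cubic(p).coeffs
            oracle = cardano_real_roots(c3, c2, c1, c0)
            ours = [r.W for r in steady_state_roots(p)]
            assert len(ours) == len(oracle)
            assert np.allclose(ours, oracle, atol=1e-6)

    def test_root_count_interval_structure(self):
        # one equilibrium outside [v1, v4], three strictly inside, two at
        # the fold endpoints (parameter tolerance 1e-3)
        v1, v4 = -9.359, 2.3304
        at = lambda v: sum(r.multiplicity for r in steady_state_roots(ModelParams(E=70.0, v=v)))
        n_at = lambda v: len(steady_state_roots(ModelParams(E=70.0, v=v)))
        assert n_at(v1 - 0.002) == 1 and n_at(v4 + 0.002) == 1
        assert n_at(v1 + 0.002) == 3 and n_at(v4 - 0.002) == 3
        # at the fold itself (located precisely first): a simple root plus
        # a double root, total multiplicity 3
        from cqneuron import find_saddle_node

        for bracket in ((-12.0, 0.0), (0.0, 6.0)):
            sn = find_saddle_node("v", ModelParams(E=70.0, v=0.0), bracket)[0]
            assert at(sn.critical_value) == 3
            assert n_at(sn.critical_value) == 2


class TestEigenvaluesAt:
    def test_complex_pair_at_benchmark(self):
        l1, l2 = eigenvalues_at(3.6215, ModelParams(E=70.0, v=1.5))
        assert l1 == pytest.approx(complex(-5.1729, 5.8139), abs=1e-3)
        assert l2 == pytest.approx(complex(-5.1729, -5.8139), abs=1e-3)

    def test_real_pair_at_benchmark(self):
        l1, l2 = eigenvalues_at(1.9030, ModelParams(E=70.0, v=3.0))
        assert l1.real == pytest.approx(16.3020, abs=1e-3)
        assert l2.real == pytest.approx(1.8338, abs=1e-3)
        assert l1.imag == 0.0 and l2.imag == 0.0

    def test_trace_determinant_identities(self):
        rng = np.random.default_rng(13)
        for _ in range(1000):
            W = rng.uniform(-20, 20)
            p = ModelParams(
                E=70.0, v=rng.uniform(-12, 6), tau=rng.uniform(0.05, 8.0)
            )
            l1, l2 = eigenvalues_at(W, p)
            tr = (-3 * W**2 + 30) - 1 / p.tau
            det = (3 * W**2 + 10 * W - 30 + 10 * p.v) / p.tau
            scale = max(1.0, abs(tr), abs(det))
            assert abs((l1 + l2) - tr) < 1e-10 * scale
            assert abs((l1 * l2) - det) < 1e-10 * scale


class TestClassifyStability:
    @pytest.mark.parametrize(
        "eigs, expected",
        [
            ((-674.3637, -0.6240), Stability.STABLE_NODE),
            ((complex(0.4509, 7.0355), complex(0.4509, -7.0355)), Stability.UNSTABLE_FOCUS),
            ((complex(-2.0117, 3.2861), complex(-2.0117, -3.2861)), Stability.STABLE_FOCUS),
            ((29.8102, -2.3875), Stability.SADDLE),
            ((16.3020, 1.8338), Stability.UNSTABLE_NODE),
            ((0.0, -1.0), Stability.NON_HYPERBOLIC),
            ((complex(0.0, 2.0), complex(0.0, -2.0)), Stability.NON_HYPERBOLIC),
        ],
    )
    def test_classes(self, eigs, expected):
        assert classify_stability(eigs, zero_tol=1e-6) is expected

    def test_rejects_non_conjugate_pair(self):
        with pytest.raises(ValueError):
            classify_stability((complex(1, 2), complex(3, 4)))


class TestFindEquilibria:
    def test_three_equilibria_at_intermediate_offset(self):
        eqs = find_equilibria(ModelParams(E=70.0, v=-5.0))
        assert [e.W for e in eqs] == pytest.approx(
            [-12.0301, 0.7251, 6.3049], abs=1e-4
        )

    def test_unique_unstable_node(self):
        (eq,) = find_equilibria(ModelParams(E=70.0, v=3.0))
        assert eq.W == pytest.approx(1.9030, abs=1e-3)
        assert eq.Z == pytest.approx(5 * (eq.W + 3) ** 2, abs=1e-9)
        assert eq.stability is Stability.UNSTABLE_NODE

    def test_residual_vanishes_at_equilibria(self):
        rng = np.random.default_rng(19)
        for _ in range(50):
            p = ModelParams(
                E=rng.uniform(0, 200), v=rng.uniform(-12, 6), tau=rng.uniform(0.1, 5)
            )
            for eq in find_equilibria(p):
                dW, dZ = vector_field(State(eq.W, eq.Z), p)
                assert max(abs(dW), abs(dZ)) < 1e-9 * max(1.0, abs(p.E), eq.Z)

    def test_eigenvalue_pair_solves_characteristic_polynomial(self):
        for eq in find_equilibria(ModelParams(E=70.0, v=1.5)):
            J = eq.jacobian()
            tr, det = np.trace(J), np.linalg.det(J)
            for lam in eq.eigenvalues:
                res = lam**2 - tr * lam + det
                assert abs(res) < 1e-8 * max(1.0, abs(det))

    def test_all_benchmark_stability_classes_reproduced(self):
        for bm in EQUILIBRIUM_BENCHMARKS:
            eqs = find_equilibria(ModelParams(E=70.0, v=bm.v))
            eq = min(eqs, key=lambda e: abs(e.W - bm.W))
            assert abs(eq.W - bm.W) < 1e-3
            assert eq.stability.value == bm.stability
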