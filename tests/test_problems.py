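"""Core representations: energies, conversions, oracles."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cimkit import (
    IsingProblem,
    QUBOProblem,
    WeightedGraph,
    brute_force_ground,
    cut_value,
    ising_energy,
    ising_with_fields_to_fieldless,
    maxcut_to_ising,
    qubo_energy,
    qubo_to_ising,
)
from cimkit.problems import brute_force_qubo, enumerate_binary

from conftest import random_ising, random_qubo


def all_spins(n):
    for bits in itertools.product((-1, 1), repeat=n):
        yield np.array(bits, dtype=np.int8)


class TestIsingEnergy:
    def test_single_pair(self):
        p = IsingProblem(J=[[0, 1], [1, 0]])
        assert ising_energy(p, [1, 1]) == -1

    def test_empty_hamiltonian(self):
        p = IsingProblem(J=np.zeros((5, 5)))
        assert ising_energy(p, [1, -1, 1, -1, 1]) == 0

    def test_matches_triple_loop_oracle(self, rng):
        p = random_ising(rng, 4, field_scale=1.0)
        for s in all_spins(4):
            expected = p.offset
            for i in range(4):
                expected -= p.h[i] * s[i]
                for j in range(i + 1, 4):
                    expected -= p.J[i, j] * s[i] * s[j]
            assert ising_energy(p, s) == pytest.approx(expected, abs=1e-12)

    def test_dimension_mismatch_rejected(self):
        p = IsingProblem(J=np.zeros((3, 3)))
        with pytest.raises(ValueError):
            ising_energy(p, [1, -1])

    def test_gauge_symmetry_without_fields(self, rng):
        p = random_ising(rng, 5)
        for s in all_spins(5):
            assert ising_energy(p, s) == pytest.approx(ising_energy(p, -s))

    @pytest.mark.parametrize(
        "bad", [np.ones((3, 4)), [[0, 1], [2, 0]], [[1, 1], [1, 0]]],
        ids=["rectangular", "asymmetric", "nonzero-diagonal"],
    )
    def test_invalid_couplings_rejected(self, bad):
        with pytest.raises(ValueError):
            IsingProblem(J=bad)


class TestQuboEnergy:
    def test_single_variable(self):
        q = QUBOProblem(Q=[[3.0]])
        assert qubo_energy(q, [1]) == 3.0

    def test_all_zeros_gives_offset(self, rng):
        q = random_qubo(rng, 4)
        assert qubo_energy(q, np.zeros(4, dtype=int)) == pytest.approx(q.offset)

    def test_matches_double_loop_oracle(self, rng):
        q = random_qubo(rng, 5)
        for x in enumerate_binary(5):
            expected = q.offset
            for j in range(5):
                for k in range(j, 5):
                    expected += q.Q[j, k] * x[j] * x[k]
            assert qubo_energy(q, x) == pytest.approx(expected, abs=1e-12)

    def test_non_binary_rejected(self):
        q = QUBOProblem(Q=[[1.0]])
        with pytest.raises(ValueError):
            qubo_energy(q, [2])

    def test_lower_triangle_rejected(self):
        with pytest.raises(ValueError):
            QUBOProblem(Q=[[1, 0], [1, 1]])


class TestQuboToIsing:
    def test_single_linear_term(self):
        ising = qubo_to_ising(QUBOProblem(Q=[[1.0]]))
        assert ising.h[0] == pytest.approx(-0.5)
        assert ising.offset == pytest.approx(0.5)
        assert ising_energy(ising, [-1]) == pytest.approx(0.0)  # x=0
        assert ising_energy(ising, [1]) == pytest.approx(1.0)  # x=1

    def test_pure_offset(self):
        ising = qubo_to_ising(QUBOProblem(Q=np.zeros((3, 3)), offset=2.5))
        assert np.all(ising.J == 0) and np.all(ising.h == 0)
        assert ising.offset == 2.5

    def test_exact_equality_on_all_assignments(self, rng):
        q = random_qubo(rng, 8)
        ising = qubo_to_ising(q)
        for x in enumerate_binary(8):
            sigma = (2 * x - 1).astype(np.int8)
            assert ising_energy(ising, sigma) == pytest.approx(
                qubo_energy(q, x), abs=1e-10
            )

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(n=st.integers(1, 6), seed=st.integers(0, 2**31 - 1))
    def test_energy_preserved_property(self, n, seed):
        q = random_qubo(np.random.default_rng(seed), n)
        ising = qubo_to_ising(q)
        for x in enumerate_binary(n):
            sigma = (2 * x - 1).astype(np.int8)
            assert ising_energy(ising, sigma) == pytest.approx(
                qubo_energy(q, x), abs=1e-9
            )


class TestAncillaReduction:
    def test_fieldless_input_gains_decoupled_ancilla(self, rng):
        p = random_ising(rng, 4)
        r = ising_with_fields_to_fieldless(p)
        assert r.N == 5
        assert np.all(r.J[4, :4] == 0)
        assert not r.has_fields

    def test_single_spin_field_ground_states(self):
        p = IsingProblem(J=[[0.0]], h=[1.0])
        r = ising_with_fields_to_fieldless(p)
        e, configs = brute_force_ground(r)
        assert e == -1
        # gauge-fixed representative: both spins aligned with the ancilla
        assert all(np.all(c == c[-1]) for c in configs)

    def test_energies_match_in_positive_ancilla_sector(self, rng):
        p = random_ising(rng, 6, field_scale=1.0)
        r = ising_with_fields_to_fieldless(p)
        for s in all_spins(6):
            ext = np.append(s, 1).astype(np.int8)
            assert ising_energy(r, ext) == pytest.approx(ising_energy(p, s))

    def test_ground_energy_preserved(self, rng):
        p = random_ising(rng, 6, field_scale=1.0)
        r = ising_with_fields_to_fieldless(p)
        assert brute_force_ground(r)[0] == pytest.approx(brute_force_ground(p)[0])


class TestMaxCut:
    def test_single_edge(self):
        g = WeightedGraph(V=2, edges=((0, 1, 1.0),))
        p = maxcut_to_ising(g)
        assert ising_energy(p, [1, -1]) == -1
        assert cut_value(g, [1, -1]) == 1

    def test_triangle_cut_identity_all_configs(self):
        g = WeightedGraph(V=3, edges=((0, 1, 1.0), (0, 2, 1.0), (1, 2, 1.0)))
        p = maxcut_to_ising(g)
        for s in all_spins(3):
            cut = cut_value(g, s)
            assert cut == pytest.approx((g.total_weight - ising_energy(p, s)) / 2)
            assert cut in (0, 2)

    def test_cut_identity_random_graph(self, rng):
        from cimkit import random_graph

        g = random_graph(10, 0.4, seed=5)
        p = maxcut_to_ising(g)
        for _ in range(100):
            s = rng.choice([-1, 1], size=10)
            assert cut_value(g, s) == pytest.approx(
                (g.total_weight - ising_energy(p, s)) / 2
            )

    def test_all_equal_spins_cut_zero(self):
        g = WeightedGraph(V=4, edges=((0, 1, 2.0), (2, 3, 1.5)))
        assert cut_value(g, [1, 1, 1, 1]) == 0

    def test_even_cycle_alternating_cuts_all(self):
        V = 8
        g = WeightedGraph(V=V, edges=tuple((i, (i + 1) % V, 1.0) for i in range(V - 1)) + ((0, V - 1, 1.0),))
        s = np.array([(-1) ** i for i in range(V)])
        assert cut_value(g, s) == V

    def test_complete_graph_balanced_split(self):
        edges = tuple((i, j, 1.0) for i in range(6) for j in range(i + 1, 6))
        g = WeightedGraph(V=6, edges=edges)
        s = np.array([1, 1, 1, -1, -1, -1])
        assert cut_value(g, s) == 9
        p = maxcut_to_ising(g)
        e, _ = brute_force_ground(p)
        assert (g.total_weight - e) / 2 == 9  # 6^2/4 is the maximum


class TestBruteForce:
    def test_two_spin_ferromagnet(self):
        p = IsingProblem(J=[[0, 1], [1, 0]])
        e, configs = brute_force_ground(p)
        assert e == -1
        assert len(configs) == 1 and np.all(configs[0] == 1)

    def test_mobius_8_max_cut(self):
        from cimkit import mobius_ladder

        g = mobius_ladder(8)
        e, _ = brute_force_ground(maxcut_to_ising(g))
        assert (g.total_weight - e) / 2 == 10

    def test_mobius_20_matches_formula(self):
        from cimkit import mobius_ladder

        g = mobius_ladder(20)
        e, _ = brute_force_ground(maxcut_to_ising(g))
        assert (g.total_weight - e) / 2 == 3 * 20 // 2 - 2

    def test_size_guard(self):
        with pytest.raises(ValueError):
            brute_force_ground(IsingProblem(J=np.zeros((25, 25))))

    def test_qubo_brute_force_matches_enumeration(self, rng):
        q = random_qubo(rng, 7)
        e, x = brute_force_qubo(q)
        expected = min(qubo_energy(q, x) for x in enumerate_binary(7))
        assert e == pytest.approx(expected, abs=1e-12)
        assert qubo_energy(q, x) == pytest.approx(e)


class TestWeightedGraph:
    def test_rejects_self_loop(self):
        with pytest.raises(ValueError):
            WeightedGraph(V=3, edges=((1, 1, 1.0),))

    def test_rejects_duplicate_edge(self):
        with pytest.raises(ValueError):
            WeightedGraph(V=3, edges=((0, 1, 1.0), (1, 0, 2.0)))

    def test_canonicalizes_orientation(self):
        g = WeightedGraph(V=3, edges=((2, 0, 1.5),))
        assert g.edges == ((0, 2, 1.5),)
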