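"""Mechanism repertoires, disintegrating partitions, φ_d, and distinctions."""

import itertools

import numpy as np
import pytest

import phistruct as ps
from phistruct import statespace as ss
from phistruct.mechanisms import (
    cause_repertoire,
    compute_distinctions,
    distinction_phi,
    effect_repertoire,
    enumerate_disintegrations,
    maximal_purview,
    mechanism_ii,
)
from phistruct.integration import system_phi
from phistruct.system import condition

from conftest import oracle_effect_repertoire, random_net


def swap_pair():
    """Deterministic mutual copies A<->B (exact truth tables)."""
    alpha = (2, 2)
    ta = np.zeros((4, 2))
    tb = np.zeros((4, 2))
    for r in range(4):
        a, b = ss.index_state(r, alpha)
        ta[r, b] = 1.0
        tb[r, a] = 1.0
    return ps.Network(["A", "B"], alpha, [ta, tb], (1, 0))


class TestRepertoires:
    def test_full_mechanism_deterministic_point_mass(self):
        system = condition(swap_pair(), [0, 1])
        rep = effect_repertoire(system, 0b11, 0b11)
        # A=1,B=0 deterministically maps to A=0,B=1
        want = np.zeros(4)
        want[ss.state_index((0, 1), (2, 2))] = 1.0
        assert np.allclose(rep.table, want)

    def test_empty_mechanism_is_product_of_marginals(self):
        system = condition(random_net(4), [0, 1, 2])
        rep = effect_repertoire(system, 0, 0b111)
        want = np.ones(8)
        for znum, z in enumerate(ss.iter_states((2, 2, 2))):
            v = 1.0
            for p in range(3):
                v *= system.te_factors[p][:, z[p]].mean()
            want[znum] = v
        assert np.allclose(rep.table, want, atol=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_effect_repertoire_matches_enumeration_oracle(self, seed):
        system = condition(random_net(seed), [0, 1, 2])
        for mech, purview in [((0,), (1,)), ((0, 2), (0, 1)), ((1,), (0, 1, 2)), ((0, 1, 2), (2,))]:
            mmask = sum(1 << p for p in mech)
            zmask = sum(1 << p for p in purview)
            rep = effect_repertoire(system, mmask, zmask)
            want = oracle_effect_repertoire(system, list(mech), list(purview))
            assert np.allclose(rep.table, want, atol=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_cause_repertoire_matches_enumeration_oracle(self, seed):
        system = condition(random_net(seed), [0, 1, 2])
        tc = system.cause_tpm()
        for mech, purview in [((1,), (0,)), ((0, 1), (1, 2)), ((2,), (0, 1, 2))]:
            mmask = sum(1 << p for p in mech)
            zmask = sum(1 << p for p in purview)
            rep = cause_repertoire(system, mmask, zmask)
            # oracle: average full-row factors over non-purview prior units
            z_alpha = [system.alphabets[p] for p in purview]
            want = np.ones(ss.n_states(z_alpha))
            for znum, z in enumerate(ss.iter_states(z_alpha)):
                v = 1.0
                for u in mech:
                    acc, cnt = 0.0, 0
                    for full in ss.iter_states(system.alphabets):
                        if any(full[p] != zz for p, zz in zip(purview, z)):
                            continue
                        acc += system.tc_factors[u][
                            ss.state_index(full, system.alphabets), system.state[u]
                        ]
                        cnt += 1
                    v *= acc / cnt
                want[znum] = v
            assert np.allclose(rep.table, want, atol=1e-12)

    def test_single_unit_mechanism_is_plain_conditional(self):
        system = condition(random_net(7), [0, 1, 2])
        rep = cause_repertoire(system, 0b001, 0b110)
        assert np.allclose(rep.table, system.cause_factor_table(0, 0b110))

    def test_impossible_mechanism_state_flagged(self):
        system = condition(random_net(1), [0, 1, 2])
        system._caches.clear()
        system.tc_factors[0] = np.zeros_like(system.tc_factors[0])  # causeless by fiat
        rep = cause_repertoire(system, 0b001, 0b110)
        assert rep.undefined and rep.backward is None
        phi, _, _ = distinction_phi(system, 0b001, 0b110, "cause")
        assert phi == 0.0


class TestMechanismII:
    def test_deterministic_copy_one_ibit(self):
        system = condition(swap_pair(), [0, 1])
        rep, ii, tied = mechanism_ii(system, 0b01, 0b10, "effect")  # A over B
        assert max(ii) == pytest.approx(1.0)
        assert tied == [ss.state_index((1,), (2,))]  # B -> ON (copies A=1)

    def test_unconstrained_pair_zero(self):
        tables = [np.full((4, 2), 0.5), np.full((4, 2), 0.5)]
        net = ps.Network(["A", "B"], (2, 2), tables, (0, 0))
        system = condition(net, [0, 1])
        _, ii, tied = mechanism_ii(system, 0b01, 0b10, "effect")
        assert np.allclose(ii, 0.0) and tied == []

    def test_cycle_first_order_matches_direct_evaluation(self, cycle6):
        system = condition(cycle6, range(6))
        for zpos in range(6):
            rep, ii, _ = mechanism_ii(system, 0b000001, 1 << zpos, "effect")
            want = rep.table * np.log2(rep.table / rep.unconstrained)
            assert np.allclose(ii, want, atol=1e-12)


class TestDisintegrations:
    def test_minimal_pair_single_partition(self):
        parts = enumerate_disintegrations(0b01, 0b10)
        assert len(parts) == 1
        assert set(parts[0].parts) == {(0b01, 0), (0, 0b10)}
        assert parts[0].normalization == 1

    def test_count_matches_independent_bruteforce(self):
        # independent enumeration: assign each element a block id
        def brute(m_elems, z_elems):
            elems = [("m", x) for x in m_elems] + [("z", x) for x in z_elems]
            seen = set()
            for labels in itertools.product(range(len(elems)), repeat=len(elems)):
                blocks = {}
                for e, l in zip(elems, labels):
                    blocks.setdefault(l, []).append(e)
                if len(blocks) < 2:
                    continue
                key = frozenset(frozenset(b) for b in blocks.values())
                ok = True
                for b in blocks.values():
                    ms = {x for k, x in b if k == "m"}
                    zs = {x for k, x in b if k == "z"}
                    if ms == set(m_elems) and zs:
                        ok = False
                if ok:
                    seen.add(key)
            return len(seen)

        for m_elems, z_elems in [([0], [1]), ([0, 1], [2]), ([0, 1], [2, 3]), ([0], [1, 2])]:
            mmask = sum(1 << x for x in m_elems)
            zmask = sum(1 << x for x in z_elems)
            assert len(enumerate_disintegrations(mmask, zmask)) == brute(m_elems, z_elems)

    def test_intact_pair_excluded(self):
        for theta in enumerate_disintegrations(0b011, 0b100):
            assert (0b011, 0b100) not in theta.parts

    def test_normalization_positive(self):
        for theta in enumerate_disintegrations(0b011, 0b110):
            assert theta.normalization >= 1


class TestDistinctionPhi:
    def test_disconnected_mechanism_zero(self):
        # two independent self-loop units: A has no effect on B
        net = ps.build_logistic_network(ps.LogisticSpec(np.eye(2), 4.0), (1, 0))
        system = condition(net, [0, 1])
        phi, _, _ = distinction_phi(system, 0b01, 0b10, "effect")
        assert phi == 0.0

    def test_cycle_first_order_single_disintegration_value(self, cycle6):
        # mechanism {A} over its successor {B}: the only disintegration fully
        # severs the connection, so phi equals the direct formula
        system = condition(cycle6, range(6))
        phi, z_state, mip = distinction_phi(system, 0b000001, 0b000010, "effect")
        p = 1.0 / (1.0 + np.exp(-4.0))
        want = p * np.log2(p / 0.5)
        assert phi == pytest.approx(want, abs=1e-12)
        assert z_state == {1: 1}  # B driven ON

    @pytest.mark.parametrize("seed", range(6))
    def test_zero_shortcut_agrees_with_full_enumeration(self, seed):
        system = condition(random_net(seed), [0, 1, 2])
        for mmask in range(1, 8):
            for zmask in range(1, 8):
                for side in ("effect", "cause"):
                    fast = distinction_phi(system, mmask, zmask, side, shortcut=True)[0]
                    slow = distinction_phi(system, mmask, zmask, side, shortcut=False)[0]
                    assert fast == pytest.approx(slow, abs=1e-9)

    @pytest.mark.parametrize("seed", range(4))
    def test_phi_zero_when_nothing_specified(self, seed):
        # a mechanism that specifies no purview state (max ii ≤ 0) cannot be
        # irreducible over it; and φ is never negative
        system = condition(random_net(seed), [0, 1, 2])
        for mmask in range(1, 8):
            for zmask in range(1, 8):
                for side in ("effect", "cause"):
                    _, ii, tied = mechanism_ii(system, mmask, zmask, side)
                    phi, _, _ = distinction_phi(system, mmask, zmask, side)
                    assert phi >= 0.0
                    if not tied:
                        assert phi == 0.0


class TestMaximalPurview:
    def test_copy_chain_selects_neighbours(self):
        # 3-unit shift cycle: B's effect purview is C, cause purview is A
        alpha = (2, 2, 2)
        tables = []
        for i in range(3):
            t = np.zeros((8, 2))
            for r in range(8):
                t[r, ss.index_state(r, alpha)[(i - 1) % 3]] = 1.0
            tables.append(t)
        net = ps.Network(["A", "B", "C"], alpha, tables, (1, 0, 0))
        system = condition(net, [0, 1, 2])
        e_mask, _, e_phi, _ = maximal_purview(system, 0b010, "effect")
        c_mask, _, c_phi, _ = maximal_purview(system, 0b010, "cause")
        assert e_mask == 0b100 and c_mask == 0b001
        assert e_phi == pytest.approx(1.0) and c_phi == pytest.approx(1.0)

    def test_disconnected_mechanism_null_purview(self):
        net = ps.build_logistic_network(ps.LogisticSpec(np.eye(2), 4.0), (1, 0))
        system = condition(net, [0, 1])
        # A's only causal route is its self-loop; restrict attention to B side:
        # mechanism {A} can specify nothing about {B}
        phi, _, _ = distinction_phi(system, 0b01, 0b10, "effect")
        assert phi == 0.0


class TestDistinctionSet:
    def test_candidate_count_and_first_order_cycle(self, cycle6_structure):
        st = cycle6_structure
        assert st.n_candidate_mechanisms == 63
        assert len(st.distinctions) == 6
        assert all(d.order == 1 for d in st.distinctions)

    def test_congruence_filter_uses_states(self, cycle6_structure):
        # every kept purview state must be a sub-state of the system's
        # maximal cause/effect state
        st = cycle6_structure
        ces = st.system_result.ces
        s_c = ss.index_state(ces.cause_state, st.system.alphabets)
        s_e = ss.index_state(ces.effect_state, st.system.alphabets)
        for d in st.distinctions:
            assert all(s_c[p] == v for p, v in d.cause)
            assert all(s_e[p] == v for p, v in d.effect)

    def test_phi_d_is_min_of_sides(self, cycle6_structure):
        for d in cycle6_structure.distinctions:
            assert d.phi_d == pytest.approx(min(d.phi_c, d.phi_e))
            assert d.phi_d > 0

    def test_joint_dependency_yields_high_order_distinction(self):
        # deterministic bijection with a genuine joint dependency
        # (A' = A XOR B, B' = A): the full mechanism is irreducible, unlike a
        # pure copy loop where every unit factorizes onto a single parent
        alpha = (2, 2)
        ta = np.zeros((4, 2))
        tb = np.zeros((4, 2))
        for r in range(4):
            a, b = ss.index_state(r, alpha)
            ta[r, a ^ b] = 1.0
            tb[r, a] = 1.0
        net = ps.Network(["A", "B"], alpha, [ta, tb], (1, 0))
        system = condition(net, [0, 1])
        phi_e, _, _ = distinction_phi(system, 0b11, 0b11, "effect")
        assert phi_e > 0
        res = system_phi(system)
        dset = compute_distinctions(system, res.ces)
        assert any(d.order == 2 for d in dset)
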