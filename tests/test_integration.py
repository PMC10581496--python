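"""Directional partitions, partitioned TPMs, and system integrated information."""

import itertools

import numpy as np
import pytest

import phistruct as ps
from phistruct import statespace as ss
from phistruct.integration import partitioned_tpm, phi_directional, system_phi
from phistruct.partitions import enumerate_partitions, labeled_partitions
from phistruct.system import condition

from conftest import random_net, states


class TestPartitionEnumeration:
    def test_two_units_collapse_to_three_cuts(self):
        parts = enumerate_partitions([0, 1])
        assert len(parts) == 3
        cuts = {p.cut_pairs for p in parts}
        assert cuts == {
            frozenset({(0, 1)}),
            frozenset({(1, 0)}),
            frozenset({(0, 1), (1, 0)}),
        }

    def test_three_units_raw_labeling_count(self):
        # 3 bipartitions × 3² labelings + 1 tripartition × 3³ = 54
        assert sum(1 for _ in labeled_partitions([0, 1, 2])) == 54

    def test_single_unit_complete_self_cut(self):
        parts = enumerate_partitions([0])
        assert len(parts) == 1
        assert parts[0].cut_pairs == frozenset({(0, 0)})
        assert parts[0].normalization == 1

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            enumerate_partitions([])

    def test_normalization_counts_cut_pairs(self):
        for p in enumerate_partitions([0, 1, 2, 3]):
            assert p.normalization == len(p.cut_pairs) > 0


class TestPartitionedTPM:
    def oracle(self, system, partition, side):
        """Brute-force causal marginalization of each unit's cut inputs."""
        n = system.n
        factors = system.te_factors if side == "e" else system.tc_factors
        cut = {t: [s for (tt, s) in partition.cut_pairs if tt == t] for t in range(n)}
        nfull = system.n_states
        out = np.ones((nfull, nfull))
        for r, row_state in enumerate(states(system.alphabets)):
            for c, col_state in enumerate(states(system.alphabets)):
                v = 1.0
                for t in range(n):
                    acc, cnt = 0.0, 0
                    for noisy in states([system.alphabets[i] for i in cut[t]]):
                        full = list(row_state)
                        for i, x in zip(cut[t], noisy):
                            full[i] = x
                        acc += factors[t][ss.state_index(full, system.alphabets), col_state[t]]
                        cnt += 1
                    v *= acc / cnt
                out[r, c] = v
        return out

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_bruteforce_marginalization(self, seed):
        system = condition(random_net(seed), [0, 1, 2])
        for partition in enumerate_partitions(range(3)):
            for side in ("e", "c"):
                got = partitioned_tpm(system, partition, side)
                assert np.allclose(got, self.oracle(system, partition, side), atol=1e-12)

    def test_independent_units_unaffected(self):
        # two self-loop units with no cross edges: any partition is inert
        w = np.eye(2)
        net = ps.build_logistic_network(ps.LogisticSpec(w, 4.0), (1, 0))
        system = condition(net, [0, 1])
        for partition in enumerate_partitions([0, 1]):
            assert np.allclose(partitioned_tpm(system, partition, "e"), system.effect_tpm())

    def test_copy_pair_cut_both_noises_to_half(self):
        # mutual copies at w=1: severing both directions leaves each unit with
        # a uniformly noised input, i.e. the logistic marginal 0.5
        net = ps.make_copy_pairs(1, k=4.0)
        system = condition(net, [0, 1])
        both = next(
            p for p in enumerate_partitions([0, 1])
            if p.cut_pairs == frozenset({(0, 1), (1, 0)})
        )
        assert np.allclose(partitioned_tpm(system, both, "e"), 0.25)  # 0.5 * 0.5 per row


class TestPhiDirectional:
    def test_inert_partition_gives_zero(self):
        w = np.eye(2)
        net = ps.build_logistic_network(ps.LogisticSpec(w, 4.0), (1, 0))
        system = condition(net, [0, 1])
        res = system_phi(system)
        e_state = ss.index_state(res.ces.effect_state, system.alphabets)
        for partition in enumerate_partitions([0, 1]):
            assert phi_directional(system, "effect", e_state, partition) == 0.0

    def test_never_negative_and_clamped(self):
        for seed in range(8):
            system = condition(random_net(seed), [0, 1, 2])
            res = system_phi(system)
            if res.ces.powerless:
                continue
            e_state = ss.index_state(res.ces.effect_state, system.alphabets)
            c_state = ss.index_state(res.ces.cause_state, system.alphabets)
            for partition in enumerate_partitions(range(3)):
                assert phi_directional(system, "effect", e_state, partition) >= 0.0
                assert phi_directional(system, "cause", c_state, partition) >= 0.0


class TestSystemPhi:
    def test_disconnected_pairs_reducible(self):
        net = ps.make_copy_pairs(2)
        res = system_phi(condition(net, range(4)))
        assert res.phi == 0.0 and res.reducible

    def test_self_loop_unit_is_integrated(self):
        net = ps.build_logistic_network(ps.LogisticSpec(np.eye(1), 4.0), (1,))
        res = system_phi(condition(net, [0]))
        assert res.phi > 0.5  # near-deterministic self-copy
        assert res.mip.cut_pairs == frozenset({(0, 0)})

    def test_phi_bounded_by_normalization(self):
        for seed in range(8):
            system = condition(random_net(seed), [0, 1, 2])
            res = system_phi(system)
            if res.ces.powerless:
                continue
            e_state = ss.index_state(res.ces.effect_state, system.alphabets)
            c_state = ss.index_state(res.ces.cause_state, system.alphabets)
            for partition in enumerate_partitions(range(3)):
                phi = min(
                    phi_directional(system, "effect", e_state, partition),
                    phi_directional(system, "cause", c_state, partition),
                )
                assert phi <= partition.normalization + 1e-9

    def test_not_strongly_connected_means_zero(self):
        import networkx as nx

        for seed in range(10):
            net = ps.make_random_dag(4, seed=seed)
            g = net.interaction_graph()
            assert not nx.is_strongly_connected(g)
            res = system_phi(condition(net, range(4)))
            assert res.phi == 0.0

    def test_dedup_matches_full_labeled_enumeration(self):
        # scoring only deduplicated cut-sets must agree with scoring every
        # labeled partition (the optimization cannot change the minimum)
        for seed in range(5):
            system = condition(random_net(seed, n=4), range(4))
            res = system_phi(system)
            if res.ces.powerless:
                continue
            e_state = ss.index_state(res.ces.effect_state, system.alphabets)
            c_state = ss.index_state(res.ces.cause_state, system.alphabets)
            best = None
            for theta in labeled_partitions(range(4)):
                phi = min(
                    phi_directional(system, "effect", e_state, theta),
                    phi_directional(system, "cause", c_state, theta),
                )
                key = (phi / theta.normalization, -phi)
                if best is None or key < best[0]:
                    best = (key, phi)
            assert res.phi == pytest.approx(best[1], abs=1e-10)
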