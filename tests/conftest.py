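"""Shared fixtures and independent brute-force oracles.

The oracles here recompute conditioning, repertoires, and partitioned tables
directly from the joint TPM with explicit loops over full state spaces; they
share no code path with the package internals they check.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

import phistruct as ps
from phistruct import statespace as ss


@pytest.fixture(scope="session")
def cycle6():
    return ps.make_directed_cycle(6, 4.0)


@pytest.fixture(scope="session")
def cycle6_structure(cycle6):
    # unfolding the full 6-unit complex is reused by several tests
    return ps.unfold(cycle6)


def joint_tpm(net):
    return net.joint_tpm()


def states(alphabets):
    return list(ss.iter_states(alphabets))


def oracle_effect_tpm(net, members):
    """Eq-3 style brute force: slice the joint TPM at the background state and
    marginalize the next-state distribution onto the members."""
    members = sorted(members)
    background = [i for i in range(net.n) if i not in members]
    T = joint_tpm(net)
    s_alpha = [net.alphabets[i] for i in members]
    n_s = ss.n_states(s_alpha)
    out = np.zeros((n_s, n_s))
    for si, s in enumerate(states(s_alpha)):
        cur = [0] * net.n
        for pos, m in enumerate(members):
            cur[m] = s[pos]
        for b in background:
            cur[b] = net.state[b]
        row = T[ss.state_index(cur, net.alphabets)]
        for r, p in enumerate(row):
            full_next = ss.index_state(r, net.alphabets)
            sbar = tuple(full_next[m] for m in members)
            out[si, ss.state_index(sbar, s_alpha)] += p
    return out


def oracle_cause_factors(net, members):
    """Direct evaluation of the cause-TPM unit factors: for each member unit,
    a mixture over prior background states weighted by the posterior of the
    background given the current universe state under a uniform prior."""
    members = sorted(members)
    background = [i for i in range(net.n) if i not in members]
    s_alpha = [net.alphabets[i] for i in members]
    w_alpha = [net.alphabets[i] for i in background]
    u_idx = ss.state_index(net.state, net.alphabets)
    T = joint_tpm(net)
    # posterior over prior background states
    total = T[:, u_idx].sum()
    assert total > 0
    weights = {}
    for wbar in states(w_alpha) if background else [()]:
        acc = 0.0
        for shat in states(s_alpha):
            prior = [0] * net.n
            for pos, m in enumerate(members):
                prior[m] = shat[pos]
            for pos, b in enumerate(background):
                prior[b] = wbar[pos]
            acc += T[ss.state_index(prior, net.alphabets), u_idx]
        weights[wbar] = acc / total
    factors = []
    for pos, m in enumerate(members):
        node = net.node_tpms[m]
        table = np.zeros((ss.n_states(s_alpha), net.alphabets[m]))
        for si, sbar in enumerate(states(s_alpha)):
            for wbar, q in weights.items():
                prior = [0] * net.n
                for p2, mm in enumerate(members):
                    prior[mm] = sbar[p2]
                for p2, b in enumerate(background):
                    prior[b] = wbar[p2]
                table[si] += q * node[ss.state_index(prior, net.alphabets)]
        factors.append(table)
    return factors


def oracle_effect_repertoire(system, mech_positions, purview_positions):
    """Eq-28/29 brute force from the joint effect TPM of the system: per-unit
    conditionals averaged over the non-mechanism units, combined by product."""
    te = system.effect_tpm()
    alpha = system.alphabets
    n = system.n
    other = [i for i in range(n) if i not in mech_positions]
    z_alpha = [alpha[p] for p in purview_positions]
    out = np.ones(ss.n_states(z_alpha))
    for znum, z in enumerate(states(z_alpha)):
        v = 1.0
        for p, zv in zip(purview_positions, z):
            acc = 0.0
            count = 0
            for full in states(alpha):
                if any(full[m] != system.state[m] for m in mech_positions):
                    continue
                count += 1
                row = te[ss.state_index(full, alpha)]
                # marginal of unit p's next state
                acc += sum(
                    pr
                    for c, pr in enumerate(row)
                    if ss.index_state(c, alpha)[p] == zv
                )
            v *= acc / count
        out[znum] = v
    return out


def random_net(seed, n=3, k=4.0):
    return ps.make_random_logistic(n=n, k=k, seed=seed, sparsity=0.3)
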