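"""Generator for the network families used throughout the examples and tests.

All families are built from binary logistic units (weighted connections with
incoming weights summing to one, slope k controlling determinism), except the
feed-forward counter, whose units are exactly deterministic truth tables.
Every generator is deterministic given its parameters (and seed, where one
applies).

Only the directed cycle and the feed-forward family carry literature-reported
φ values; the other families reproduce the qualitative architecture classes
(bottleneck, modular pairs, specialized lattice, excitatory/inhibitory loop)
with parameterized weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .network import LogisticSpec, Network, build_logistic_network

__all__ = [
    "FixtureSpec",
    "make",
    "make_directed_cycle",
    "make_feedforward_counter",
    "make_random_logistic",
    "make_random_dag",
    "make_copy_pairs",
    "make_modular_pairs",
    "make_bottleneck",
    "make_specialized_lattice",
    "make_excitatory_inhibitory",
]


@dataclass(frozen=True)
class FixtureSpec:
    """Reproducible recipe for a test network."""

    family: str
    n: int = 6
    k: float = 4.0
    seed: int = 0
    params: tuple = field(default_factory=tuple)  # sorted (key, value) pairs

    def build(self) -> Network:
        return make(self)


_FAMILIES = {}


def _family(name):
    def deco(fn):
        _FAMILIES[name] = fn
        return fn

    return deco


def make(spec: FixtureSpec) -> Network:
    if spec.family not in _FAMILIES:
        raise ValueError(f"unknown fixture family {spec.family!r}; know {sorted(_FAMILIES)}")
    return _FAMILIES[spec.family](spec)


@_family("directed-cycle")
def _cycle_from_spec(spec: FixtureSpec) -> Network:
    return make_directed_cycle(spec.n, spec.k, **dict(spec.params))


def make_directed_cycle(n: int, k: float = 4.0, state=None) -> Network:
    """Unidirectional cycle: unit i copies unit i−1 (mod n) with weight 1.0.

    Default state has the first unit ON and the rest OFF (e.g. ``Abcdef``)."""
    if n < 2:
        raise ValueError("a directed cycle needs at least 2 units")
    w = np.zeros((n, n))
    for i in range(n):
        w[(i - 1) % n, i] = 1.0
    if state is None:
        state = [1] + [0] * (n - 1)
    return build_logistic_network(LogisticSpec(w, k), state)


@_family("feedforward-counter")
def _ff_from_spec(spec: FixtureSpec) -> Network:
    return make_feedforward_counter(**dict(spec.params))


def make_feedforward_counter(input_on: bool = True) -> Network:
    """Three deterministic binary units A, B, C with feed-forward connections
    A→B and A→C only (plus self-loops), driven by a frozen background input
    unit I. With I = 1 the internal state advances around a cycle; with I = 0
    it holds. Unit update rules: A' = A⊕I, B' = B⊕(A∧I), C' = C⊕(¬A∧I).

    The 3-unit system {A, B, C} is not strongly connected, hence reducible
    (φ_s = 0) no matter the state.
    """
    units = ["I", "A", "B", "C"]
    alphabets = (2, 2, 2, 2)
    nfull = 16
    from . import statespace as ss

    def point(bit):
        return np.array([1.0 - bit, float(bit)])

    tables = [np.zeros((nfull, 2)) for _ in units]
    for r in range(nfull):
        i, a, b, c = ss.index_state(r, alphabets)
        tables[0][r] = point(i)  # input holds its state
        tables[1][r] = point(a ^ i)
        tables[2][r] = point(b ^ (a & i))
        tables[3][r] = point(c ^ ((1 - a) & i))
    state = (1 if input_on else 0, 1, 0, 0)  # analyzed in internal state 100
    return Network(units, alphabets, tables, state)


@_family("random-logistic")
def _rand_from_spec(spec: FixtureSpec) -> Network:
    return make_random_logistic(spec.n, spec.k, spec.seed, **dict(spec.params))


def make_random_logistic(n: int, k: float = 4.0, seed: int = 0, sparsity: float = 0.3) -> Network:
    """Random column-normalized logistic network, reproducible by seed: each
    unit keeps each potential input with probability 1−sparsity (at least
    one), with Dirichlet weights over the kept inputs."""
    if n < 1:
        raise ValueError("need at least one unit")
    rng = np.random.default_rng(seed)
    w = np.zeros((n, n))
    for i in range(n):
        keep = np.nonzero(rng.random(n) >= sparsity)[0]
        if keep.size == 0:
            keep = np.array([rng.integers(n)])
        w[keep, i] = rng.dirichlet(np.ones(keep.size))
    state = tuple(int(x) for x in rng.integers(0, 2, size=n))
    return build_logistic_network(LogisticSpec(w, k), state)


@_family("random-dag")
def _dag_from_spec(spec: FixtureSpec) -> Network:
    return make_random_dag(spec.n, spec.k, spec.seed)


def make_random_dag(n: int, k: float = 4.0, seed: int = 0) -> Network:
    """Random feed-forward (DAG-topology) logistic network: inputs only from
    strictly earlier units in a random order; units without predecessors, and
    a share of the weight elsewhere, fall back on a self-loop so that every
    column still sums to one. Never strongly connected for n ≥ 2."""
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    w = np.zeros((n, n))
    for rank, i in enumerate(order):
        earlier = order[:rank]
        chosen = [j for j in earlier if rng.random() < 0.6]
        inputs = chosen if chosen else [i]  # roots listen to themselves
        weights = rng.dirichlet(np.ones(len(inputs)))
        for j, wt in zip(inputs, weights):
            w[j, i] = wt
    state = tuple(int(x) for x in rng.integers(0, 2, size=n))
    return build_logistic_network(LogisticSpec(w, k), state)


@_family("modular-pairs")
def _pairs_from_spec(spec: FixtureSpec) -> Network:
    return make_modular_pairs(n_modules=max(1, spec.n // 2), k=spec.k, **dict(spec.params))


def make_copy_pairs(n_pairs: int = 2, k: float = 50.0, state=None) -> Network:
    """Disconnected pairs of mutual copies (weight 1 each way); high slope
    makes each pair a near-deterministic swap."""
    n = 2 * n_pairs
    w = np.zeros((n, n))
    for p in range(n_pairs):
        a, b = 2 * p, 2 * p + 1
        w[a, b] = 1.0
        w[b, a] = 1.0
    if state is None:
        state = [1, 0] * n_pairs
    return build_logistic_network(LogisticSpec(w, k), state)


def make_modular_pairs(
    n_modules: int = 3, k: float = 4.0, intra: float = 0.95, state=None
) -> Network:
    """Strongly coupled two-unit modules weakly chained in a ring: each unit
    listens to its partner with weight ``intra`` and to one unit of the
    previous module with weight 1−intra."""
    n = 2 * n_modules
    w = np.zeros((n, n))
    inter = 1.0 - intra
    for m in range(n_modules):
        a, b = 2 * m, 2 * m + 1
        w[a, b] = intra
        w[b, a] = intra
        prev = (2 * ((m - 1) % n_modules)) if n_modules > 1 else a
        if n_modules > 1:
            w[prev, a] = inter
            w[prev + 1, b] = inter
        else:
            w[a, b] += 0.0
            w[a, a] = inter
            w[b, b] = inter
    if state is None:
        state = [1] + [0] * (n - 1)
    return build_logistic_network(LogisticSpec(w, k), state)


@_family("bottleneck")
def _bn_from_spec(spec: FixtureSpec) -> Network:
    return make_bottleneck(spec.n, spec.k)


def make_bottleneck(n: int = 6, k: float = 4.0, state=None) -> Network:
    """Degenerate hub: the first unit pools equal-weight inputs from all the
    others and is their only input."""
    if n < 3:
        raise ValueError("a bottleneck needs at least 3 units")
    w = np.zeros((n, n))
    for i in range(1, n):
        w[0, i] = 1.0  # hub drives everyone
        w[i, 0] = 1.0 / (n - 1)  # everyone drives the hub
    if state is None:
        state = [1] + [0] * (n - 1)
    return build_logistic_network(LogisticSpec(w, k), state)


@_family("specialized-lattice")
def _lat_from_spec(spec: FixtureSpec) -> Network:
    return make_specialized_lattice(spec.n, spec.k, spec.seed)


def make_specialized_lattice(n: int = 6, k: float = 4.0, seed: int = 7, state=None) -> Network:
    """Heterogeneously connected lattice of specialized units: overlapping
    receptive fields (each unit listens to itself and two ring neighbours with
    unequal, seed-fixed weights). Qualitative architecture only."""
    rng = np.random.default_rng(seed)
    w = np.zeros((n, n))
    for i in range(n):
        inputs = [i, (i - 1) % n, (i + 1) % n]
        weights = rng.dirichlet(np.ones(len(inputs)) * 2.0)
        for j, wt in zip(inputs, weights):
            w[j, i] += wt
    if state is None:
        state = [1] + [0] * (n - 1)
    return build_logistic_network(LogisticSpec(w, k), state)


def make_excitatory_inhibitory(k: float = 4.0, state=None) -> Network:
    """Five binary units coupled through excitatory and inhibitory weights
    (signed, columns still summing to one): a qualitative stand-in for mixed
    excitation/inhibition loops. Synthetic; no literature φ values claimed."""
    n = 5
    w = np.zeros((n, n))
    ring = [(0, 1), (1, 2), (2, 3), (3, 4), (4, 0)]
    for j, i in ring:
        w[j, i] = 1.3
    for j, i in [(1, 0), (2, 1), (3, 2), (4, 3), (0, 4)]:
        w[j, i] = -0.3  # inhibitory back-connections
    if state is None:
        state = [1, 1, 0, 0, 1]
    return build_logistic_network(LogisticSpec(w, k), state)
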