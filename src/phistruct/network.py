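"""Finite-state causal networks and their transition probability tables.

A :class:`Network` is a set of units with finite alphabets, a current state,
and a complete interventional transition probability function p(next | do(current)).
Units are assumed conditionally independent given the preceding joint state, so
the joint TPM factors into one table per unit; the factored form is the primary
representation here (the joint |Ω|×|Ω| matrix is built on demand).

Networks of binary logistic units are built from a weight matrix and slope via
:func:`build_logistic_network`: unit i turns ON with probability
``1 / (1 + exp(-k * sum_j w[j, i] * u_j))`` where u_j ∈ {−1, +1} and each
unit's incoming weights sum to one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import statespace as ss

DEFAULT_TOL = 1e-10

__all__ = [
    "Network",
    "LogisticSpec",
    "TPMDiagnostics",
    "build_logistic_network",
    "validate_tpm",
    "DEFAULT_TOL",
]


class UnreachableStateError(ValueError):
    """The current universe state has zero probability under every prior state."""


@dataclass(frozen=True)
class LogisticSpec:
    """Weighted-connection network of binary logistic units.

    ``weights[j, i]`` is the connection weight from unit j onto unit i; the
    incoming weights of every unit must sum to 1. ``k`` (> 0) is the slope of
    the logistic activation and controls determinism. Unit states are the
    binary alphabet {−1, +1}, stored internally as indices {0, 1}.
    """

    weights: np.ndarray
    k: float

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "weights", w)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weights must be a square matrix")
        if self.k <= 0:
            raise ValueError(f"slope k must be positive, got {self.k}")
        colsums = w.sum(axis=0)
        if not np.allclose(colsums, 1.0, atol=1e-9):
            raise ValueError(
                f"incoming weights of every unit must sum to 1; column sums are {colsums}"
            )

    @property
    def n(self) -> int:
        return self.weights.shape[0]


class Network:
    """A universe of interacting units with a full interventional TPM.

    Parameters
    ----------
    units:
        Ordered unit names.
    alphabets:
        Per-unit alphabet sizes (each ≥ 2).
    node_tpms:
        One table per unit of shape (|Ω_U|, |A_i|); row r is the distribution
        of the unit's next state given the joint current state with flat index
        r (little-endian, unit 0 fastest).
    state:
        Current joint state as per-unit state indices.
    """

    def __init__(self, units, alphabets, node_tpms, state):
        self.units = tuple(units)
        self.alphabets = tuple(int(a) for a in alphabets)
        if len(self.units) != len(self.alphabets):
            raise ValueError("units and alphabets length mismatch")
        if any(a < 2 for a in self.alphabets):
            raise ValueError("every unit needs an alphabet of size >= 2")
        nfull = ss.n_states(self.alphabets)
        self.node_tpms = []
        for i, t in enumerate(node_tpms):
            t = np.asarray(t, dtype=float)
            if t.shape != (nfull, self.alphabets[i]):
                raise ValueError(
                    f"node table {i} has shape {t.shape}, expected {(nfull, self.alphabets[i])}"
                )
            self.node_tpms.append(t)
        self.state = tuple(int(s) for s in state)
        if len(self.state) != len(self.units):
            raise ValueError("state length mismatch")
        for s, a in zip(self.state, self.alphabets):
            if not 0 <= s < a:
                raise ValueError(f"state component {s} outside alphabet of size {a}")

    # -- constructors ------------------------------------------------------

    @classmethod
    def from_joint_tpm(cls, units, alphabets, tpm, state) -> "Network":
        """Build from a state-by-state joint TPM, factoring it into per-unit
        tables by marginalization (valid under conditional independence; use
        :func:`validate_tpm` to check the factorization reproduces the joint)."""
        alphabets = tuple(int(a) for a in alphabets)
        tpm = np.asarray(tpm, dtype=float)
        nfull = ss.n_states(alphabets)
        if tpm.shape != (nfull, nfull):
            raise ValueError(f"joint TPM has shape {tpm.shape}, expected {(nfull, nfull)}")
        node_tpms = []
        grid = ss.as_grid(tpm.T, alphabets)  # axis i = next-state of unit i, last = current
        for i, a in enumerate(alphabets):
            axes = tuple(j for j in range(len(alphabets)) if j != i)
            marg = grid.sum(axis=axes)  # (a_i, nfull)
            node_tpms.append(np.ascontiguousarray(marg.T))
        return cls(units, alphabets, node_tpms, state)

    # -- basic properties --------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.units)

    @property
    def n_full_states(self) -> int:
        return ss.n_states(self.alphabets)

    def with_state(self, state) -> "Network":
        if isinstance(state, str):
            state = ss.parse_state_label(state, self.units)
        return Network(self.units, self.alphabets, self.node_tpms, state)

    def state_label(self) -> str:
        return ss.state_label(self.state, self.units)

    def joint_tpm(self) -> np.ndarray:
        """The |Ω_U|×|Ω_U| joint TPM, rebuilt as the product of unit factors."""
        nfull = self.n_full_states
        comps = np.array([ss.index_state(r, self.alphabets) for r in range(nfull)])
        out = np.ones((nfull, nfull))
        for i, t in enumerate(self.node_tpms):
            out *= t[:, comps[:, i]]  # (current, next)
        return out

    def depends_on(self, unit: int) -> frozenset[int]:
        """Indices of units whose current state actually influences ``unit``'s
        next-state distribution (numerical dependency, tolerance-based)."""
        t = self.node_tpms[unit]
        grid = ss.as_grid(t, self.alphabets)  # axes 0..n-1 current units, last = next state
        deps = set()
        for j in range(self.n):
            spread = grid.max(axis=j) - grid.min(axis=j)
            if spread.max() > DEFAULT_TOL:
                deps.add(j)
        return frozenset(deps)

    def interaction_graph(self):
        """Directed dependency graph: edge j→i iff unit i listens to unit j."""
        import networkx as nx

        g = nx.DiGraph()
        g.add_nodes_from(range(self.n))
        for i in range(self.n):
            for j in self.depends_on(i):
                g.add_edge(j, i)
        return g

    def __repr__(self):
        return f"Network(units={list(self.units)}, state={self.state_label()!r})"


def build_logistic_network(spec: LogisticSpec, state) -> Network:
    """Construct the factored TPM of a binary logistic-unit network.

    ``state`` may be a vector over {−1, +1}, a vector of indices {0, 1}, or a
    case-coded label. Unit names default to letters A, B, C, ...
    """
    n = spec.n
    units = [chr(ord("A") + i) if n <= 26 else f"U{i}" for i in range(n)]
    if isinstance(state, str):
        idx_state = ss.parse_state_label(state, units)
    else:
        state = list(state)
        if set(state) <= {-1, 1}:
            idx_state = tuple(0 if s == -1 else 1 for s in state)
        elif set(state) <= {0, 1}:
            idx_state = tuple(int(s) for s in state)
        else:
            raise ValueError(f"binary state must be over {{-1,+1}} or {{0,1}}, got {state}")
    alphabets = (2,) * n
    nfull = 2**n
    # spins[r, j] = ±1 value of unit j in flat state r
    spins = np.empty((nfull, n))
    for r in range(nfull):
        st = ss.index_state(r, alphabets)
        spins[r] = [2 * x - 1 for x in st]
    drive = spins @ spec.weights  # (nfull, n): summed weighted input to each target
    with np.errstate(over="ignore"):  # saturated tails underflow cleanly to 0/1
        p_on = 1.0 / (1.0 + np.exp(-spec.k * drive))
    node_tpms = [np.column_stack([1.0 - p_on[:, i], p_on[:, i]]) for i in range(n)]
    return Network(units, alphabets, node_tpms, idx_state)


@dataclass
class TPMDiagnostics:
    """Pure report on the contracts a TPM must satisfy; callers may escalate."""

    row_sum_max_deviation: float
    bad_rows: list = field(default_factory=list)
    negative_entries: int = 0
    independence_max_error: float = 0.0
    independent: bool = True
    chance_level: bool = False

    @property
    def ok(self) -> bool:
        return not self.bad_rows and self.negative_entries == 0 and self.independent

    def summary(self) -> str:
        lines = [
            f"row-sum max deviation: {self.row_sum_max_deviation:.3e}"
            + (f" (rows violating: {self.bad_rows})" if self.bad_rows else ""),
            f"negative entries: {self.negative_entries}",
            f"conditional-independence max error: {self.independence_max_error:.3e}"
            + ("" if self.independent else " (FACTORIZATION FAILS)"),
        ]
        if self.chance_level:
            lines.append("uniform TPM: no cause-effect power")
        return "\n".join(lines)


def validate_tpm(net: Network, joint: np.ndarray | None = None, tol: float = 1e-6) -> TPMDiagnostics:
    """Check row-stochasticity, non-negativity, and (when a reference joint
    TPM is supplied) that the joint equals the product of its unit factors."""
    diag = TPMDiagnostics(row_sum_max_deviation=0.0)
    neg = 0
    worst = 0.0
    bad_rows: set[int] = set()
    for t in net.node_tpms:
        neg += int((t < -DEFAULT_TOL).sum())
        dev = np.abs(t.sum(axis=1) - 1.0)
        worst = max(worst, float(dev.max()))
        bad_rows |= set(np.nonzero(dev > tol)[0].tolist())
    rebuilt = net.joint_tpm()
    if joint is not None:
        joint = np.asarray(joint, dtype=float)
        neg += int((joint < -DEFAULT_TOL).sum())
        dev = np.abs(joint.sum(axis=1) - 1.0)
        worst = max(worst, float(dev.max()))
        bad_rows |= set(np.nonzero(dev > tol)[0].tolist())
        diag.independence_max_error = float(np.abs(rebuilt - joint).max())
        diag.independent = diag.independence_max_error <= tol
    diag.row_sum_max_deviation = worst
    diag.bad_rows = sorted(bad_rows)
    diag.negative_entries = neg
    diag.chance_level = bool(np.abs(rebuilt - rebuilt.mean(axis=0)).max() <= DEFAULT_TOL)
    return diag
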