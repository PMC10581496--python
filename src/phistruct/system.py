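"""Candidate systems conditioned on their background.

A candidate system S is a subset of a network's units; the remaining units W
are background conditions and are causally marginalized conditional on the
current universe state. Two directional TPMs result:

* the effect TPM ``p_e(s̄|s) = p(s̄ | s, w)`` with the background clamped to
  its current state, and
* the cause TPM ``p_c(s|s̄)``, in which each unit factor is a mixture over
  prior background states weighted by their posterior probability given the
  current universe state under a uniform prior over prior universe states.

Both are stored factored (one table per member unit) and remain row-stochastic
products of unit factors. All repertoire and partition computations downstream
pull single-unit factor values from the caches kept on the system object.
"""

from __future__ import annotations

import numpy as np

from . import statespace as ss
from .network import DEFAULT_TOL, Network, UnreachableStateError

__all__ = ["ConditionedSystem", "condition", "condition_effect_tpm", "condition_cause_tpm"]


def _mask_axes(mask: int, n: int) -> tuple[int, ...]:
    return tuple(i for i in range(n) if mask >> i & 1)


class ConditionedSystem:
    """A candidate system with background-conditioned effect and cause TPMs.

    ``members`` are global unit indices (kept sorted); positions 0..|S|-1 index
    the members in that order. ``te_factors[i]`` has shape (|Ω_S|, |A_i|) with
    rows enumerating current system states s; ``tc_factors[i]`` has the same
    shape with rows enumerating prior system states s̄.
    """

    def __init__(self, net: Network, members):
        members = tuple(sorted(members))
        if not members:
            raise ValueError("a candidate system needs at least one member unit")
        if any(m < 0 or m >= net.n for m in members):
            raise ValueError(f"member indices {members} outside universe of {net.n} units")
        self.net = net
        self.members = members
        self.alphabets = tuple(net.alphabets[m] for m in members)
        self.state = tuple(net.state[m] for m in members)
        self.background = tuple(i for i in range(net.n) if i not in members)
        self.background_state = tuple(net.state[i] for i in self.background)
        self.te_factors: list[np.ndarray] | None = None
        self.tc_factors: list[np.ndarray] | None = None
        self._caches: dict = {}

    # -- sizes and labels --------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.members)

    @property
    def n_states(self) -> int:
        return ss.n_states(self.alphabets)

    def labels(self) -> tuple[str, ...]:
        return tuple(self.net.units[m] for m in self.members)

    def state_label(self, state=None) -> str:
        return ss.state_label(self.state if state is None else state, self.labels())

    def substate(self, mask: int, state=None) -> frozenset[tuple[int, int]]:
        """A sub-state as a set of (position, state) tuples, following the
        convention that states are sets of unit/state pairs."""
        state = self.state if state is None else state
        return frozenset((i, state[i]) for i in _mask_axes(mask, self.n))

    # -- conditioning ------------------------------------------------------

    def _node_grid(self, pos: int, factors: str) -> np.ndarray:
        """Factor table for member ``pos`` as a grid with one axis per member
        unit plus a trailing next/current-state axis."""
        key = ("grid", factors, pos)
        if key not in self._caches:
            table = (self.te_factors if factors == "e" else self.tc_factors)[pos]
            self._caches[key] = ss.as_grid(table, self.alphabets)
        return self._caches[key]

    def build_effect(self) -> "ConditionedSystem":
        """Fill the effect TPM factors (background clamped at its state)."""
        net = self.net
        self.te_factors = []
        for pos, m in enumerate(self.members):
            grid = ss.as_grid(net.node_tpms[m], net.alphabets)
            indexer = [slice(None)] * net.n + [slice(None)]
            for b, bs in zip(self.background, self.background_state):
                indexer[b] = bs
            sub = grid[tuple(indexer)]  # member axes (in order) + next-state axis
            self.te_factors.append(ss.from_grid(sub, self.n))
        return self

    def build_cause(self) -> "ConditionedSystem":
        """Fill the cause TPM factors (mixture over prior background states)."""
        net = self.net
        # posterior over prior universe states of the current state u
        p_u = np.ones(net.n_full_states)
        for i, t in enumerate(net.node_tpms):
            p_u *= t[:, net.state[i]]
        total = p_u.sum()
        if total <= DEFAULT_TOL:
            raise UnreachableStateError(
                f"current state {net.state_label()!r} is unreachable: "
                "no prior state produces it"
            )
        grid_u = ss.as_grid(p_u, net.alphabets)
        member_axes = tuple(range(net.n))
        member_axes = tuple(a for a in member_axes if a in self.members)
        q = grid_u.sum(axis=member_axes) if member_axes else grid_u
        q = np.asarray(q, dtype=float) / total  # over background axes, in order
        self.tc_factors = []
        for pos, m in enumerate(self.members):
            grid = ss.as_grid(net.node_tpms[m], net.alphabets)
            bg_axes = tuple(i for i, b in enumerate(range(net.n)) if b in self.background)
            if self.background:
                mixed = np.tensordot(grid, q, axes=(bg_axes, tuple(range(q.ndim))))
            else:
                mixed = grid
            self.tc_factors.append(ss.from_grid(mixed, self.n))
        return self

    # -- joint matrices ----------------------------------------------------

    def _joint(self, factors: list[np.ndarray]) -> np.ndarray:
        nfull = self.n_states
        comps = np.array([ss.index_state(r, self.alphabets) for r in range(nfull)])
        out = np.ones((nfull, nfull))
        for i, t in enumerate(factors):
            out *= t[:, comps[:, i]]
        return out

    def effect_tpm(self) -> np.ndarray:
        """Joint Te over Ω_S (rows: current state s, columns: next state s̄)."""
        if "Te" not in self._caches:
            self._caches["Te"] = self._joint(self.te_factors)
        return self._caches["Te"]

    def cause_tpm(self) -> np.ndarray:
        """Joint Tc over Ω_S (rows: prior state s̄, columns: current state s)."""
        if "Tc" not in self._caches:
            self._caches["Tc"] = self._joint(self.tc_factors)
        return self._caches["Tc"]

    # -- single-unit factor values used by partitions and repertoires ------

    def partitioned_factor(self, side: str, pos: int, cut_mask: int, row_state, col: int) -> float:
        """p(unit ``pos`` takes value ``col`` | row_state) with the row-state
        components in ``cut_mask`` causally marginalized (uniform) and the rest
        held fixed — the partitioned single-unit probability."""
        key = ("pf", side, pos, cut_mask, tuple(row_state), col)
        if key not in self._caches:
            grid = self._node_grid(pos, side)[..., col]
            indexer = [row_state[i] for i in range(self.n)]
            cut_axes = []
            for i in _mask_axes(cut_mask, self.n):
                indexer[i] = slice(None)
                cut_axes.append(i)
            sub = grid[tuple(indexer)]
            self._caches[key] = float(sub.mean()) if cut_axes else float(sub)
        return self._caches[key]

    def effect_factor(self, pos: int, mech_mask: int) -> np.ndarray:
        """p_e(z_pos | m): the effect-side factor of unit ``pos`` constrained
        by the sub-mechanism ``mech_mask`` in its current state, with all other
        member units causally marginalized. Vector over the unit's alphabet."""
        key = ("ef", pos, mech_mask)
        if key not in self._caches:
            grid = self._node_grid(pos, "e")
            indexer: list = [slice(None)] * self.n + [slice(None)]
            free = []
            for i in range(self.n):
                if mech_mask >> i & 1:
                    indexer[i] = self.state[i]
                else:
                    free.append(i)
            sub = grid[tuple(indexer)]
            if free:
                sub = sub.mean(axis=tuple(range(len(free))))
            self._caches[key] = sub
        return self._caches[key]

    def effect_factor_table(self, pos: int, mech_mask: int) -> np.ndarray:
        """p_e(z_pos | m̂) for every sub-state m̂ of the mechanism units in
        ``mech_mask`` (non-mechanism members causally marginalized). Shape
        (|Ω_M|, |A_pos|), rows little-endian over the mechanism sub-space."""
        key = ("eft", pos, mech_mask)
        if key not in self._caches:
            grid = self._node_grid(pos, "e")
            marg_axes = tuple(i for i in range(self.n) if not mech_mask >> i & 1)
            sub = grid.mean(axis=marg_axes) if marg_axes else grid
            sub = np.asarray(sub)
            self._caches[key] = sub.reshape(-1, sub.shape[-1], order="F")
        return self._caches[key]

    def factor_dependencies(self, side: str, pos: int) -> frozenset[int]:
        """Member positions whose row-state component actually influences the
        factor of unit ``pos`` on the given side ('e' or 'c')."""
        key = ("dep", side, pos)
        if key not in self._caches:
            grid = self._node_grid(pos, side)
            deps = set()
            for j in range(self.n):
                spread = grid.max(axis=j) - grid.min(axis=j)
                if spread.max() > DEFAULT_TOL:
                    deps.add(j)
            self._caches[key] = frozenset(deps)
        return self._caches[key]

    def cause_factor_table(self, pos: int, purview_mask: int) -> np.ndarray:
        """p_c(m_pos | z) for every purview state z ∈ Ω_Z: the probability
        that mechanism unit ``pos`` is in its current state given the prior
        sub-state z on ``purview_mask``, with the remaining prior units
        causally marginalized. Flat little-endian array over Ω_Z."""
        key = ("cf", pos, purview_mask)
        if key not in self._caches:
            grid = self._node_grid(pos, "c")[..., self.state[pos]]
            marg_axes = tuple(i for i in range(self.n) if not purview_mask >> i & 1)
            sub = grid.mean(axis=marg_axes) if marg_axes else grid
            self._caches[key] = np.asarray(sub).reshape(-1, order="F")
        return self._caches[key]

    def mask_alphabets(self, mask: int) -> tuple[int, ...]:
        return tuple(self.alphabets[i] for i in _mask_axes(mask, self.n))

    def __repr__(self):
        return (
            f"ConditionedSystem(members={list(self.labels())}, "
            f"state={self.state_label()!r})"
        )


def condition_effect_tpm(net: Network, members) -> ConditionedSystem:
    """Effect-condition a candidate system: background clamped to its current
    state (returns a system with Te filled)."""
    return ConditionedSystem(net, members).build_effect()


def condition_cause_tpm(net: Network, members) -> ConditionedSystem:
    """Cause-condition a candidate system: background mixed over its possible
    prior states, weighted by their posterior probability given the current
    universe state (returns a system with Tc filled)."""
    return ConditionedSystem(net, members).build_cause()


def condition(net: Network, members) -> ConditionedSystem:
    """Build a candidate system with both Te and Tc filled."""
    return ConditionedSystem(net, members).build_effect().build_cause()
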