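"""Mechanism-level repertoires, disintegrating partitions, φ_d, and distinctions.

A mechanism M ⊆ S in its current sub-state m constrains cause and effect
purviews Z ⊆ S through *product* repertoires: every single-unit conditional
is computed with the non-mechanism (resp. non-purview) units causally
marginalized, and units are recombined by product so that no correlation can
be smuggled in by units outside the mechanism.

Irreducibility is assessed over "disintegrating" partitions: joint partitions
of (M, Z) into k ≥ 2 parts (empty sub-parts allowed, but no part may pair the
whole mechanism with a non-empty purview part). The partitioned repertoire is
the product of the part repertoires; parts with an empty mechanism use the
fully marginalized factors. φ is the selectivity times the positive part of
the intact/partitioned log-ratio, minimized over partitions normalized by the
number of mechanism→purview unit pairs they sever.

A mechanism's maximal cause and effect purviews are the φ-maxima over all
non-empty Z ⊆ S; the distinction exists if φ_d = min(φ_c, φ_e) > 0 and both
purview states are congruent with the system's maximal cause-effect state.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from . import statespace as ss
from .intrinsic import CauseEffectState
from .network import DEFAULT_TOL
from .partitions import set_partitions
from .system import ConditionedSystem

__all__ = [
    "Repertoire",
    "MechanismPartition",
    "Distinction",
    "DistinctionSet",
    "effect_repertoire",
    "cause_repertoire",
    "mechanism_ii",
    "enumerate_disintegrations",
    "distinction_phi",
    "maximal_purview",
    "compute_distinctions",
]


def _positions(mask: int, n: int) -> list[int]:
    return [i for i in range(n) if mask >> i & 1]


def _popcount(mask: int) -> int:
    return bin(mask).count("1")


def _sub_index(state: dict, positions: list[int], alphabets) -> int:
    """Little-endian flat index of a sub-state restricted to ``positions``."""
    idx = 0
    mult = 1
    for p in positions:
        idx += state[p] * mult
        mult *= alphabets[p]
    return idx


# ---------------------------------------------------------------------------
# repertoires


@dataclass
class Repertoire:
    """A mechanism's product probability over a purview.

    ``table`` is flat little-endian over Ω_Z: the effect repertoire π_e(z|m),
    or on the cause side π_c(m|z) as a function of the candidate cause z.
    ``backward`` (cause side) is π_c←(z|m) via Bayes under a uniform prior on
    z; ``unconstrained`` is π_e(z;M) (vector) or π_c(m;Z) (scalar)."""

    side: str
    mech_mask: int
    purview_mask: int
    table: np.ndarray
    unconstrained: np.ndarray | float
    backward: np.ndarray | None = None
    undefined: bool = False


def effect_repertoire(system: ConditionedSystem, mech_mask: int, purview_mask: int) -> Repertoire:
    if purview_mask == 0:
        raise ValueError("effect repertoire needs a non-empty purview")
    zpos = _positions(purview_mask, system.n)
    mpos = _positions(mech_mask, system.n)
    n_m = ss.n_states([system.alphabets[p] for p in mpos]) if mpos else 1
    # full (Ω_M, Ω_Z) product table, then the current-m row and the row average
    full = np.ones((n_m, 1))
    for v in zpos:
        fac = system.effect_factor_table(v, mech_mask)  # (Ω_M, a_v)
        # append v as the slower axis so that flat order stays little-endian
        full = (full[:, None, :] * fac[:, :, None]).reshape(n_m, -1)
    mrow = _sub_index(dict(enumerate(system.state)), mpos, system.alphabets)
    return Repertoire(
        side="effect",
        mech_mask=mech_mask,
        purview_mask=purview_mask,
        table=full[mrow].copy(),
        unconstrained=full.mean(axis=0),
    )


def cause_repertoire(system: ConditionedSystem, mech_mask: int, purview_mask: int) -> Repertoire:
    if purview_mask == 0:
        raise ValueError("cause repertoire needs a non-empty purview")
    if mech_mask == 0:
        raise ValueError("cause repertoire needs a non-empty mechanism")
    mpos = _positions(mech_mask, system.n)
    table = np.ones(ss.n_states(system.mask_alphabets(purview_mask)))
    for u in mpos:
        table = table * system.cause_factor_table(u, purview_mask)
    total = table.sum()
    undefined = total <= DEFAULT_TOL
    return Repertoire(
        side="cause",
        mech_mask=mech_mask,
        purview_mask=purview_mask,
        table=table,
        unconstrained=float(table.mean()),
        backward=None if undefined else table / total,
        undefined=undefined,
    )


def mechanism_ii(system, mech_mask: int, purview_mask: int, side: str, tol: float = DEFAULT_TOL):
    """Intrinsic information of mechanism m over purview Z on one side.

    Returns ``(rep, ii_values, tied_argmax)``: the repertoire, the ii of every
    purview state, and the argmax states tied within tolerance (empty when the
    maximum is ≤ 0, meaning the mechanism specifies no state on this side)."""
    if side == "effect":
        rep = effect_repertoire(system, mech_mask, purview_mask)
        p, q, sel = rep.table, rep.unconstrained, rep.table
    else:
        rep = cause_repertoire(system, mech_mask, purview_mask)
        if rep.undefined:
            return rep, np.zeros_like(rep.table), []
        p = rep.table
        q = np.full_like(p, rep.unconstrained)
        sel = rep.backward
    ii = np.zeros_like(np.asarray(p, dtype=float))
    mask = (p > 0) & (q > 0)
    ii[mask] = np.asarray(sel)[mask] * np.log2(p[mask] / q[mask])
    best = float(ii.max()) if ii.size else 0.0
    if best <= tol:
        return rep, ii, []
    tied = [int(i) for i in np.nonzero(ii >= best - tol)[0]]
    return rep, ii, tied


# ---------------------------------------------------------------------------
# disintegrating partitions


@dataclass(frozen=True)
class MechanismPartition:
    """A disintegrating partition of a mechanism-purview pair: parts are
    (mechanism-mask, purview-mask) pairs."""

    parts: tuple[tuple[int, int], ...]
    mech_mask: int
    purview_mask: int

    @property
    def normalization(self) -> int:
        cut = _popcount(self.mech_mask) * _popcount(self.purview_mask)
        for mm, zm in self.parts:
            cut -= _popcount(mm) * _popcount(zm)
        return cut

    def sort_key(self):
        return tuple(sorted(self.parts))


def enumerate_disintegrations(mech_mask: int, purview_mask: int) -> list[MechanismPartition]:
    """All disintegrating partitions of (M, Z): joint set-partitions of the
    mechanism and purview units into ≥ 2 parts, excluding any part that pairs
    the full mechanism with a non-empty purview part. For |M| = 1 every
    partition therefore severs all mechanism-purview connections."""
    n = max(mech_mask.bit_length(), purview_mask.bit_length())
    elements = [("m", i) for i in _positions(mech_mask, n)] + [
        ("z", j) for j in _positions(purview_mask, n)
    ]
    out = []
    for blocks in set_partitions(elements, min_k=2):
        parts = []
        ok = True
        for b in blocks:
            mm = zm = 0
            for kind, i in b:
                if kind == "m":
                    mm |= 1 << i
                else:
                    zm |= 1 << i
            if mm == mech_mask and zm != 0:
                ok = False
                break
            parts.append((mm, zm))
        if ok:
            out.append(MechanismPartition(tuple(sorted(parts)), mech_mask, purview_mask))
    return out


def _zero_disintegration(system, side, mech_mask, purview_mask) -> MechanismPartition | None:
    """A disintegrating partition severing no actual mechanism→purview
    dependency, if one exists: its partitioned repertoire equals the intact
    one, so φ = 0 exactly and it is a minimum. Dependencies are read off the
    factored TPM. One-directional: returning None decides nothing."""
    n = system.n
    mpos = _positions(mech_mask, n)
    zpos = _positions(purview_mask, n)
    parent = {("m", i): ("m", i) for i in mpos}
    parent.update({("z", j): ("z", j) for j in zpos})

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb

    for v in zpos if side == "effect" else mpos:
        deps = system.factor_dependencies("e" if side == "effect" else "c", v)
        if side == "effect":
            for u in deps & set(mpos):
                union(("m", u), ("z", v))
        else:
            for z in deps & set(zpos):
                union(("m", v), ("z", z))
    comps: dict = {}
    for x in parent:
        comps.setdefault(find(x), []).append(x)
    mech_comps = [c for c in comps.values() if any(k == "m" for k, _ in c)]
    blocks = None
    if len(mech_comps) >= 2:
        blocks = list(comps.values())
    elif len(mech_comps) == 1 and not any(k == "z" for k, _ in mech_comps[0]):
        if len(comps) >= 2:
            blocks = list(comps.values())
    if blocks is None:
        return None
    parts = []
    for b in blocks:
        mm = zm = 0
        for kind, i in b:
            if kind == "m":
                mm |= 1 << i
            else:
                zm |= 1 << i
        parts.append((mm, zm))
    return MechanismPartition(tuple(sorted(parts)), mech_mask, purview_mask)


def _partitioned_value(system, side, theta: MechanismPartition, z_state: dict) -> float:
    """π_θ(z′|m) (effect) or π_θ(m|z′) (cause): product over the parts."""
    v = 1.0
    if side == "effect":
        for mm, zm in theta.parts:
            for zp in _positions(zm, system.n):
                v *= float(system.effect_factor(zp, mm)[z_state[zp]])
    else:
        for mm, zm in theta.parts:
            zpos = _positions(zm, system.n)
            zidx = _sub_index(z_state, zpos, system.alphabets)
            for up in _positions(mm, system.n):
                v *= float(system.cause_factor_table(up, zm)[zidx])
    return v


def _phi_over_partitions(
    system, side, mech_mask, purview_mask, z_state, numerator, selectivity,
    tol=DEFAULT_TOL, shortcut=True,
):
    """(φ, MIP) over all disintegrating partitions, normalized minimization."""
    if numerator <= tol or selectivity <= tol:
        return 0.0, None
    if shortcut:
        zero = _zero_disintegration(system, side, mech_mask, purview_mask)
        if zero is not None:
            return 0.0, zero
    log2num = np.log2(numerator)
    best = None
    for theta in enumerate_disintegrations(mech_mask, purview_mask):
        q = _partitioned_value(system, side, theta, z_state)
        r = log2num - np.log2(q) if q > 0 else np.inf
        phi = selectivity * r if r > tol else 0.0
        key = (phi / theta.normalization, -phi, theta.sort_key())
        if best is None or key < best[0]:
            best = (key, phi, theta)
    return best[1], best[2]


def distinction_phi(system, mech_mask, purview_mask, side, tol=DEFAULT_TOL, shortcut=True):
    """Integrated information of a mechanism over one purview on one side.

    Returns ``(phi, z_state_dict, mip)``; the purview state is the maximal-ii
    state, with ties resolved by the larger φ, then the smaller state index.
    """
    rep, ii, tied = mechanism_ii(system, mech_mask, purview_mask, side, tol=tol)
    if not tied:
        return 0.0, None, None
    zpos = _positions(purview_mask, system.n)
    zalpha = [system.alphabets[p] for p in zpos]
    best = None
    for zidx in tied:
        sub = ss.index_state(zidx, zalpha)
        z_state = dict(zip(zpos, sub))
        if side == "effect":
            numerator = selectivity = float(rep.table[zidx])
        else:
            numerator = float(rep.table[zidx])
            selectivity = float(rep.backward[zidx])
        phi, mip = _phi_over_partitions(
            system, side, mech_mask, purview_mask, z_state, numerator, selectivity,
            tol=tol, shortcut=shortcut,
        )
        key = (-phi, zidx)
        if best is None or key < best[0]:
            best = (key, phi, z_state, mip)
    return best[1], best[2], best[3]


def maximal_purview(system, mech_mask, side, tol=DEFAULT_TOL, shortcut=True):
    """Scan all non-empty purviews Z ⊆ S for the one with maximal φ.

    Ties go to the larger purview, then the lexicographically smallest unit
    set. Returns ``(purview_mask, z_state_dict, phi, mip)``; a mechanism with
    φ = 0 everywhere returns (0, None, 0.0, None) — a null purview."""
    best = (0, None, 0.0, None)
    for purview_mask in range(1, 1 << system.n):
        phi, z_state, mip = distinction_phi(system, mech_mask, purview_mask, side,
                                            tol=tol, shortcut=shortcut)
        if phi <= tol:
            continue
        bmask, _, bphi, _ = best
        if (
            phi > bphi + tol
            or (abs(phi - bphi) <= tol
                and (_popcount(purview_mask), _sorted_key(purview_mask))
                > (_popcount(bmask), _sorted_key(bmask)))
        ):
            best = (purview_mask, z_state, phi, mip)
    return best


def _sorted_key(mask: int):
    # larger purview first; among equal sizes prefer the smaller unit tuple,
    # encoded so that "greater" means "preferred"
    return tuple(-i for i in _positions(mask, mask.bit_length()))


# ---------------------------------------------------------------------------
# distinctions


@dataclass
class Distinction:
    """A mechanism with its maximally irreducible, congruent cause and effect."""

    mech_mask: int
    mechanism: frozenset  # (position, state) tuples
    cause_mask: int
    cause: frozenset
    effect_mask: int
    effect: frozenset
    phi_c: float
    phi_e: float
    phi_d: float
    congruent: bool = True

    @property
    def order(self) -> int:
        return _popcount(self.mech_mask)

    def purview_union_size(self) -> int:
        """|z*_c ∪ z*_e| over (unit, state) tuples — congruent cause/effect
        units count once."""
        return len(self.cause | self.effect)


@dataclass
class DistinctionSet:
    distinctions: list[Distinction] = field(default_factory=list)
    n_candidates: int = 0
    n_positive_phi: int = 0

    def __iter__(self):
        return iter(self.distinctions)

    def __len__(self):
        return len(self.distinctions)

    @property
    def sum_phi_d(self) -> float:
        return sum(d.phi_d for d in self.distinctions)


def compute_distinctions(
    system: ConditionedSystem,
    ces: CauseEffectState,
    tol: float = DEFAULT_TOL,
    shortcut: bool = True,
) -> DistinctionSet:
    """Evaluate all 2^|S|−1 candidate mechanisms and keep those with φ_d > 0
    whose maximal purview states are congruent with the system's maximal
    cause-effect state (as (unit, state) tuple subsets)."""
    if ces.powerless:
        raise ValueError("system has no maximal cause-effect state; nothing to unfold")
    s_c = ss.index_state(ces.cause_state, system.alphabets)
    s_e = ss.index_state(ces.effect_state, system.alphabets)
    out = DistinctionSet()
    for mech_mask in range(1, 1 << system.n):
        out.n_candidates += 1
        c_mask, c_state, phi_c, _ = maximal_purview(system, mech_mask, "cause",
                                                    tol=tol, shortcut=shortcut)
        if phi_c <= tol:
            continue
        e_mask, e_state, phi_e, _ = maximal_purview(system, mech_mask, "effect",
                                                    tol=tol, shortcut=shortcut)
        if phi_e <= tol:
            continue
        out.n_positive_phi += 1
        congruent = all(v == s_c[p] for p, v in c_state.items()) and all(
            v == s_e[p] for p, v in e_state.items()
        )
        if not congruent:
            continue
        out.distinctions.append(
            Distinction(
                mech_mask=mech_mask,
                mechanism=system.substate(mech_mask),
                cause_mask=c_mask,
                cause=frozenset(c_state.items()),
                effect_mask=e_mask,
                effect=frozenset(e_state.items()),
                phi_c=phi_c,
                phi_e=phi_e,
                phi_d=min(phi_c, phi_e),
            )
        )
    return out
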