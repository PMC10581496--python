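"""Φ-structures: the unfolded cause-effect structure of a complex.

The Φ-structure of a complex is the set of its congruent causal distinctions
together with all the relations among them; its structure integrated
information is the plain sum

    Φ = Σ_D φ_d + Σ_R φ_r.

Φ-folds are sub-structures: the fold of a distinction is the distinction plus
every relation bound to it; the compound fold of a unit subset is the union
of the folds of all mechanisms containing any of those units.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from . import statespace as ss
from .condense import Complex, find_first_complex
from .integration import SystemPhiResult, system_phi
from .mechanisms import DistinctionSet, Distinction, compute_distinctions
from .network import DEFAULT_TOL, Network
from .relations import Relation, compute_relations
from .system import ConditionedSystem, condition

__all__ = ["PhiStructure", "unfold", "big_phi", "distinction_fold", "compound_fold"]


@dataclass
class PhiStructure:
    """A complex with its distinctions, relations, and Φ ledger."""

    complex: Complex
    system_result: SystemPhiResult
    distinctions: DistinctionSet
    relations: list[Relation]
    labels: tuple[str, ...] = ()
    system: ConditionedSystem | None = None

    @property
    def sum_phi_d(self) -> float:
        return self.distinctions.sum_phi_d

    @property
    def sum_phi_r(self) -> float:
        return sum(r.phi for r in self.relations)

    @property
    def big_phi(self) -> float:
        return self.sum_phi_d + self.sum_phi_r

    @property
    def n_candidate_mechanisms(self) -> int:
        return self.distinctions.n_candidates


@dataclass
class PhiFold:
    """A sub-structure anchored on one or more distinctions."""

    distinctions: list[Distinction]
    relations: list[Relation]

    @property
    def sum_phi(self) -> float:
        return sum(d.phi_d for d in self.distinctions) + sum(r.phi for r in self.relations)


def unfold(
    net: Network,
    members=None,
    tol: float = DEFAULT_TOL,
    max_distinctions: int = 20,
    shortcut: bool = True,
) -> PhiStructure:
    """Unfold the cause-effect structure of a complex.

    With ``members=None`` the first complex of the universe is identified by
    exhaustive scan; otherwise the given unit subset is treated as the complex
    (the rest of the universe as background conditions).
    """
    if members is None:
        cx = find_first_complex(net, tol=tol)
        if cx.null:
            raise ValueError("no integrated subset: nothing to unfold")
        members = cx.members
        system = condition(net, members)
        result = cx.result
    else:
        members = tuple(sorted(members))
        system = condition(net, members)
        result = system_phi(system, tol=tol)
        cx = Complex(
            members,
            tuple(net.units[i] for i in members),
            tuple(net.state[i] for i in members),
            result.phi,
            rank=1,
            result=result,
        )
    if result.ces.powerless:
        return PhiStructure(cx, result, DistinctionSet(n_candidates=2**system.n - 1), [],
                            labels=system.labels(), system=system)
    dset = compute_distinctions(system, result.ces, tol=tol, shortcut=shortcut)
    rels = compute_relations(dset, tol=tol, max_distinctions=max_distinctions)
    return PhiStructure(cx, result, dset, rels, labels=system.labels(), system=system)


def big_phi(structure: PhiStructure) -> float:
    """Structure integrated information: the exact sum over the ledger."""
    return structure.big_phi


def distinction_fold(structure: PhiStructure, d: Distinction) -> PhiFold:
    """The sub-structure composed of ``d`` and every relation bound to it."""
    try:
        pos = structure.distinctions.distinctions.index(d)
    except ValueError:
        raise KeyError("distinction is not part of this structure") from None
    rels = [r for r in structure.relations if pos in r.indices]
    return PhiFold([d], rels)


def compound_fold(structure: PhiStructure, positions) -> PhiFold:
    """The union of the folds of every mechanism containing any of the given
    member positions."""
    mask = 0
    for p in positions:
        mask |= 1 << p
    ds = [d for d in structure.distinctions if d.mech_mask & mask]
    idx = {structure.distinctions.distinctions.index(d) for d in ds}
    rels = [r for r in structure.relations if idx & set(r.indices)]
    return PhiFold(ds, rels)
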