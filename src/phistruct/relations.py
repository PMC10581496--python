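"""Causal relations: congruent overlaps among distinction purviews.

A set of distinctions is related when their causes and/or effects overlap
congruently — over the same units in the same states. Purviews and overlaps
are sets of (unit, state) tuples throughout, so intersections and unions
automatically respect state congruence.

For a set of distinctions d, every selection of purviews (the cause, the
effect, or both, per distinction) whose common intersection is non-empty is a
*face* of the relation; a relation over |d| > 1 distinctions has at most
3^|d| faces, and a single distinction can carry one self-relation face (its
cause and effect jointly). The relation's integrated information is

    φ_r(d) = |∪ face purviews| · min_{d∈d} φ_d / |z*_c(d) ∪ z*_e(d)|,

the weakest distinction's irreducible information per unique purview unit,
scaled by the number of units jointly specified across all faces.

Enumeration over subsets of the distinction set is pruned by downward
closure: restricting a face's selection to a subset of its distinctions
leaves a non-empty intersection, so any related set has all its ≥1-subsets
related; candidate sets are grown level-wise from related subsets.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

from .mechanisms import Distinction, DistinctionSet
from .network import DEFAULT_TOL

__all__ = [
    "RelationFace",
    "Relation",
    "congruent_overlap",
    "enumerate_faces",
    "relation_phi",
    "compute_relations",
    "CapacityError",
]

MAX_DISTINCTIONS_DEFAULT = 20


class CapacityError(RuntimeError):
    """The distinction set exceeds the configured relation-enumeration cap."""


def congruent_relation_count(n_distinctions: int) -> int:
    """Exact relation count in the fully congruent special case.

    When every cause and effect purview of n distinctions overlaps on a
    shared congruent unit, every non-empty subset of the distinctions is
    related (self-relations included), giving 2**n − 1 relations — the upper
    bound for any distinction set of that size. Used to validate the
    brute-force enumeration."""
    return 2**n_distinctions - 1


def congruent_overlap(purviews) -> frozenset:
    """Intersection of purview sub-states over (unit, state) tuples; empty
    means no congruent overlap (state disagreement counts as no overlap)."""
    purviews = list(purviews)
    if len(purviews) < 2:
        raise ValueError("an overlap needs at least two purviews")
    out = frozenset(purviews[0])
    for p in purviews[1:]:
        out &= frozenset(p)
    return out


@dataclass(frozen=True)
class RelationFace:
    """One way a set of distinctions overlaps: a per-distinction selection of
    cause/effect purviews with their common congruent intersection."""

    selection: tuple[tuple[str, ...], ...]  # per distinction: ('c',), ('e',) or ('c','e')
    purview: frozenset  # o*(z), the face purview

    @property
    def degree(self) -> int:
        return sum(len(s) for s in self.selection)


def enumerate_faces(distinctions: list[Distinction]) -> list[RelationFace]:
    """All faces of the relation over ``distinctions``. Selections must pick
    more than one purview in total, so a single distinction only admits the
    {cause, effect} self-relation face."""
    options = [(("c",), ("e",), ("c", "e"))] * len(distinctions)
    faces = []
    for sel in itertools.product(*[o for o in options]):
        if sum(len(s) for s in sel) < 2:
            continue
        chosen = []
        for d, sides in zip(distinctions, sel):
            for side in sides:
                chosen.append(d.cause if side == "c" else d.effect)
        overlap = congruent_overlap(chosen)
        if overlap:
            faces.append(RelationFace(tuple(sel), overlap))
    return faces


@dataclass(frozen=True)
class Relation:
    """A related set of distinctions with its faces and φ_r."""

    indices: tuple[int, ...]  # positions into the distinction set
    faces: tuple[RelationFace, ...]
    joint_purview: frozenset  # union of face purviews (the relation purview)
    phi: float

    @property
    def degree(self) -> int:
        return len(self.indices)


def relation_phi(distinctions: list[Distinction], faces) -> tuple[float, frozenset]:
    """φ_r and the joint purview for a face set (Eq.-style minimum of the
    per-unit distributed φ_d scaled by the joint purview size)."""
    joint: frozenset = frozenset()
    for f in faces:
        joint |= f.purview
    if not joint:
        return 0.0, joint
    weakest = min(d.phi_d / d.purview_union_size() for d in distinctions)
    return len(joint) * weakest, joint


def _make_relation(dset: list[Distinction], idx: tuple[int, ...], tol: float) -> Relation | None:
    ds = [dset[i] for i in idx]
    faces = enumerate_faces(ds)
    if not faces:
        return None
    phi, joint = relation_phi(ds, faces)
    if phi <= tol:
        return None
    return Relation(idx, tuple(faces), joint, phi)


def compute_relations(
    distinctions: DistinctionSet | list[Distinction],
    tol: float = DEFAULT_TOL,
    max_distinctions: int = MAX_DISTINCTIONS_DEFAULT,
    pruned: bool = True,
) -> list[Relation]:
    """All relations (including self-relations) among a set of distinctions.

    ``pruned=False`` forces the unpruned exhaustive subset enumeration (oracle
    mode for small sets). Raises :class:`CapacityError` beyond the cap."""
    dset = list(distinctions)
    if len(dset) > max_distinctions:
        raise CapacityError(
            f"{len(dset)} distinctions exceed the relation cap of {max_distinctions}; "
            "raise max_distinctions or sample the distinction set"
        )
    out: list[Relation] = []
    if not pruned:
        for h in range(1, len(dset) + 1):
            for idx in itertools.combinations(range(len(dset)), h):
                rel = _make_relation(dset, idx, tol)
                if rel is not None:
                    out.append(rel)
        return out
    # level-wise growth: a set can only be related if all its subsets are
    level = []
    for i in range(len(dset)):
        rel = _make_relation(dset, (i,), tol)
        if rel is not None:
            out.append(rel)
    for i, j in itertools.combinations(range(len(dset)), 2):
        rel = _make_relation(dset, (i, j), tol)
        if rel is not None:
            out.append(rel)
            level.append((i, j))
    related_prev = set(level)
    while related_prev:
        candidates = set()
        for idx in related_prev:
            for j in range(idx[-1] + 1, len(dset)):
                cand = idx + (j,)
                if all(
                    tuple(x for x in cand if x != drop) in related_prev
                    for drop in cand
                ):
                    candidates.add(cand)
        related_next = set()
        for cand in sorted(candidates):
            rel = _make_relation(dset, cand, tol)
            if rel is not None:
                out.append(rel)
                related_next.add(cand)
        related_prev = related_next
    return out
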