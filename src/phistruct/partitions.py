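"""Directional system partitions.

A directional partition divides a system into k ≥ 2 disjoint covering parts
and assigns each part a direction: its inputs (←), outputs (→), or both (↔)
are severed and replaced by independent noise. The set of units whose inputs
to part S^(i) are cut is

    X^(i) = S \\ S^(i)                       if δ_i ∈ {←, ↔}
    X^(i) = ∪ { S^(j) : j ≠ i, δ_j ∈ {→, ↔} }  if δ_i = →

Distinct labelings can induce the same severed connections; partitions are
deduplicated by their induced cut-pair set (target, source). The normalization
Σ_i |S^(i)|·|X^(i)| — the maximal number of pairwise interactions a partition
can affect — equals the size of that cut-pair set.

A single-unit system admits one partition: the complete noising of the unit's
input from itself.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Sequence

IN, OUT, BOTH = "in", "out", "both"
_DELTA_SYMBOL = {IN: "←", OUT: "→", BOTH: "↔"}

__all__ = ["SystemPartition", "set_partitions", "labeled_partitions", "enumerate_partitions"]


@dataclass(frozen=True)
class SystemPartition:
    """A directional partition with its induced cut."""

    parts: tuple[tuple[int, ...], ...]
    deltas: tuple[str, ...]
    cut_pairs: frozenset  # of (target_unit, source_unit)

    @property
    def normalization(self) -> int:
        return len(self.cut_pairs)

    def cut_sources(self, i: int) -> tuple[int, ...]:
        """X^(i): units whose inputs into part i are severed."""
        part = set(self.parts[i])
        return tuple(sorted({src for (tgt, src) in self.cut_pairs if tgt in part}))

    def sort_key(self):
        return tuple(sorted((p, d) for p, d in zip(self.parts, self.deltas)))

    def describe(self, labels: Sequence[str] | None = None) -> str:
        def name(us):
            return "".join(labels[u] if labels else str(u) for u in us)

        return " / ".join(
            f"{name(p)}{_DELTA_SYMBOL[d]}" for p, d in zip(self.parts, self.deltas)
        )


def set_partitions(elements: Sequence, min_k: int = 2) -> Iterator[list[list]]:
    """All set partitions of ``elements`` into at least ``min_k`` blocks."""
    elements = list(elements)

    def rec(i, blocks):
        if i == len(elements):
            if len(blocks) >= min_k:
                yield [list(b) for b in blocks]
            return
        x = elements[i]
        for b in blocks:
            b.append(x)
            yield from rec(i + 1, blocks)
            b.pop()
        blocks.append([x])
        yield from rec(i + 1, blocks)
        blocks.pop()

    yield from rec(0, [])


def _cut_pairs(parts, deltas) -> frozenset:
    all_units = set().union(*(set(p) for p in parts))
    out_parts = set()
    for p, d in zip(parts, deltas):
        if d in (OUT, BOTH):
            out_parts.update(p)
    pairs = set()
    for p, d in zip(parts, deltas):
        pset = set(p)
        if d in (IN, BOTH):
            x = all_units - pset
        else:
            x = out_parts - pset
        pairs.update((t, s) for t in pset for s in x)
    return frozenset(pairs)


def labeled_partitions(members: Sequence[int]) -> Iterator[SystemPartition]:
    """Every (set-partition × direction-labeling) combination, before
    deduplication by induced cut (exposed for combinatorial checks)."""
    import itertools

    members = sorted(members)
    if not members:
        raise ValueError("cannot partition an empty unit set")
    for blocks in set_partitions(members, min_k=2):
        parts = tuple(tuple(sorted(b)) for b in sorted(blocks, key=lambda b: min(b)))
        for deltas in itertools.product((IN, OUT, BOTH), repeat=len(parts)):
            yield SystemPartition(parts, deltas, _cut_pairs(parts, deltas))


def enumerate_partitions(members: Sequence[int]) -> list[SystemPartition]:
    """All directional partitions of a unit set, deduplicated by induced
    cut-set. A singleton system yields the single complete self-input cut."""
    members = sorted(members)
    if not members:
        raise ValueError("cannot partition an empty unit set")
    if len(members) == 1:
        u = members[0]
        return [SystemPartition(((u,),), (BOTH,), frozenset({(u, u)}))]
    seen: dict[frozenset, SystemPartition] = {}
    for p in labeled_partitions(members):
        if p.cut_pairs not in seen or p.sort_key() < seen[p.cut_pairs].sort_key():
            seen[p.cut_pairs] = p
    return sorted(seen.values(), key=lambda p: p.sort_key())
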