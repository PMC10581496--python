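"""Maximal substrates (complexes) and recursive condensation of a universe.

A complex is a candidate system whose φ_s exceeds that of every overlapping
candidate. Complexes are extracted iteratively: the subset with maximal φ_s
is removed from candidacy (its units still serve as background conditions for
later rounds) and the search repeats on the remaining units until none are
left or no remaining subset is integrated. The result is a disjoint set of
complexes.

Tie handling (deterministic): non-overlapping candidates tied for maximal φ_s
are extracted simultaneously; if all tied candidates overlap, the next best
candidate that is unique at its φ_s level is chosen instead; residual
ambiguity prefers the larger system, then lexicographic unit order.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

from .integration import SystemPhiResult, system_phi
from .network import DEFAULT_TOL, Network
from .system import condition

__all__ = ["Complex", "find_first_complex", "condense"]

MAX_UNITS_DEFAULT = 8


@dataclass
class Complex:
    """A maximal substrate: members (global unit indices), state, φ_s*, rank."""

    members: tuple[int, ...]
    labels: tuple[str, ...]
    state: tuple[int, ...]
    phi: float
    rank: int
    result: SystemPhiResult | None = None

    @property
    def null(self) -> bool:
        return not self.members

    def state_label(self) -> str:
        from . import statespace as ss

        return ss.state_label(self.state, self.labels)

    def __repr__(self):
        if self.null:
            return "Complex(null)"
        return f"Complex({self.state_label()!r}, phi={self.phi:.4g}, rank={self.rank})"


class CandidateScan:
    """Scores φ_s for candidate subsets, caching results (the background of a
    candidate is always the rest of the universe at its current state, so a
    subset's score does not depend on the extraction round)."""

    def __init__(self, net: Network, tol: float = DEFAULT_TOL, max_units: int = MAX_UNITS_DEFAULT):
        if net.n > max_units:
            raise ValueError(
                f"universe has {net.n} units; exhaustive subset scan is capped at "
                f"{max_units} (raise max_units explicitly to override)"
            )
        self.net = net
        self.tol = tol
        self._cache: dict[tuple[int, ...], SystemPhiResult] = {}

    def score(self, members) -> SystemPhiResult:
        members = tuple(sorted(members))
        if members not in self._cache:
            self._cache[members] = system_phi(condition(self.net, members), tol=self.tol)
        return self._cache[members]

    def score_all(self, units) -> dict[tuple[int, ...], SystemPhiResult]:
        out = {}
        for r in range(1, len(units) + 1):
            for members in itertools.combinations(sorted(units), r):
                out[members] = self.score(members)
        return out


def _select_maximal(scored: dict, tol: float) -> list[tuple[tuple[int, ...], SystemPhiResult]]:
    """Apply the tie rules; returns the candidates to extract this round
    (possibly several if tied and mutually disjoint), or [] if nothing is
    integrated."""
    positive = {m: r for m, r in scored.items() if r.phi > tol}
    if not positive:
        return []
    levels = sorted({round(r.phi, 12) for r in positive.values()}, reverse=True)

    def level_members(lv):
        cands = [m for m, r in positive.items() if abs(r.phi - lv) <= tol]
        return sorted(cands, key=lambda m: (-len(m), m))

    top = level_members(levels[0])
    if len(top) == 1:
        return [(top[0], positive[top[0]])]
    if all(set(a).isdisjoint(b) for a, b in itertools.combinations(top, 2)):
        return [(m, positive[m]) for m in top]
    # all-overlapping (or mixed) tie at the top: the next best unique system
    for lv in levels[1:]:
        cands = level_members(lv)
        if len(cands) == 1:
            return [(cands[0], positive[cands[0]])]
        if all(set(a).isdisjoint(b) for a, b in itertools.combinations(cands, 2)):
            return [(m, positive[m]) for m in cands]
    # no unique level at all: deterministic fallback on the top level
    m = top[0]
    return [(m, positive[m])]


def find_first_complex(
    net: Network, tol: float = DEFAULT_TOL, max_units: int = MAX_UNITS_DEFAULT
) -> Complex:
    """Exhaustive scan of all non-empty unit subsets for the substrate with
    maximal φ_s. Returns a null complex (empty members) if no subset is
    integrated."""
    scan = CandidateScan(net, tol=tol, max_units=max_units)
    scored = scan.score_all(range(net.n))
    chosen = _select_maximal(scored, tol)
    if not chosen:
        return Complex((), (), (), 0.0, rank=0, result=None)
    members, result = chosen[0]
    return Complex(
        members,
        tuple(net.units[i] for i in members),
        tuple(net.state[i] for i in members),
        result.phi,
        rank=1,
        result=result,
    )


def condense(net: Network, tol: float = DEFAULT_TOL, max_units: int = MAX_UNITS_DEFAULT) -> list[Complex]:
    """Recursively extract disjoint complexes from the universe."""
    scan = CandidateScan(net, tol=tol, max_units=max_units)
    remaining = set(range(net.n))
    complexes: list[Complex] = []
    rank = 1
    while remaining:
        scored = scan.score_all(remaining)
        chosen = _select_maximal(scored, tol)
        if not chosen:
            break
        for members, result in chosen:
            complexes.append(
                Complex(
                    members,
                    tuple(net.units[i] for i in members),
                    tuple(net.state[i] for i in members),
                    result.phi,
                    rank=rank,
                    result=result,
                )
            )
            rank += 1
            remaining -= set(members)
    return complexes
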