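"""State-space indexing for finite-alphabet unit networks.

Joint states are tuples of per-unit state indices. The flat enumeration is
little-endian: unit 0 varies fastest. This convention is fixed for every
in-memory table and every file format in the package, so that serialized
TPMs round-trip bit-exactly.
"""

from __future__ import annotations

import itertools
from typing import Iterator, Sequence

import numpy as np

__all__ = [
    "state_index",
    "index_state",
    "iter_states",
    "n_states",
    "state_label",
    "parse_state_label",
]


def n_states(alphabets: Sequence[int]) -> int:
    out = 1
    for a in alphabets:
        out *= a
    return out


def state_index(state: Sequence[int], alphabets: Sequence[int]) -> int:
    """Flat index of a joint state (unit 0 fastest)."""
    idx = 0
    mult = 1
    for s, a in zip(state, alphabets):
        if not 0 <= s < a:
            raise ValueError(f"state component {s} outside alphabet of size {a}")
        idx += s * mult
        mult *= a
    return idx


def index_state(idx: int, alphabets: Sequence[int]) -> tuple[int, ...]:
    """Inverse of :func:`state_index`."""
    out = []
    for a in alphabets:
        idx, r = divmod(idx, a)
        out.append(r)
    return tuple(out)


def iter_states(alphabets: Sequence[int]) -> Iterator[tuple[int, ...]]:
    """All joint states in flat (little-endian) order."""
    for combo in itertools.product(*(range(a) for a in reversed(alphabets))):
        yield tuple(reversed(combo))


def as_grid(rows: np.ndarray, alphabets: Sequence[int]) -> np.ndarray:
    """Reshape a table whose leading axis enumerates joint states into a grid
    with one axis per unit (axis i belongs to unit i)."""
    tail = rows.shape[1:]
    return rows.reshape(tuple(alphabets) + tail, order="F")


def from_grid(grid: np.ndarray, n_units: int) -> np.ndarray:
    """Inverse of :func:`as_grid` for the leading ``n_units`` axes."""
    shape = grid.shape
    lead = 1
    for a in shape[:n_units]:
        lead *= a
    return grid.reshape((lead,) + shape[n_units:], order="F")


def state_label(state: Sequence[int], units: Sequence[str]) -> str:
    """Render a binary state as a case-coded label (lowercase = state 0/OFF,
    uppercase = state 1/ON). Falls back to a comma-joined index list for
    non-binary alphabets or non-letter unit names."""
    parts = []
    for s, name in zip(state, units):
        if len(name) == 1 and name.isalpha() and s in (0, 1):
            parts.append(name.upper() if s == 1 else name.lower())
        else:
            return ",".join(str(x) for x in state)
    return "".join(parts)


def parse_state_label(label: str, units: Sequence[str]) -> tuple[int, ...]:
    """Parse a case-coded binary state label such as ``"Abcdef"``."""
    if len(label) != len(units):
        raise ValueError(f"state label {label!r} has wrong length for {len(units)} units")
    state = []
    for ch, name in zip(label, units):
        if ch.lower() != name.lower():
            raise ValueError(f"state label {label!r} does not match unit order {list(units)}")
        state.append(1 if ch.isupper() else 0)
    return tuple(state)
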