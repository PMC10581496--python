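"""System integrated information φ_s over the minimum directional partition.

For a partition θ the partitioned TPM replaces every severed connection by
independent noise: the factor of unit j in part S^(i) is averaged uniformly
over the states of its cut sources X^(i), with the intact inputs held fixed.
Integrated effect information is

    φ_e(θ) = p_e(s′_e|s) · | log2( p_e(s′_e|s) / p_eθ(s′_e|s) ) |₊

(and analogously φ_c with the backward selectivity), φ_s(θ) = min(φ_c, φ_e).
The minimum information partition θ′ minimizes φ_s(θ) normalized by the
maximal number of connections θ can affect, Σ|S^(i)||X^(i)|; the reported
φ_s is the unnormalized value at θ′. Ties on the normalized value go to the
partition with the largest unnormalized φ_s, then to the lowest lexicographic
part encoding.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import statespace as ss
from .intrinsic import CauseEffectState, maximal_cause_effect_state
from .network import DEFAULT_TOL
from .partitions import SystemPartition, enumerate_partitions
from .system import ConditionedSystem

__all__ = ["SystemPhiResult", "partitioned_tpm", "phi_directional", "system_phi"]


def _mask(positions) -> int:
    m = 0
    for p in positions:
        m |= 1 << p
    return m


def _cut_masks(partition: SystemPartition, n: int) -> dict[int, int]:
    """Per-unit bitmask of severed input sources."""
    masks = {t: 0 for t in range(n)}
    for (t, s) in partition.cut_pairs:
        masks[t] |= 1 << s
    return masks


def _pos_log_ratio(p: float, q: float, tol: float) -> float:
    """|log2(p/q)|₊ with a tolerance so that numerically identical
    probabilities yield exactly zero."""
    if p <= tol or q <= 0:
        return 0.0
    r = np.log2(p / q)
    return float(r) if r > tol else 0.0


def partitioned_tpm(system: ConditionedSystem, partition: SystemPartition, side: str) -> np.ndarray:
    """The full partitioned joint TPM T^θ for one side (product over unit
    factors with cut inputs causally marginalized). Used mainly by oracle
    checks; φ evaluation touches only the needed entries."""
    n = system.n
    nfull = system.n_states
    side = "e" if side.startswith("e") else "c"
    masks = _cut_masks(partition, n)
    comps = [ss.index_state(r, system.alphabets) for r in range(nfull)]
    out = np.empty((nfull, nfull))
    for r in range(nfull):
        for c in range(nfull):
            v = 1.0
            for t in range(n):
                v *= system.partitioned_factor(side, t, masks[t], comps[r], comps[c][t])
            out[r, c] = v
    return out


def _factor_product(system, side, row_state, col_state, masks) -> float:
    v = 1.0
    for t in range(system.n):
        v *= system.partitioned_factor(side, t, masks[t], row_state, col_state[t])
    return v


def _intact_effect(system: ConditionedSystem, effect_state) -> float:
    row = ss.state_index(system.state, system.alphabets)
    v = 1.0
    for t in range(system.n):
        v *= system.te_factors[t][row, effect_state[t]]
    return float(v)


def _intact_cause(system: ConditionedSystem, cause_state) -> tuple[float, float]:
    """(p_c(s|s̄'), backward selectivity p_c←(s̄'|s))."""
    tc = system.cause_tpm()
    s = ss.state_index(system.state, system.alphabets)
    sbar = ss.state_index(cause_state, system.alphabets)
    col = tc[:, s]
    total = col.sum()
    return float(col[sbar]), float(col[sbar] / total) if total > 0 else 0.0


def phi_directional(
    system: ConditionedSystem,
    side: str,
    state,
    partition: SystemPartition,
    tol: float = DEFAULT_TOL,
) -> float:
    """φ_c or φ_e of the system for one partition: selectivity times the
    positive part of the log-ratio of intact vs partitioned probability of
    the maximal state on that side."""
    masks = _cut_masks(partition, system.n)
    if side == "effect":
        p = _intact_effect(system, state)
        sel = p
        q = _factor_product(system, "e", system.state, state, masks)
    elif side == "cause":
        p, sel = _intact_cause(system, state)
        q = _factor_product(system, "c", state, system.state, masks)
    else:
        raise ValueError(f"side must be 'cause' or 'effect', got {side!r}")
    return sel * _pos_log_ratio(p, q, tol)


@dataclass
class SystemPhiResult:
    """φ_s of a candidate system with its minimum partition and cause-effect state."""

    phi: float
    phi_c: float
    phi_e: float
    mip: SystemPartition | None
    normalized_phi: float
    ces: CauseEffectState
    reducible: bool = False
    labels: tuple = field(default_factory=tuple)

    @property
    def cause_state(self):
        return self.ces.cause_state

    @property
    def effect_state(self):
        return self.ces.effect_state


def _side_phi_at_mip(system, side, state_idx, parts_list, tol) -> float:
    """φ on one side at that side's own normalized-minimum partition (used to
    resolve ties among maximal states, per the maximal existence principle)."""
    state = ss.index_state(state_idx, system.alphabets)
    best = None
    for theta in parts_list:
        phi = phi_directional(system, side, state, theta, tol)
        key = (phi / theta.normalization, -phi, theta.sort_key())
        if best is None or key < best[0]:
            best = (key, phi)
    return best[1]


def system_phi(system: ConditionedSystem, tol: float = DEFAULT_TOL) -> SystemPhiResult:
    """Evaluate φ_s over the maximal cause-effect state and all directional
    partitions of the system (exhaustive search, deduplicated cut-sets)."""
    if system.te_factors is None:
        system.build_effect()
    if system.tc_factors is None:
        system.build_cause()
    te = system.effect_tpm()
    tc = system.cause_tpm()
    s = ss.state_index(system.state, system.alphabets)
    parts_list = enumerate_partitions(range(system.n))

    def tie_break(side, tied):
        scored = [(-_side_phi_at_mip(system, side, st, parts_list, tol), st) for st in tied]
        return min(scored)[1]

    ces = maximal_cause_effect_state(te, tc, s, tol=tol, tie_break=tie_break)
    if ces.powerless:
        return SystemPhiResult(0.0, 0.0, 0.0, None, 0.0, ces, reducible=True,
                               labels=system.labels())

    e_state = ss.index_state(ces.effect_state, system.alphabets)
    c_state = ss.index_state(ces.cause_state, system.alphabets)
    best = None
    for theta in parts_list:
        phi_e = phi_directional(system, "effect", e_state, theta, tol)
        phi_c = phi_directional(system, "cause", c_state, theta, tol)
        phi_s = min(phi_c, phi_e)
        key = (phi_s / theta.normalization, -phi_s, theta.sort_key())
        if best is None or key < best[0]:
            best = (key, phi_s, phi_c, phi_e, theta)
    _, phi_s, phi_c, phi_e, theta = best
    return SystemPhiResult(
        phi=phi_s,
        phi_c=phi_c,
        phi_e=phi_e,
        mip=theta,
        normalized_phi=phi_s / theta.normalization,
        ces=ces,
        reducible=phi_s <= tol,
        labels=system.labels(),
    )
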