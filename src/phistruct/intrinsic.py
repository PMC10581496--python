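"""System-level intrinsic cause/effect information and the maximal cause-effect state.

Intrinsic information (ii, in intrinsic bits) is the product of selectivity
and informativeness. On the effect side, for current state s and candidate
effect state s̄,

    ii_e(s, s̄) = p_e(s̄|s) · log2( p_e(s̄|s) / p_e(s̄) ),

with p_e(s̄) the effect probability averaged over a uniform distribution of
current states. On the cause side the selectivity is the backward probability
obtained by Bayes' rule under a uniform prior over cause states,

    ii_c(s, s̄) = p_c←(s̄|s) · log2( p_c(s|s̄) / p_c(s) ).

The maximal cause-effect state is the argmax of ii on each side. ii values of
non-maximal states may be negative; the maximum is always ≥ 0, and it is 0
exactly when the constrained repertoire equals chance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network import DEFAULT_TOL

__all__ = [
    "CauseEffectState",
    "unconstrained_effect_probability",
    "ii_effect",
    "ii_cause",
    "ii_effect_all",
    "ii_cause_all",
    "maximal_cause_effect_state",
]


class UnreachableSystemStateError(ValueError):
    """The system's current state has zero probability under every cause state."""


def _xlog2(p: np.ndarray, q: np.ndarray, sel: np.ndarray | None = None) -> np.ndarray:
    """sel · log2(p/q) with the 0·log(·) = 0 convention (sel defaults to p)."""
    if sel is None:
        sel = p
    out = np.zeros_like(np.asarray(p, dtype=float))
    mask = (np.asarray(p) > 0) & (np.asarray(q) > 0)
    out[mask] = np.asarray(sel)[mask] * np.log2(np.asarray(p)[mask] / np.asarray(q)[mask])
    return out


def unconstrained_effect_probability(te: np.ndarray, sbar: int | None = None):
    """p_e(s̄): the effect probability averaged over all current states with
    equal weight (column mean of Te). Returns the full vector if ``sbar`` is
    omitted."""
    col_mean = np.asarray(te, dtype=float).mean(axis=0)
    return col_mean if sbar is None else float(col_mean[sbar])


def ii_effect_all(te: np.ndarray, s: int) -> np.ndarray:
    """Intrinsic effect information of current state ``s`` over every
    candidate effect state (vector over Ω_S)."""
    te = np.asarray(te, dtype=float)
    return _xlog2(te[s], te.mean(axis=0))


def ii_effect(te: np.ndarray, s: int, sbar: int) -> float:
    """ii_e(s, s̄) in ibits; negative values are allowed for non-maximal s̄."""
    return float(ii_effect_all(te, s)[sbar])


def ii_cause_all(tc: np.ndarray, s: int) -> np.ndarray:
    """Intrinsic cause information of current state ``s`` over every candidate
    cause state. ``tc`` rows are cause states s̄, columns current states."""
    tc = np.asarray(tc, dtype=float)
    col = tc[:, s]  # p_c(s | s̄) for every s̄
    total = col.sum()
    if total <= DEFAULT_TOL:
        raise UnreachableSystemStateError(
            f"system state index {s} is unreachable (p_c(s|s̄) = 0 for every s̄)"
        )
    backward = col / total  # p_c←(s̄|s), Bayes under uniform prior on s̄
    pc_s = col.mean()  # unconstrained p_c(s)
    return _xlog2(col, np.full_like(col, pc_s), sel=backward)


def ii_cause(tc: np.ndarray, s: int, sbar: int) -> float:
    return float(ii_cause_all(tc, s)[sbar])


@dataclass
class CauseEffectState:
    """The maximal cause-effect state of a system in its current state.

    ``cause_state``/``effect_state`` are flat state indices (None when the
    corresponding side has no cause-effect power, i.e. ii = 0)."""

    cause_state: int | None
    effect_state: int | None
    ii_c: float
    ii_e: float
    cause_ties: tuple[int, ...] = ()
    effect_ties: tuple[int, ...] = ()

    @property
    def powerless(self) -> bool:
        return self.cause_state is None or self.effect_state is None


def _argmax_with_ties(values: np.ndarray, tol: float) -> tuple[float, list[int]]:
    best = float(values.max())
    tied = [int(i) for i in np.nonzero(values >= best - tol)[0]]
    return best, tied


def maximal_cause_effect_state(
    te: np.ndarray,
    tc: np.ndarray,
    s: int,
    tol: float = DEFAULT_TOL,
    tie_break=None,
) -> CauseEffectState:
    """Select the cause and effect states that maximize intrinsic information.

    Ties within ``tol`` are resolved by ``tie_break(side, tied_states)`` when
    given (the system-integration layer supplies a resolver that scores each
    tied state by its φ over that side's minimum partition, per the maximal
    existence principle); otherwise by smallest state index. A side whose
    maximal ii is ≤ tol has no cause-effect power and selects no state.
    """
    out = {}
    for side, values in (("effect", ii_effect_all(te, s)), ("cause", ii_cause_all(tc, s))):
        best, tied = _argmax_with_ties(values, tol)
        if best <= tol:
            out[side] = (None, 0.0, tuple(tied))
            continue
        if len(tied) > 1 and tie_break is not None:
            chosen = tie_break(side, tied)
        else:
            chosen = tied[0]
        out[side] = (chosen, float(values[chosen]), tuple(tied))
    (e_state, ii_e, e_ties) = out["effect"]
    (c_state, ii_c, c_ties) = out["cause"]
    return CauseEffectState(
        cause_state=c_state,
        effect_state=e_state,
        ii_c=ii_c,
        ii_e=ii_e,
        cause_ties=c_ties,
        effect_ties=e_ties,
    )
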