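"""Weighted state-to-state transition analytics.

Transition matrices are estimated from a weighted sequence pool either at
spell level (each adjacent pair of spells counts once per trajectory weight;
the diagonal is empty by construction) or at day level (each day-to-day pair
counts, making the matrix diagonal-heavy with state stability).  Rates are
row-normalized counts; rows without outgoing mass are flagged absorbing.

Severity (number of dependent ADLs) orders the states: a transition that
lowers severity is a *recovery*, one that raises it a *decline*, and an
equal-severity move is *lateral*.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

from .sequences import SequencePool
from .states import severity, state_name

__all__ = [
    "TransitionMatrix",
    "NextState",
    "transition_rates",
    "classify_transition",
    "recovery_fraction",
    "most_likely_next",
    "top_recovery_patterns",
]


@dataclass
class TransitionMatrix:
    """Weighted transition counts and row-stochastic rates over an alphabet."""

    alphabet: list[int]
    counts: np.ndarray
    mode: str  # "spell" | "daily"
    _index: dict[int, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        a = len(self.alphabet)
        if self.counts.shape != (a, a):
            raise ValueError("counts shape must match the alphabet")
        if self.mode not in ("spell", "daily"):
            raise ValueError("mode must be 'spell' or 'daily'")
        self._index = {s: i for i, s in enumerate(self.alphabet)}

    @property
    def rates(self) -> np.ndarray:
        """Row-normalized counts; absorbing rows stay all-zero."""
        totals = self.counts.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.where(totals > 0, self.counts / totals, 0.0)
        return r

    @property
    def absorbing(self) -> np.ndarray:
        """Boolean mask of rows with no outgoing transitions."""
        return self.counts.sum(axis=1) == 0

    def without_diagonal(self) -> "TransitionMatrix":
        """Copy with the diagonal zeroed (for display and next-state prediction)."""
        counts = self.counts.copy()
        np.fill_diagonal(counts, 0.0)
        return TransitionMatrix(list(self.alphabet), counts, self.mode)

    def rate(self, i: int, j: int) -> float:
        return float(self.rates[self._index[i], self._index[j]])

    def to_frame(self) -> pd.DataFrame:
        """Square rate matrix with state-name headers."""
        names = [state_name(s) for s in self.alphabet]
        return pd.DataFrame(self.rates, index=names, columns=names)

    def to_long_frame(self) -> pd.DataFrame:
        """Tidy (from, to, count, rate, class) rows for nonzero counts."""
        rates = self.rates
        rows = []
        for i, si in enumerate(self.alphabet):
            for j, sj in enumerate(self.alphabet):
                if self.counts[i, j] > 0:
                    rows.append(
                        {
                            "from": state_name(si),
                            "to": state_name(sj),
                            "from_code": si,
                            "to_code": sj,
                            "count": float(self.counts[i, j]),
                            "rate": float(rates[i, j]),
                            "class": "stable" if si == sj else classify_transition(si, sj),
                        }
                    )
        return pd.DataFrame(
            rows,
            columns=["from", "to", "from_code", "to_code", "count", "rate", "class"],
        )


def _single_change(i: int, j: int) -> bool:
    return (i ^ j).bit_count() == 1


def transition_rates(
    pool: SequencePool,
    mode: str = "spell",
    single_change_only: bool = False,
) -> TransitionMatrix:
    """Estimate the weighted transition matrix of a pool.

    ``spell`` mode counts each adjacent spell pair once per trajectory
    weight (diagonal empty); ``daily`` mode counts day-to-day pairs, so a
    spell of ``d`` days contributes ``d - 1`` diagonal counts plus one
    off-diagonal count at its boundary.  ``single_change_only`` drops
    transitions that flip more than one ADL at once, mirroring an analysis
    restricted to one-disability steps.
    """
    if len(pool) == 0:
        raise ValueError("empty pool")
    a = pool.a
    index = {s: k for k, s in enumerate(pool.alphabet)}
    counts = np.zeros((a, a), dtype=float)
    for traj in pool:
        w = traj.weight
        if mode == "spell":
            for sp_a, sp_b in zip(traj.spells, traj.spells[1:]):
                if single_change_only and not _single_change(sp_a.state, sp_b.state):
                    continue
                counts[index[sp_a.state], index[sp_b.state]] += w
        elif mode == "daily":
            for k, sp in enumerate(traj.spells):
                i = index[sp.state]
                counts[i, i] += w * (sp.duration - 1)
                if k + 1 < traj.n_spells:
                    j = index[traj.spells[k + 1].state]
                    if single_change_only and not _single_change(
                        sp.state, traj.spells[k + 1].state
                    ):
                        continue
                    counts[i, j] += w
        else:
            raise ValueError("mode must be 'spell' or 'daily'")
    return TransitionMatrix(list(pool.alphabet), counts, mode)


def classify_transition(i: int, j: int) -> str:
    """``recovery`` if severity falls, ``decline`` if it rises, else ``lateral``."""
    if i == j:
        raise ValueError("a transition requires two distinct states")
    si, sj = severity(i), severity(j)
    if sj < si:
        return "recovery"
    if sj > si:
        return "decline"
    return "lateral"


def recovery_fraction(pool: SequencePool) -> float:
    """Weighted share of spell-level transitions that are recoveries."""
    num = den = 0.0
    for traj in pool:
        for a, b in zip(traj.states, traj.states[1:]):
            den += traj.weight
            if severity(b) < severity(a):
                num += traj.weight
    if den == 0:
        raise ValueError("pool contains no transitions")
    return num / den


class NextState(NamedTuple):
    """Modal next state: ``state`` is None for absorbing rows; ``tied`` marks
    a tie broken toward the lowest state code."""

    state: int | None
    rate: float
    tied: bool


def most_likely_next(matrix: TransitionMatrix, state: int) -> NextState:
    """Most likely next state from ``state`` (diagonal excluded)."""
    if state not in matrix._index:
        raise KeyError(f"state {state} not in the matrix alphabet")
    nd = matrix.without_diagonal()
    i = nd._index[state]
    row = nd.rates[i]
    if nd.counts[i].sum() == 0:
        return NextState(None, 0.0, False)
    best = float(row.max())
    winners = [nd.alphabet[j] for j in np.flatnonzero(row == best)]
    return NextState(min(winners), best, len(winners) > 1)


def top_recovery_patterns(matrix: TransitionMatrix, k: int) -> list[tuple[tuple[int, int], float]]:
    """The ``k`` recovery transitions with the highest rates.

    Ranked by rate, then weighted count, then (from, to) codes; returns
    ``((from_state, to_state), rate)`` pairs.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    rates = matrix.rates
    entries = []
    for i, si in enumerate(matrix.alphabet):
        for j, sj in enumerate(matrix.alphabet):
            if matrix.counts[i, j] > 0 and si != sj:
                if classify_transition(si, sj) == "recovery":
                    entries.append(((si, sj), float(rates[i, j]), float(matrix.counts[i, j])))
    entries.sort(key=lambda e: (-e[1], -e[2], e[0]))
    return [(pair, rate) for pair, rate, _ in entries[:k]]
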