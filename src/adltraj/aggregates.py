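"""Cross-sectional and whole-pool descriptive analytics.

Covers the four descriptive views of a weighted trajectory pool: the
day-by-day state distribution (which state prevails at each follow-up day),
the most frequent trajectories, the mean time spent in each state, and a
deterministic evenly-spaced sample of sorted trajectories for index plots.
"""

from __future__ import annotations

import functools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .sequences import SequencePool, Trajectory
from .states import state_name

__all__ = [
    "StateDistribution",
    "state_distribution",
    "most_frequent",
    "mean_time_per_state",
    "sample_index",
]


@dataclass
class StateDistribution:
    """Per-day weighted state proportions among trajectories still observed."""

    days: np.ndarray  # the time grid, 1-based days
    proportions: pd.DataFrame  # index: day, columns: state codes, rows sum to 1
    observed_mass: np.ndarray  # total weight still observed at each grid day


def state_distribution(
    pool: SequencePool,
    grid: np.ndarray | None = None,
    dropout: bool = True,
) -> StateDistribution:
    """Weighted proportion of each alphabet state at each grid day.

    At day ``t`` the weights of trajectories of length >= ``t`` are placed
    on their day-``t`` states and normalized.  With ``dropout`` (default),
    ended trajectories leave the denominator (right truncation); with
    ``dropout=False`` they are carried in an explicit ``"exited"`` column so
    proportions stay comparable across days.
    """
    if len(pool) == 0:
        raise ValueError("empty pool")
    max_len = max(t.length for t in pool)
    if grid is None:
        grid = np.arange(1, max_len + 1)
    grid = np.asarray(grid, dtype=int)
    if grid.size == 0:
        raise ValueError("empty time grid")
    if grid.min() < 1 or grid.max() > max_len:
        raise ValueError(f"grid must lie within [1, {max_len}]")

    index = {s: k for k, s in enumerate(pool.alphabet)}
    mass = np.zeros((grid.size, pool.a))
    exited = np.zeros(grid.size)
    for traj in pool:
        ends = np.cumsum(traj.durations)
        inside = grid <= ends[-1]
        spell_idx = np.searchsorted(ends, grid[inside], side="left")
        cols = [index[traj.spells[k].state] for k in spell_idx]
        np.add.at(mass, (np.flatnonzero(inside), cols), traj.weight)
        exited[~inside] += traj.weight

    observed = mass.sum(axis=1)
    if dropout:
        with np.errstate(invalid="ignore", divide="ignore"):
            props = np.where(observed[:, None] > 0, mass / observed[:, None], 0.0)
        frame = pd.DataFrame(props, index=grid, columns=pool.alphabet)
    else:
        total = observed + exited
        block = np.column_stack([mass, exited]) / total[:, None]
        frame = pd.DataFrame(block, index=grid, columns=[*pool.alphabet, "exited"])
    frame.index.name = "day"
    return StateDistribution(days=grid, proportions=frame, observed_mass=observed)


def _daily_name_cmp(t1: Trajectory, t2: Trajectory) -> int:
    """Lexicographic comparison of the day-by-day state-name sequences,
    walking spells without expanding to daily vectors."""
    i = j = 0
    r1 = t1.spells[0].duration
    r2 = t2.spells[0].duration
    while True:
        n1 = state_name(t1.spells[i].state)
        n2 = state_name(t2.spells[j].state)
        if n1 != n2:
            return -1 if n1 < n2 else 1
        step = min(r1, r2)
        r1 -= step
        r2 -= step
        if r1 == 0:
            i += 1
            if i == t1.n_spells:
                # t1 exhausted: shorter (or equal) sequence sorts first
                return 0 if (r2 == 0 and j == t2.n_spells - 1) else -1
            r1 = t1.spells[i].duration
        if r2 == 0:
            j += 1
            if j == t2.n_spells:
                return 1
            r2 = t2.spells[j].duration


def most_frequent(pool: SequencePool, k: int) -> list[Trajectory]:
    """Top-``k`` trajectories by weight.

    Ties break toward the shorter trajectory, then by the lexicographic
    order of the daily state-name sequence, so the ranking is deterministic.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    ordered = sorted(
        pool,
        key=functools.cmp_to_key(
            lambda x, y: (
                (y.weight > x.weight) - (y.weight < x.weight)
                or (x.length > y.length) - (x.length < y.length)
                or _daily_name_cmp(x, y)
            )
        ),
    )
    return ordered[:k]


def mean_time_per_state(pool: SequencePool) -> pd.Series:
    """Weighted mean days spent in each alphabet state, descending.

    Trajectories that never visit a state contribute zero days for it
    (population mean), matching the zero-padding convention of the starred
    spell-duration statistics.
    """
    if len(pool) == 0:
        raise ValueError("empty pool")
    index = {s: k for k, s in enumerate(pool.alphabet)}
    totals = np.zeros(pool.a)
    for traj in pool:
        for sp in traj.spells:
            totals[index[sp.state]] += traj.weight * sp.duration
    means = totals / pool.total_weight
    series = pd.Series(means, index=pool.alphabet, name="mean_days")
    series.index.name = "state"
    return series.sort_values(ascending=False, kind="mergesort")


def sample_index(pool: SequencePool, n: int = 250) -> list[Trajectory]:
    """Evenly spaced sample of the sorted pool, for index plots.

    Trajectories are sorted lexicographically by their daily state-name
    sequence, partitioned into ``n`` contiguous groups of ``ceil(N/n)``
    (the last possibly smaller), and the first trajectory of each group is
    returned, order preserved.  Pools smaller than ``n`` are returned whole
    with a warning.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    ordered = sorted(pool, key=functools.cmp_to_key(_daily_name_cmp))
    big_n = len(ordered)
    if big_n < n:
        warnings.warn(
            f"pool holds only {big_n} trajectories (< n={n}); returning all",
            stacklevel=2,
        )
        return ordered
    group = math.ceil(big_n / n)
    return ordered[::group]
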