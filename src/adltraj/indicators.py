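"""Per-trajectory sequence indicators: basic, diversity, complexity and
(un)favorableness measures.

The suite covers four families.  *Basic*: length in days, spell count,
number of distinct visited states and the recurrence degree
(spells per visited state; 1 means no state is revisited).  *Diversity*:
longitudinal Shannon entropy of the day-level state occupancy, normalized by
``log(a)`` where ``a`` is the alphabet size, plus spell-duration mean and
standard deviation, optionally padded with one zero-length spell per
non-visited alphabet state.  *Complexity*: the turbulence measure

    T*(x) = log2( Phi(x) * (s*^2_max + 1) / (s*^2 + 1) )

where ``Phi(x)`` is the exact count of distinct subsequences of the
distinct-successive-states (DSS) sequence (empty subsequence included) and
``s*^2`` the padded population variance of spell durations; ``T*`` is then
normalized against the most turbulent sequence of the same length over the
same alphabet (unit-day spells cycling through the alphabet).  *Unfavorable-
ness*: the insecurity index

    I_insec(x) = pi(x_1) * I_integr(x, sp(x_1)) + I_degrad(x) + c(x)

combining the severity of the initial state (rescaled to [0, 1]), the
integrative potential of the first spell, the degradation index
(worsening minus improving transitions over all transitions, severity
ordering the states) and the complexity index
``c(x) = sqrt(transition share * normalized entropy)``.
"""

from __future__ import annotations

import math
from functools import lru_cache

import numpy as np
import pandas as pd

from .sequences import SequencePool, Trajectory
from .states import severity, severity_norm

__all__ = [
    "basic_indicators",
    "spell_duration_stats",
    "entropy_norm",
    "count_distinct_subsequences",
    "turbulence",
    "integration_index",
    "degradation_index",
    "complexity_index",
    "insecurity_index",
    "indicator_row",
    "indicators_frame",
    "weighted_quantile",
    "indicator_table",
    "INDICATOR_COLUMNS",
]

INDICATOR_COLUMNS = (
    "length",
    "n_spells",
    "n_visited",
    "recurrence",
    "spell_dur_mean",
    "spell_dur_sd",
    "spell_dur_mean_star",
    "spell_dur_sd_star",
    "entropy",
    "entropy_norm",
    "phi",
    "turbulence",
    "turbulence_norm",
    "integration",
    "degradation",
    "complexity",
    "insecurity",
)


def basic_indicators(traj: Trajectory) -> dict:
    """Length, spell count, visited-state count and recurrence degree."""
    n_spells = traj.n_spells
    n_visited = len(traj.visited)
    return {
        "length": traj.length,
        "n_spells": n_spells,
        "n_visited": n_visited,
        "recurrence": n_spells / n_visited,
    }


def _padded_durations(traj: Trajectory, a: int) -> np.ndarray:
    n_visited = len(traj.visited)
    if a < n_visited:
        raise ValueError(
            f"alphabet size {a} smaller than the {n_visited} states visited"
        )
    dur = np.asarray(traj.durations, dtype=float)
    return np.concatenate([dur, np.zeros(a - n_visited)])


def spell_duration_stats(
    traj: Trajectory, a: int | None = None, include_unvisited: bool = False
) -> tuple[float, float]:
    """Mean and population SD of spell durations.

    With ``include_unvisited`` the duration list is padded with one
    zero-length spell per alphabet state the trajectory never visits
    (``a - n_visited`` zeros), so that never-entered states pull the summary
    toward zero.
    """
    if include_unvisited:
        if a is None:
            raise ValueError("alphabet size required when include_unvisited=True")
        dur = _padded_durations(traj, a)
    else:
        dur = np.asarray(traj.durations, dtype=float)
    return float(dur.mean()), float(dur.std(ddof=0))


def _occupancy(traj: Trajectory, level: str) -> np.ndarray:
    """State-occupancy probabilities: day-level (default) or spell-level."""
    if level == "day":
        weights: dict[int, float] = {}
        for sp in traj.spells:
            weights[sp.state] = weights.get(sp.state, 0.0) + sp.duration
    elif level == "spell":
        weights = {}
        for sp in traj.spells:
            weights[sp.state] = weights.get(sp.state, 0.0) + 1.0
    else:
        raise ValueError("level must be 'day' or 'spell'")
    p = np.asarray(list(weights.values()), dtype=float)
    return p / p.sum()


def entropy_norm(traj: Trajectory, a: int, level: str = "day") -> float:
    """Longitudinal normalized entropy ``H / log(a)`` in [0, 1].

    ``p_i`` is the fraction of the trajectory spent in state ``i`` (day-level
    occupancy by default; spell-level available for comparison).  The
    maximum entropy ``log(a)`` is attained when occupancy is uniform over
    the whole alphabet.  Defined as 0 for a single-state alphabet.
    """
    if a < 1:
        raise ValueError("alphabet size must be >= 1")
    if a == 1:
        return 0.0
    p = _occupancy(traj, level)
    h = float(-(p * np.log(p)).sum())
    return h / math.log(a)


def count_distinct_subsequences(dss) -> int:
    """Exact number of distinct subsequences of a DSS sequence, empty one included.

    Uses the standard dynamic program ``phi_i = 2 phi_{i-1} - phi_{j-1}``
    where ``j`` is the previous position of the symbol at ``i`` (the
    subtraction removes subsequences counted twice), with arbitrary-precision
    integers, so counts like the multi-million values seen on long
    trajectories are exact.
    """
    dss = list(dss)
    phi = [1] * (len(dss) + 1)  # phi[i]: count over the first i symbols
    last: dict[object, int] = {}
    for i, sym in enumerate(dss, start=1):
        phi[i] = 2 * phi[i - 1]
        if sym in last:
            phi[i] -= phi[last[sym] - 1]
        last[sym] = i
    return phi[len(dss)]


def _max_padded_variance(n_spells: int, length: int, m: int) -> float:
    """Maximum population variance of a padded duration list.

    Over all allocations of ``length`` days to ``n_spells`` spells of at
    least one day each, padded with ``m - n_spells`` zero-length spells, the
    variance is maximized by concentrating all slack in one spell:
    durations ``(1, ..., 1, length - n_spells + 1, 0, ..., 0)``.  The closed
    form below is that configuration's variance; with no padding
    (``m == n_spells``) it reduces to the classic bound
    ``(n - 1) (1 - mean)^2``.
    """
    mu = length / m
    return (
        (n_spells - 1) * (1.0 - mu) ** 2
        + (length - n_spells + 1 - mu) ** 2
        + (m - n_spells) * mu**2
    ) / m


def _log2_turbulence(phi: int, s2: float, s2max: float) -> float:
    # split the log so that astronomically large phi stays exact
    return math.log2(phi) + math.log2((s2max + 1.0) / (s2 + 1.0))


@lru_cache(maxsize=4096)
def _log2_phi_reference(length: int, a: int) -> float:
    """log2 of Phi for the maximal-turbulence reference sequence.

    The reference sequence has ``length`` unit-day spells cycling through
    the alphabet (floor(l/a) full cycles plus the first ``l mod a`` states),
    so the previous occurrence of each symbol is exactly ``a`` steps back.
    """
    phi = [1] * (length + 1)
    for i in range(1, length + 1):
        phi[i] = 2 * phi[i - 1]
        if i > a:
            phi[i] -= phi[i - a - 1]
    return math.log2(phi[length])


def turbulence(traj: Trajectory, a: int) -> tuple[float, float]:
    """Turbulence ``T*`` and its normalized version ``T*_n``.

    ``T* = log2(Phi * (s*^2_max + 1)/(s*^2 + 1))`` with the zero-padded
    duration variance; ``T*_n = (T* - 1)/(T*_max - 1)`` where ``T*_max`` is
    the turbulence of the reference sequence of the same total length whose
    unit-day spells cycle through the alphabet.  The reference attains its
    own variance bound, so its ratio term is 1 and ``T*_max`` reduces to
    ``log2(Phi_ref)``.  Degenerate normalizations (``T*_max <= 1``, possible
    only for day-scale lengths) return ``T*_n = 0``.
    """
    if a < 1:
        raise ValueError("alphabet size must be >= 1")
    length = traj.length
    dur = _padded_durations(traj, a)
    m = dur.size
    s2 = float(dur.var(ddof=0))
    s2max = _max_padded_variance(traj.n_spells, length, m)
    phi = count_distinct_subsequences(traj.states)
    t_star = _log2_turbulence(phi, s2, s2max)

    t_max = _log2_phi_reference(length, a) if a > 1 else 1.0
    if t_max <= 1.0:
        return t_star, 0.0
    return t_star, (t_star - 1.0) / (t_max - 1.0)


def integration_index(traj: Trajectory, spell_index: int = 0, z: float = 1.0) -> float:
    """Integrative potential of one spell: position-weighted share of the
    trajectory it occupies, ``sum_{t in spell} t^z / sum_{t=1..l} t^z``.

    Later days weigh more (for ``z > 0``), so a spell at the end of the
    trajectory integrates more than an equally long spell at the start.
    """
    if not 0 <= spell_index < traj.n_spells:
        raise ValueError("spell_index out of range")
    start = 1 + sum(sp.duration for sp in traj.spells[:spell_index])
    end = start + traj.spells[spell_index].duration  # exclusive
    t = np.arange(1, traj.length + 1, dtype=float)
    w = t**z
    return float(w[start - 1 : end - 1].sum() / w.sum())


def degradation_index(traj: Trajectory) -> float:
    """(worsening − improving transitions) / all transitions, in [−1, 1].

    A transition worsens if severity rises, improves if it falls; equal-
    severity (lateral) moves count only in the denominator.  Improvement
    pushes the index negative; −1 means every transition was a recovery.
    Trajectories without transitions score 0.
    """
    states = traj.states
    n_trans = len(states) - 1
    if n_trans == 0:
        return 0.0
    worsening = improving = 0
    for i, j in zip(states, states[1:]):
        si, sj = severity(i), severity(j)
        if sj > si:
            worsening += 1
        elif sj < si:
            improving += 1
    return (worsening - improving) / n_trans


def complexity_index(traj: Trajectory, a: int, level: str = "day") -> float:
    """``c(x) = sqrt( (q/(l-1)) * H_norm )`` in [0, 1].

    ``q = n_spells - 1`` is the number of transitions and ``l - 1`` the
    number of day-to-day steps, so ``q/(l-1)`` is the proportion of steps at
    which the state changes; multiplying the normalized entropy by it
    penalizes diversity that never actually transitions.  Defined as 0 for
    one-day trajectories.
    """
    length = traj.length
    if length <= 1:
        return 0.0
    q = traj.n_spells - 1
    return math.sqrt((q / (length - 1)) * entropy_norm(traj, a, level=level))


def insecurity_index(traj: Trajectory, a: int, z: float = 1.0, level: str = "day") -> float:
    """``I_insec = pi(x_1) * I_integr(first spell) + I_degrad + c``.

    ``pi(x_1)`` is the severity of the initial state rescaled to [0, 1]
    (number of disabilities / 9), so the first term reads the initial
    transition as a fall from the fully able state.  Mostly lands in [0, 1]
    but is unbounded: strongly improving trajectories go negative and
    severe, degrading ones can exceed 1.
    """
    first = severity_norm(traj.states[0]) * integration_index(traj, 0, z=z)
    return first + degradation_index(traj) + complexity_index(traj, a, level=level)


def indicator_row(traj: Trajectory, a: int, level: str = "day") -> dict:
    """Every indicator for one trajectory, as a plain dict."""
    row = basic_indicators(traj)
    row["spell_dur_mean"], row["spell_dur_sd"] = spell_duration_stats(traj)
    row["spell_dur_mean_star"], row["spell_dur_sd_star"] = spell_duration_stats(
        traj, a=a, include_unvisited=True
    )
    h_norm = entropy_norm(traj, a, level=level)
    row["entropy"] = h_norm * (math.log(a) if a > 1 else 1.0)
    row["entropy_norm"] = h_norm
    phi = count_distinct_subsequences(traj.states)
    row["phi"] = float(phi)
    row["turbulence"], row["turbulence_norm"] = turbulence(traj, a)
    row["integration"] = integration_index(traj, 0)
    row["degradation"] = degradation_index(traj)
    row["complexity"] = complexity_index(traj, a, level=level)
    row["insecurity"] = insecurity_index(traj, a, level=level)
    return row


def indicators_frame(pool: SequencePool, level: str = "day") -> pd.DataFrame:
    """One row per trajectory (id, weight, all indicators)."""
    rows = []
    for traj in pool:
        row = {"id": traj.id, "weight": traj.weight}
        row.update(indicator_row(traj, pool.a, level=level))
        rows.append(row)
    return pd.DataFrame(rows, columns=["id", "weight", *INDICATOR_COLUMNS])


def weighted_quantile(values, weights, q: float) -> float:
    """Weighted quantile by lower cumulative-weight interpolation: the first
    sorted value whose cumulative weight reaches ``q`` times the total."""
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if values.size == 0:
        raise ValueError("empty value list")
    if not 0.0 <= q <= 1.0:
        raise ValueError("q must be in [0, 1]")
    order = np.argsort(values, kind="mergesort")
    v, w = values[order], weights[order]
    cw = np.cumsum(w)
    idx = int(np.searchsorted(cw, q * cw[-1], side="left"))
    return float(v[min(idx, v.size - 1)])


def indicator_table(pool: SequencePool, level: str = "day") -> pd.DataFrame:
    """Weighted Min/Q1/Median/Mean/Q3/Max summary of every indicator."""
    if len(pool) == 0:
        raise ValueError("empty pool")
    frame = indicators_frame(pool, level=level)
    w = frame["weight"].to_numpy(dtype=float)
    out: dict[str, list[float]] = {}
    for col in INDICATOR_COLUMNS:
        v = frame[col].to_numpy(dtype=float)
        out[col] = [
            float(v.min()),
            weighted_quantile(v, w, 0.25),
            weighted_quantile(v, w, 0.50),
            float(np.average(v, weights=w)),
            weighted_quantile(v, w, 0.75),
            float(v.max()),
        ]
    return pd.DataFrame(out, index=["Min", "Q1", "Median", "Mean", "Q3", "Max"])
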