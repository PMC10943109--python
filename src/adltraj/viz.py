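"""Structural renderings of the five descriptive plot types.

Every plot writes a tidy JSON payload next to the image; the payload holds
exactly the numbers the analytics modules produced (series, labels and the
palette index per state), so the figures are reproducible and the payload —
not the pixels — is the contract.
"""

from __future__ import annotations

import json
from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .aggregates import mean_time_per_state, most_frequent, sample_index, state_distribution
from .sequences import SequencePool
from .states import state_name
from .transitions import TransitionMatrix

__all__ = [
    "palette_for",
    "plot_index",
    "plot_state_distribution",
    "plot_frequency",
    "plot_mean_time",
    "plot_bubble",
]

# fixed 25-color palette keyed by alphabet index, so legends are reproducible
_PALETTE = [plt.get_cmap("tab20")(i / 19) for i in range(20)] + [
    plt.get_cmap("tab20b")(i / 19) for i in (0, 4, 8, 12, 16)
]


def palette_for(alphabet: list[int]) -> dict[int, tuple]:
    """State code -> RGBA color, by alphabet index (cycled past 25 states)."""
    return {s: _PALETTE[i % len(_PALETTE)] for i, s in enumerate(alphabet)}


def _save(fig, payload: dict, out: Path) -> dict:
    out = Path(out)
    out.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(out, dpi=120, bbox_inches="tight")
    plt.close(fig)
    with open(out.with_suffix(".json"), "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=1)
    return payload


def plot_index(pool: SequencePool, out, n: int = 250) -> dict:
    """Index plot: each sampled weighted trajectory as one horizontal lane."""
    sample = sample_index(pool, n=n)
    colors = palette_for(pool.alphabet)
    fig, ax = plt.subplots(figsize=(9, 6))
    payload_rows = []
    for lane, traj in enumerate(sample):
        start = 0
        for sp in traj.spells:
            ax.barh(lane, sp.duration, left=start, height=1.0,
                    color=colors[sp.state], linewidth=0)
            start += sp.duration
        payload_rows.append(
            {"id": traj.id, "weight": traj.weight,
             "spells": [[sp.state, sp.duration] for sp in traj.spells]}
        )
    ax.set_xlabel("day")
    ax.set_ylabel("sampled weighted trajectory")
    ax.set_title(f"Index plot ({len(sample)} sampled trajectories)")
    payload = {
        "kind": "index",
        "alphabet": list(pool.alphabet),
        "palette_index": {str(s): i for i, s in enumerate(pool.alphabet)},
        "trajectories": payload_rows,
    }
    return _save(fig, payload, out)


def plot_state_distribution(pool: SequencePool, out, max_points: int = 400) -> dict:
    """Stacked-area state distribution over follow-up days."""
    max_len = max(t.length for t in pool)
    step = max(1, max_len // max_points)
    grid = np.arange(1, max_len + 1, step)
    dist = state_distribution(pool, grid=grid)
    colors = palette_for(pool.alphabet)
    fig, ax = plt.subplots(figsize=(9, 5))
    ax.stackplot(
        dist.days,
        dist.proportions.T.to_numpy(),
        colors=[colors[s] for s in pool.alphabet],
        labels=[state_name(s) for s in pool.alphabet],
    )
    ax.set_xlabel("day")
    ax.set_ylabel("proportion of observed trajectories")
    ax.set_ylim(0, 1)
    ax.set_title("State distribution")
    ax.legend(fontsize=6, ncol=2, loc="center left", bbox_to_anchor=(1.0, 0.5))
    payload = {
        "kind": "state_distribution",
        "days": dist.days.tolist(),
        "states": [state_name(s) for s in pool.alphabet],
        "proportions": dist.proportions.to_numpy().round(6).tolist(),
        "observed_mass": dist.observed_mass.tolist(),
    }
    return _save(fig, payload, out)


def plot_frequency(pool: SequencePool, out, k: int = 10) -> dict:
    """Top-k most frequent trajectories; bar width proportional to weight."""
    top = most_frequent(pool, k)
    total = pool.total_weight
    colors = palette_for(pool.alphabet)
    fig, ax = plt.subplots(figsize=(9, 5))
    y = 0.0
    payload_rows = []
    for traj in top:
        height = traj.weight / total
        start = 0
        for sp in traj.spells:
            ax.barh(y + height / 2, sp.duration, left=start, height=height * 0.92,
                    color=colors[sp.state], linewidth=0)
            start += sp.duration
        payload_rows.append(
            {"id": traj.id, "weight": traj.weight, "share": height,
             "spells": [[sp.state, sp.duration] for sp in traj.spells]}
        )
        y += height
    ax.set_xlabel("day")
    ax.set_ylabel("cumulative frequency share")
    ax.set_title(f"{len(top)} most frequent trajectories")
    payload = {"kind": "frequency", "total_weight": total, "trajectories": payload_rows}
    return _save(fig, payload, out)


def plot_mean_time(pool: SequencePool, out) -> dict:
    """Mean days spent per state, bars in descending order."""
    means = mean_time_per_state(pool)
    colors = palette_for(pool.alphabet)
    fig, ax = plt.subplots(figsize=(9, 4.5))
    names = [state_name(s) for s in means.index]
    ax.bar(names, means.to_numpy(), color=[colors[s] for s in means.index])
    ax.set_ylabel("mean days per trajectory")
    ax.set_title("Mean time spent in each state")
    ax.tick_params(axis="x", rotation=75, labelsize=7)
    payload = {
        "kind": "mean_time",
        "states": names,
        "mean_days": means.round(6).to_numpy().tolist(),
    }
    return _save(fig, payload, out)


def plot_bubble(matrix: TransitionMatrix, out) -> dict:
    """Transition-rate bubble plot, diagonal excluded.

    Vertical axis: preceding state; horizontal: destination.  Bubble area
    and color are proportional to the rate.
    """
    nd = matrix.without_diagonal()
    rates = nd.rates
    names = [state_name(s) for s in nd.alphabet]
    a = len(names)
    fig, ax = plt.subplots(figsize=(7.5, 7))
    ii, jj = np.nonzero(rates)
    vals = rates[ii, jj]
    ax.scatter(jj, ii, s=2000 * vals, c=vals, cmap="Blues", alpha=0.85,
               edgecolors="grey", linewidths=0.3)
    ax.set_xticks(range(a), names, rotation=90, fontsize=6)
    ax.set_yticks(range(a), names, fontsize=6)
    ax.invert_yaxis()
    ax.set_xlabel("destination state")
    ax.set_ylabel("preceding state")
    ax.set_title("Transition rates (diagonal excluded)")
    payload = {
        "kind": "bubble",
        "states": names,
        "transitions": [
            {"from": names[i], "to": names[j], "rate": float(rates[i, j])}
            for i, j in zip(ii.tolist(), jj.tolist())
        ],
    }
    return _save(fig, payload, out)
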