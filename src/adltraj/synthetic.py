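"""Synthetic nursing-home cohorts with the statistical structure the
analysis assumes.

The generator emulates a long-running cohort of residents assessed on nine
binary ADLs at roughly quarterly intervals: each resident starts from a
severity prior concentrated on few or no disabilities, and at every
assessment epoch their state either persists or changes by flipping a single
ADL.  The direction of each change (recovery vs onset) follows severity-
dependent probabilities that are *solved at configuration time* so that the
long-run share of realized recoveries matches a target (0.45 by default) —
more severe residents are more likely to recover, residents with no
disability can only decline.  Follow-up ends by a per-assessment censoring
hazard or at the horizon.  The emitted table also plants single-assessment
residents, invalid-age residents and terminal death records so downstream
exclusion logic is exercised; the planted counts are reported alongside the
gold-standard trajectories.

A second generator simulates spell sequences directly from a given
spell-level transition matrix with geometric spell durations, serving as a
parameter-recovery oracle for transition-rate estimation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from . import sequences
from .sequences import SequencePool, Trajectory, aggregate_weighted
from .states import ADL_ORDER, BIT_WEIGHTS
from .transitions import TransitionMatrix, recovery_fraction, transition_rates

__all__ = [
    "SyntheticConfig",
    "GoldStandard",
    "generate_cohort",
    "generate_from_matrix",
    "solve_recovery_probabilities",
]

#: Relative onset propensity per ADL letter: disabilities in bathing,
#: walking and grooming appear first most often, concentrating the state
#: mass on a small set of predominant combinations.
DEFAULT_ONSET_PROPENSITY: dict[str, float] = {
    "B": 5.0, "W": 4.0, "G": 3.0, "D": 1.5, "T": 1.2,
    "L": 1.0, "U": 1.0, "S": 0.8, "F": 0.6,
}


@dataclass
class SyntheticConfig:
    """Knobs of the cohort generator; defaults emulate the study setting."""

    n_residents: int = 1000
    seed: int = 0
    horizon_days: int = 5331  # longest follow-up, days
    interval_mean: int = 84  # quarterly-ish assessment cadence, days
    interval_jitter: int = 7  # assessments fall in [mean-jitter, mean+jitter]
    p_change: float = 0.2  # per-epoch probability the state changes
    recovery_share: float = 0.45  # target share of recoveries among changes
    single_change_only: bool = True  # one ADL flips per change
    alphabet_limit: int = 25  # predominant states kept downstream
    hazard: float = 0.08  # per-assessment probability follow-up ends
    p_severity_zero: float = 0.5  # initial mass on zero disabilities
    severity_decay: float = 0.55  # geometric decay of initial severity 1..9
    single_assessment_frac: float = 0.03  # planted single-assessment residents
    invalid_age_frac: float = 0.01  # planted invalid-age residents
    death_record_frac: float = 0.05  # residents whose last record is a death record

    def __post_init__(self) -> None:
        for name in ("p_change", "recovery_share", "hazard", "p_severity_zero",
                     "single_assessment_frac", "invalid_age_frac", "death_record_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.horizon_days < 2:
            raise ValueError("horizon_days must be >= 2")
        if self.interval_mean < 1 or self.interval_jitter < 0:
            raise ValueError("assessment interval must be >= 1 day")
        if self.interval_jitter >= self.interval_mean:
            raise ValueError("interval_jitter must be below interval_mean")

    def initial_severity_prior(self) -> np.ndarray:
        """P(initial severity = s), s = 0..9: mass ``p_severity_zero`` at 0,
        geometric decay over 1..9."""
        tail = self.severity_decay ** np.arange(1, 10)
        tail = (1.0 - self.p_severity_zero) * tail / tail.sum()
        return np.concatenate([[self.p_severity_zero], tail])

    def max_epochs(self) -> int:
        return max(2, self.horizon_days // self.interval_mean)


@dataclass
class GoldStandard:
    """Ground truth emitted alongside a synthetic assessment table."""

    trajectories: list[Trajectory]
    pool: SequencePool
    matrix: TransitionMatrix  # spell-level matrix realized by the gold pool
    recovery_probabilities: np.ndarray  # q(s), s = 0..9, solved at config time
    realized_recovery_share: float
    n_single_assessment: int
    n_invalid_age: int
    n_death_records: int


def _expected_recovery_share(q: np.ndarray, config: SyntheticConfig) -> float:
    """Expected recovery share under the epoch model.

    Propagates the severity distribution across assessment epochs, weighting
    epoch ``i`` by the survival probability ``(1-h)^(i-1)`` (every retained
    resident has at least two assessments, so the first step always
    happens), and accumulates expected up/down moves.  The per-epoch change
    probability cancels from the ratio only partially (it shapes the
    severity distribution), so it is modelled explicitly.
    """
    prior = config.initial_severity_prior()
    pi = prior.copy()
    p = config.p_change
    h = config.hazard
    num = den = 0.0
    for step in range(1, config.max_epochs()):
        w = (1.0 - h) ** (step - 1)
        down = p * (pi * q).sum()
        up = p * (pi * (1.0 - q)).sum()
        num += w * down
        den += w * (down + up)
        nxt = pi.copy()
        nxt -= p * pi  # mass that moves
        nxt[:-1] += p * pi[1:] * q[1:]
        nxt[1:] += p * pi[:-1] * (1.0 - q[:-1])
        pi = nxt
    if den == 0.0:
        return 0.0
    return num / den


def solve_recovery_probabilities(config: SyntheticConfig) -> np.ndarray:
    """Severity-dependent recovery probabilities hitting the target share.

    ``q(s; theta) = min(1, theta * s/9)`` for 1 <= s <= 8, with the forced
    boundaries q(0) = 0 (nothing to recover) and q(9) = 1 (nothing to lose):
    more severe states recover with higher probability.  The scalar theta is
    found by root-finding on the expected realized recovery share of the
    epoch model, so the generator needs no rejection sampling at run time.
    """
    s = np.arange(10)

    def q_of(theta: float) -> np.ndarray:
        q = np.clip(theta * s / 9.0, 0.0, 1.0)
        q[0] = 0.0
        q[9] = 1.0
        return q

    def f(theta: float) -> float:
        return _expected_recovery_share(q_of(theta), config) - config.recovery_share

    if config.p_change == 0.0:
        if config.recovery_share == 0.0:
            return q_of(0.0)  # no changes happen; the target is vacuous
        raise ValueError(
            "recovery_share target infeasible: no state changes occur with p_change=0"
        )
    lo, hi = 1e-9, 9.0
    f_lo, f_hi = f(lo), f(hi)
    if not (f_lo < 0.0 < f_hi):
        raise ValueError(
            "recovery_share target infeasible under this configuration "
            f"(attainable range ~[{f_lo + config.recovery_share:.3f}, "
            f"{f_hi + config.recovery_share:.3f}])"
        )
    theta = brentq(f, lo, hi, xtol=1e-10)
    return q_of(theta)


_LETTER_IDX = {ch: i for i, ch in enumerate(ADL_ORDER)}
_WEIGHTS_ARR = np.array([BIT_WEIGHTS[ch] for ch in ADL_ORDER])
_ONSET_ARR = np.array([DEFAULT_ONSET_PROPENSITY[ch] for ch in ADL_ORDER])


def _flags_to_code(flags: np.ndarray) -> int:
    return int((flags * _WEIGHTS_ARR).sum())


def generate_cohort(
    config: SyntheticConfig,
) -> tuple[pd.DataFrame, GoldStandard]:
    """Generate an assessment table and its gold standard.

    Returns ``(records, gold)``: ``records`` is the assessment CSV dialect
    (resident_id, assessment_date, the nine flags, age, sex, died) and
    ``gold`` carries the clean trajectories (built by the same persistence
    rule the pipeline uses), the realized spell-level transition matrix, the
    solved recovery probabilities and the planted exclusion counts.  Output
    is a deterministic function of the seed.
    """
    rng = np.random.default_rng(config.seed)
    q = solve_recovery_probabilities(config)
    prior = config.initial_severity_prior()
    e_max = config.max_epochs()

    n = config.n_residents
    order = rng.permutation(n)
    n_single = int(round(config.single_assessment_frac * n))
    n_invalid = int(round(config.invalid_age_frac * n))
    single_ids = set(order[:n_single].tolist())
    invalid_ids = set(order[n_single : n_single + n_invalid].tolist())

    base_date = np.datetime64("2000-01-01")
    rows: list[tuple] = []
    death_candidates: list[int] = []
    n_assessments: dict[int, int] = {}
    for r in range(n):
        sev0 = int(rng.choice(10, p=prior))
        flags = np.zeros(9, dtype=np.int64)
        if sev0 > 0:
            onset_p = _ONSET_ARR / _ONSET_ARR.sum()
            chosen = rng.choice(9, size=sev0, replace=False, p=onset_p)
            flags[chosen] = 1

        if r in single_ids:
            k = 1
        else:
            k = 2
            while k < e_max and rng.random() < 1.0 - config.hazard:
                k += 1
        n_assessments[r] = k

        age = float(np.clip(rng.normal(71.07, 12.26), 40.0, 100.0))
        if r in invalid_ids:
            age = 150.0
        sex = "M" if rng.random() < 0.969 else "F"

        day = int(rng.integers(0, 366))
        for epoch in range(k):
            rows.append(
                (
                    f"R{r:06d}",
                    base_date + np.timedelta64(day, "D"),
                    *flags.tolist(),
                    age,
                    sex,
                    0,
                )
            )
            if epoch == k - 1:
                break
            day += int(
                rng.integers(
                    config.interval_mean - config.interval_jitter,
                    config.interval_mean + config.interval_jitter + 1,
                )
            )
            if rng.random() < config.p_change:
                sev = int(flags.sum())
                recover = rng.random() < q[sev]
                n_flips = 1
                if not config.single_change_only and rng.random() < 0.2:
                    n_flips = 2
                for _ in range(n_flips):
                    sev = int(flags.sum())
                    if recover and sev > 0:
                        set_idx = np.flatnonzero(flags == 1)
                        flags[rng.choice(set_idx)] = 0
                    elif not recover and sev < 9:
                        unset_idx = np.flatnonzero(flags == 0)
                        p_on = _ONSET_ARR[unset_idx] / _ONSET_ARR[unset_idx].sum()
                        flags[rng.choice(unset_idx, p=p_on)] = 1
        if k >= 3 and r not in invalid_ids:
            death_candidates.append(r)

    records = pd.DataFrame(
        rows,
        columns=["resident_id", "assessment_date", *ADL_ORDER, "age", "sex", "died"],
    )

    n_death = int(round(config.death_record_frac * n))
    death_ids = death_candidates[:n_death] if n_death else []
    # mark the last record of each chosen resident as a death record; chosen
    # residents keep >= 2 non-death assessments so no extra exclusions cascade
    for r in death_ids:
        rid = f"R{r:06d}"
        idx = records.index[records["resident_id"] == rid][-1]
        records.loc[idx, "died"] = 1

    gold_trajs, _ = sequences.build_trajectories(records)
    pool = aggregate_weighted(gold_trajs)
    matrix = transition_rates(pool, mode="spell")
    try:
        share = recovery_fraction(pool)
    except ValueError:  # no transitions realized (p_change = 0)
        share = float("nan")
    gold = GoldStandard(
        trajectories=gold_trajs,
        pool=pool,
        matrix=matrix,
        recovery_probabilities=q,
        realized_recovery_share=share,
        n_single_assessment=len(single_ids),
        n_invalid_age=len(invalid_ids),
        n_death_records=len(death_ids),
    )
    return records, gold


def generate_from_matrix(
    matrix: TransitionMatrix,
    n: int,
    seed: int,
    duration_mean: float = 84.0,
    n_spells: int = 12,
) -> SequencePool:
    """Simulate a pool of spell sequences from a spell-level matrix.

    Initial states are uniform over the alphabet; successive states follow
    the matrix rows; spell durations are geometric with the given mean (in
    days).  Sequences stop after ``n_spells`` spells or upon entering an
    absorbing state.  Serves as the parameter-recovery oracle for
    :func:`adltraj.transitions.transition_rates`.
    """
    if n < 1 or n_spells < 1:
        raise ValueError("n and n_spells must be >= 1")
    if duration_mean < 1.0:
        raise ValueError("duration_mean must be >= 1 day")
    rates = matrix.rates
    absorbing = matrix.absorbing
    if not absorbing.any():
        row_sums = matrix.counts.sum(axis=1)
        if not np.allclose(rates.sum(axis=1), 1.0, atol=1e-9) or (row_sums < 0).any():
            raise ValueError("matrix rows must be stochastic")
    rng = np.random.default_rng(seed)
    a = len(matrix.alphabet)
    p_stop = 1.0 / duration_mean
    trajectories = []
    for i in range(n):
        state_idx = int(rng.integers(a))
        pairs = []
        for _ in range(n_spells):
            duration = int(rng.geometric(p_stop))
            pairs.append((matrix.alphabet[state_idx], duration))
            if absorbing[state_idx]:
                break
            state_idx = int(rng.choice(a, p=rates[state_idx]))
        trajectories.append(
            Trajectory.from_pairs(pairs, id=f"S{i:06d}", merge_adjacent=False)
        )
    return SequencePool(trajectories, list(matrix.alphabet), {"source": "matrix-sim"})
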