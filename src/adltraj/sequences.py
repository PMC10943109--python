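"""Spell-format trajectories: parsing, construction from assessment records,
alphabet selection and weighted aggregation.

A *spell* is a maximal run of consecutive days in one unchanged disability
state; a *trajectory* is the ordered list of a resident's spells, written in
the text form ``"(code,duration)-(code,duration)-..."``.  Identical
trajectories are collapsed into weighted records so that large cohorts can be
analysed without redundancy; the weight of a merged record is the number (or
summed weight) of the trajectories it represents.

Durations are integer days, 1-based, closed on the left: the day of an
assessment belongs to the state it reports, and the final assessment closes
the observation window, so the total length of a trajectory equals the span
in days between its first and last assessment.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .states import ADL_ORDER, ADL_FUNCTIONS, N_STATES, _check_code

__all__ = [
    "Spell",
    "Trajectory",
    "SequencePool",
    "ExclusionReport",
    "SpellParseError",
    "parse_spell_string",
    "format_spell_string",
    "build_trajectories",
    "select_alphabet",
    "restrict_to_alphabet",
    "aggregate_weighted",
    "expand_daily",
    "run_length_encode",
    "read_assessments",
    "write_assessments",
    "read_trajectories",
    "write_trajectories",
]

logger = logging.getLogger(__name__)

#: Assessment CSV columns holding the nine 0/1 ADL flags, in display order.
FLAG_COLUMNS: tuple[str, ...] = ADL_ORDER


@dataclass(frozen=True)
class Spell:
    """A maximal run of ``duration`` days in one ``state``."""

    state: int
    duration: int

    def __post_init__(self) -> None:
        _check_code(self.state)
        if self.duration < 1:
            raise ValueError(f"spell duration must be >= 1 day, got {self.duration}")


@dataclass(frozen=True)
class Trajectory:
    """An identified, weighted sequence of spells.

    Adjacent spells always hold different states (spells are maximal runs);
    construction enforces this.
    """

    id: str
    spells: tuple[Spell, ...]
    weight: float = 1.0

    def __post_init__(self) -> None:
        if not self.spells:
            raise ValueError("a trajectory must contain at least one spell")
        if self.weight <= 0:
            raise ValueError("trajectory weight must be positive")
        for a, b in zip(self.spells, self.spells[1:]):
            if a.state == b.state:
                raise ValueError(
                    "adjacent spells share a state; merge them before construction"
                )

    @classmethod
    def from_pairs(
        cls,
        pairs,
        id: str = "",
        weight: float = 1.0,
        merge_adjacent: bool = True,
    ) -> "Trajectory":
        """Build a trajectory from ``(state, duration)`` pairs.

        With ``merge_adjacent`` (default), runs of equal states are merged
        into single spells with a warning; otherwise they raise.
        """
        merged: list[list[int]] = []
        for state, duration in pairs:
            if merged and merged[-1][0] == state:
                if not merge_adjacent:
                    raise ValueError(f"adjacent spells share state {state}")
                warnings.warn(
                    f"merged adjacent equal-state spells (state {state})",
                    stacklevel=2,
                )
                merged[-1][1] += int(duration)
            else:
                merged.append([int(state), int(duration)])
        return cls(id=id, spells=tuple(Spell(s, d) for s, d in merged), weight=weight)

    @property
    def length(self) -> int:
        """Total length in days (sum of spell durations)."""
        return sum(sp.duration for sp in self.spells)

    @property
    def n_spells(self) -> int:
        return len(self.spells)

    @property
    def states(self) -> tuple[int, ...]:
        """The distinct-successive-states (DSS) sequence: states with durations stripped."""
        return tuple(sp.state for sp in self.spells)

    @property
    def durations(self) -> tuple[int, ...]:
        return tuple(sp.duration for sp in self.spells)

    @property
    def visited(self) -> frozenset[int]:
        return frozenset(self.states)


@dataclass
class SequencePool:
    """A weighted collection of trajectories plus the alphabet in force.

    The *alphabet* is the ordered list of admitted state codes; its size is
    the ``a`` that normalizes entropy and pads spell-duration statistics.
    """

    trajectories: list[Trajectory]
    alphabet: list[int]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        allowed = set(self.alphabet)
        if len(self.alphabet) != len(allowed):
            raise ValueError("alphabet contains duplicate states")
        for traj in self.trajectories:
            extra = traj.visited - allowed
            if extra:
                raise ValueError(
                    f"trajectory {traj.id!r} uses states outside the alphabet: {sorted(extra)}"
                )

    @property
    def a(self) -> int:
        return len(self.alphabet)

    @property
    def total_weight(self) -> float:
        return float(sum(t.weight for t in self.trajectories))

    def __len__(self) -> int:
        return len(self.trajectories)

    def __iter__(self):
        return iter(self.trajectories)


class SpellParseError(ValueError):
    """Malformed spell string; carries the character position of the fault."""

    def __init__(self, message: str, position: int) -> None:
        super().__init__(f"{message} (at position {position})")
        self.position = position


_SPELL_RE = re.compile(r"\(\s*(\d+)\s*,\s*(-?\d+)\s*\)")


def parse_spell_string(
    text: str,
    id: str = "",
    weight: float = 1.0,
    merge_adjacent: bool = True,
) -> Trajectory:
    """Parse ``"(code,duration)-(code,duration)-..."`` into a :class:`Trajectory`.

    Whitespace around tokens is tolerated.  Durations below 1 day and codes
    outside [0, 511] are rejected; adjacent equal states are merged with a
    warning (or rejected with ``merge_adjacent=False``).
    """
    pos = 0
    n = len(text)
    pairs: list[tuple[int, int]] = []
    expecting_spell = True
    while pos < n:
        if text[pos].isspace():
            pos += 1
            continue
        if expecting_spell:
            m = _SPELL_RE.match(text, pos)
            if not m:
                raise SpellParseError("expected '(code,duration)'", pos)
            code, duration = int(m.group(1)), int(m.group(2))
            if not 0 <= code < N_STATES:
                raise SpellParseError(f"state code {code} out of range", pos)
            if duration < 1:
                raise SpellParseError(f"duration {duration} below 1 day", pos)
            pairs.append((code, duration))
            pos = m.end()
            expecting_spell = False
        else:
            if text[pos] != "-":
                raise SpellParseError("expected '-' between spells", pos)
            pos += 1
            expecting_spell = True
    if expecting_spell:
        raise SpellParseError("dangling separator or empty spell string", pos)
    return Trajectory.from_pairs(pairs, id=id, weight=weight, merge_adjacent=merge_adjacent)


def format_spell_string(traj: Trajectory) -> str:
    """Serialize a trajectory; round-trips with :func:`parse_spell_string`."""
    return "-".join(f"({sp.state},{sp.duration})" for sp in traj.spells)


@dataclass
class ExclusionReport:
    """Record counts at each cleaning step of :func:`build_trajectories`."""

    n_records_in: int = 0
    n_invalid_age_records: int = 0
    n_invalid_age_residents: int = 0
    n_death_records: int = 0
    n_duplicate_records: int = 0
    n_single_assessment_residents: int = 0
    n_records_kept: int = 0
    n_residents_kept: int = 0


def _encode_flags(df: pd.DataFrame) -> np.ndarray:
    from .states import BIT_WEIGHTS

    codes = np.zeros(len(df), dtype=np.int64)
    for letter in FLAG_COLUMNS:
        codes += df[letter].to_numpy(dtype=np.int64) * BIT_WEIGHTS[letter]
    return codes


def build_trajectories(
    records: pd.DataFrame,
    valid_age: tuple[float, float] = (0.0, 120.0),
    duplicate_policy: str = "keep-last",
) -> tuple[list[Trajectory], ExclusionReport]:
    """Turn long-format assessment records into spell trajectories.

    ``records`` needs columns ``resident_id``, ``assessment_date`` and the
    nine 0/1 flag columns F,S,G,T,B,W,D,L,U; ``age`` and ``died`` are
    optional.  Cleaning applies, in order: residents with an invalid age are
    dropped, death records (``died == 1``) are dropped, duplicate
    ``(resident, date)`` rows are resolved per ``duplicate_policy``
    (``keep-last`` default, ``keep-first``, or ``error``), and residents left
    with fewer than two assessments are dropped.

    Each assessment's state persists day by day until the next assessment;
    the last assessment closes the observation window, so trajectory length
    equals the day span between first and last kept assessment.
    """
    report = ExclusionReport(n_records_in=len(records))
    df = records.copy()
    df["assessment_date"] = pd.to_datetime(df["assessment_date"])

    if "age" in df.columns:
        age = pd.to_numeric(df["age"], errors="coerce")
        bad = age.notna() & ((age < valid_age[0]) | (age > valid_age[1]))
        bad_residents = set(df.loc[bad, "resident_id"])
        mask = df["resident_id"].isin(bad_residents)
        report.n_invalid_age_records = int(mask.sum())
        report.n_invalid_age_residents = len(bad_residents)
        if bad_residents:
            logger.info("dropping %d invalid-age residents (%d records)",
                        len(bad_residents), report.n_invalid_age_records)
        df = df[~mask]

    if "died" in df.columns:
        death = df["died"].fillna(0).astype(int) == 1
        report.n_death_records = int(death.sum())
        if report.n_death_records:
            logger.info("dropping %d death records", report.n_death_records)
        df = df[~death]

    df = df.sort_values(["resident_id", "assessment_date"], kind="mergesort")
    dup = df.duplicated(["resident_id", "assessment_date"], keep=False)
    report.n_duplicate_records = int(
        df.duplicated(["resident_id", "assessment_date"]).sum()
    )
    if dup.any():
        if duplicate_policy == "error":
            raise ValueError("duplicate (resident, date) assessment records")
        keep = "last" if duplicate_policy == "keep-last" else "first"
        surplus = df.duplicated(["resident_id", "assessment_date"], keep=keep)
        logger.info("resolving %d duplicate records (%s)", int(surplus.sum()), keep)
        df = df[~surplus]

    df = df.copy()
    df["state"] = _encode_flags(df)

    trajectories: list[Trajectory] = []
    n_single = 0
    for resident, group in df.groupby("resident_id", sort=True):
        if len(group) < 2:
            n_single += 1
            continue
        dates = group["assessment_date"].to_numpy()
        states = group["state"].to_numpy()
        durations = np.diff(dates).astype("timedelta64[D]").astype(int)
        if (durations < 1).any():
            raise ValueError(
                f"non-increasing assessment dates for resident {resident!r}"
            )
        # The final assessment closes the window and contributes no days of
        # its own state; intervals carry the state at their left endpoint.
        pairs = [(int(s), int(d)) for s, d in zip(states[:-1], durations)]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # silent merge of unchanged states
            trajectories.append(
                Trajectory.from_pairs(pairs, id=str(resident), weight=1.0)
            )
        report.n_records_kept += len(group)

    report.n_single_assessment_residents = n_single
    report.n_residents_kept = len(trajectories)
    logger.info("built %d trajectories (%d single-assessment residents dropped)",
                len(trajectories), n_single)
    return trajectories, report


def select_alphabet(
    trajectories: list[Trajectory],
    k: int,
    rank_by: str = "spells",
) -> tuple[list[int], float]:
    """Pick the ``k`` predominant states and report their coverage.

    States are ranked by weighted spell occurrences (``rank_by="spells"``, a
    "case" being one spell) or by weighted person-days (``rank_by="days"``).
    Returns ``(alphabet, coverage)`` where coverage is the kept share of the
    ranking mass.  Ties break toward the lower state code.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if rank_by not in ("spells", "days"):
        raise ValueError("rank_by must be 'spells' or 'days'")
    mass: dict[int, float] = {}
    for traj in trajectories:
        for sp in traj.spells:
            amount = traj.weight if rank_by == "spells" else traj.weight * sp.duration
            mass[sp.state] = mass.get(sp.state, 0.0) + amount
    if not mass:
        raise ValueError("no trajectories supplied")
    if k > len(mass):
        warnings.warn(
            f"k={k} exceeds the {len(mass)} distinct states; keeping all",
            stacklevel=2,
        )
        k = len(mass)
    ranked = sorted(mass, key=lambda s: (-mass[s], s))
    alphabet = ranked[:k]
    total = sum(mass.values())
    coverage = sum(mass[s] for s in alphabet) / total
    return alphabet, coverage


def restrict_to_alphabet(
    trajectories: list[Trajectory],
    alphabet: list[int],
    policy: str = "drop-sequence",
) -> list[Trajectory]:
    """Restrict trajectories to an alphabet.

    ``drop-sequence`` (default) removes any trajectory containing a state
    outside the alphabet; ``drop-spell`` deletes the offending spells and
    re-merges the remainder (trajectories left empty are removed).
    """
    allowed = set(alphabet)
    out: list[Trajectory] = []
    for traj in trajectories:
        if traj.visited <= allowed:
            out.append(traj)
            continue
        if policy == "drop-sequence":
            continue
        if policy != "drop-spell":
            raise ValueError("policy must be 'drop-sequence' or 'drop-spell'")
        pairs = [(sp.state, sp.duration) for sp in traj.spells if sp.state in allowed]
        if not pairs:
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out.append(Trajectory.from_pairs(pairs, id=traj.id, weight=traj.weight))
    return out


def aggregate_weighted(
    trajectories: list[Trajectory],
    alphabet: list[int] | None = None,
    meta: dict | None = None,
) -> SequencePool:
    """Collapse identical spell lists into weighted records.

    Total weight is conserved; the merged record keeps the first
    contributing id.  The pool's alphabet defaults to the distinct states
    present, sorted by code.
    """
    merged: dict[tuple[tuple[int, int], ...], Trajectory] = {}
    for traj in trajectories:
        key = tuple((sp.state, sp.duration) for sp in traj.spells)
        if key in merged:
            prev = merged[key]
            merged[key] = Trajectory(prev.id, prev.spells, prev.weight + traj.weight)
        else:
            merged[key] = traj
    pooled = list(merged.values())
    if alphabet is None:
        alphabet = sorted({s for t in pooled for s in t.states})
    return SequencePool(pooled, list(alphabet), dict(meta or {}))


def expand_daily(traj: Trajectory) -> np.ndarray:
    """Day-indexed state vector: entry ``t-1`` is the state on day ``t``."""
    return np.repeat(
        np.fromiter((sp.state for sp in traj.spells), dtype=np.int64),
        np.fromiter((sp.duration for sp in traj.spells), dtype=np.int64),
    )


def run_length_encode(days: np.ndarray) -> list[tuple[int, int]]:
    """Inverse of :func:`expand_daily`: ``(state, duration)`` pairs of maximal runs."""
    days = np.asarray(days)
    if days.size == 0:
        return []
    change = np.flatnonzero(np.diff(days)) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [days.size]))
    return [(int(days[s]), int(e - s)) for s, e in zip(starts, ends)]


# --- file formats -----------------------------------------------------------

def read_assessments(path) -> pd.DataFrame:
    """Read the assessment CSV dialect (resident_id, assessment_date, F..U, ...)."""
    df = pd.read_csv(path)
    missing = [c for c in ("resident_id", "assessment_date", *FLAG_COLUMNS)
               if c not in df.columns]
    if missing:
        raise ValueError(f"assessment CSV missing columns: {missing}")
    df["assessment_date"] = pd.to_datetime(df["assessment_date"])
    return df


def write_assessments(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out["assessment_date"] = pd.to_datetime(out["assessment_date"]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)


def read_trajectories(path) -> list[Trajectory]:
    """Read a trajectory file: one ``id TAB weight TAB spell-string`` line each."""
    out: list[Trajectory] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(f"{path}:{lineno}: expected 'id<TAB>weight<TAB>spells'")
            out.append(parse_spell_string(parts[2], id=parts[0], weight=float(parts[1])))
    return out


def write_trajectories(trajectories, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for traj in trajectories:
            weight = traj.weight
            wtxt = str(int(weight)) if float(weight).is_integer() else repr(weight)
            fh.write(f"{traj.id}\t{wtxt}\t{format_spell_string(traj)}\n")
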