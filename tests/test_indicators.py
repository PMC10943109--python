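"""Indicator suite: entropy, subsequence counts, turbulence, insecurity and
the weighted summary table, checked against brute-force oracles."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from adltraj import (
    Trajectory,
    aggregate_weighted,
    basic_indicators,
    complexity_index,
    count_distinct_subsequences,
    degradation_index,
    entropy_norm,
    indicator_row,
    indicator_table,
    indicators_frame,
    insecurity_index,
    integration_index,
    spell_duration_stats,
    turbulence,
    weighted_quantile,
)


def brute_force_phi(dss) -> int:
    """Oracle: enumerate every subsequence as a tuple and count distinct ones."""
    dss = tuple(dss)
    found = set()
    for r in range(len(dss) + 1):
        for idx in itertools.combinations(range(len(dss)), r):
            found.add(tuple(dss[i] for i in idx))
    return len(found)


def dss_strategy(max_len=8, alphabet=4):
    """Adjacent-distinct state sequences (the DSS form)."""
    return st.lists(st.integers(0, alphabet - 1), min_size=0, max_size=max_len).map(
        lambda xs: [x for i, x in enumerate(xs) if i == 0 or x != xs[i - 1]]
    )


def random_trajectory(rng, max_spells=10, alphabet_size=20, max_dur=400) -> Trajectory:
    n = int(rng.integers(1, max_spells + 1))
    states, last = [], -1
    for _ in range(n):
        s = int(rng.choice([x for x in range(alphabet_size) if x != last]))
        states.append(s)
        last = s
    durs = rng.integers(1, max_dur + 1, size=n)
    return Trajectory.from_pairs(list(zip(states, durs)), id="r", merge_adjacent=False)


class TestSubsequenceCount:
    def test_worked_example(self):
        assert count_distinct_subsequences([0, 16, 124]) == 8

    def test_empty_sequence(self):
        assert count_distinct_subsequences([]) == 1

    def test_repeat_pattern(self):
        # {∅, A, B, AA, AB, BA, ABA}
        assert count_distinct_subsequences(["A", "B", "A"]) == 7

    @given(dss_strategy())
    @settings(max_examples=300, derandomize=True)
    def test_dp_equals_enumeration(self, dss):
        assert count_distinct_subsequences(dss) == brute_force_phi(dss)


class TestBasics:
    def test_recurrence_of_alternating_sequence(self, seq_ii):
        row = basic_indicators(seq_ii)
        assert row["n_spells"] == 12
        assert row["n_visited"] == 2
        assert row["recurrence"] == 6

    def test_sequence_i(self, seq_i):
        row = basic_indicators(seq_i)
        assert (row["n_spells"], row["n_visited"]) == (4, 3)
        assert row["recurrence"] == pytest.approx(4 / 3)

    def test_no_repeat_recurrence_is_one(self):
        t = Trajectory.from_pairs([(0, 3), (16, 2), (20, 1)], id="x")
        assert basic_indicators(t)["recurrence"] == 1

    def test_repeat_visit_increases_recurrence(self):
        base = Trajectory.from_pairs([(0, 3), (16, 2)], id="x")
        more = Trajectory.from_pairs([(0, 3), (16, 2), (0, 1)], id="y")
        assert (
            basic_indicators(more)["recurrence"] > basic_indicators(base)["recurrence"]
        )


class TestDurationStats:
    def test_padded_mean_anchor(self):
        t = Trajectory.from_pairs([(0, 2)], id="x")
        mean, _ = spell_duration_stats(t, a=25, include_unvisited=True)
        assert mean == pytest.approx(2 / 25)
        assert round(mean, 2) == 0.08

    def test_padded_sd_anchor(self):
        t = Trajectory.from_pairs([(0, 1), (16, 1)], id="x")
        _, sd = spell_duration_stats(t, a=25, include_unvisited=True)
        assert round(sd, 4) == 0.2713
        # independent recomputation: population sd of (1, 1, 0 x 23)
        data = np.array([1.0, 1.0] + [0.0] * 23)
        assert sd == pytest.approx(data.std())

    def test_unpadded_single_spell(self):
        t = Trajectory.from_pairs([(0, 17)], id="x")
        assert spell_duration_stats(t) == (17.0, 0.0)


class TestEntropy:
    def test_single_state_is_zero(self):
        t = Trajectory.from_pairs([(0, 100)], id="x")
        assert entropy_norm(t, 25) == 0.0

    def test_uniform_occupancy_is_one(self):
        t = Trajectory.from_pairs([(s, 7) for s in range(5)], id="x")
        assert entropy_norm(t, 5) == pytest.approx(1.0)

    def test_sequence_v_value(self, seq_v):
        # direct evaluation: p = (14/440, 426/440), H / ln 25
        p = np.array([14 / 440, 426 / 440])
        expected = float(-(p * np.log(p)).sum() / math.log(25))
        assert entropy_norm(seq_v, 25) == pytest.approx(expected)
        assert round(entropy_norm(seq_v, 25), 4) == 0.0438

    def test_invariant_to_spell_order(self):
        t1 = Trajectory.from_pairs([(0, 10), (16, 30), (20, 5)], id="x")
        t2 = Trajectory.from_pairs([(20, 5), (0, 10), (16, 30)], id="y")
        assert entropy_norm(t1, 25) == pytest.approx(entropy_norm(t2, 25))


class TestTurbulence:
    def test_reference_sequence_normalizes_to_one(self):
        a, length = 4, 11
        alphabet = list(range(a))
        states = [alphabet[i % a] for i in range(length)]
        ref = Trajectory.from_pairs([(s, 1) for s in states], id="ref")
        _, t_n = turbulence(ref, a)
        assert t_n == pytest.approx(1.0)

    def test_single_spell_is_minimal(self):
        t = Trajectory.from_pairs([(0, 440)], id="x")
        t_star, t_n = turbulence(t, 25)
        assert t_star == pytest.approx(1.0)  # phi=2 and the variance bound is attained
        assert t_n == pytest.approx(0.0)

    def test_equal_durations_maximize_over_compositions(self):
        """With states fixed, T* depends on durations only through the padded
        variance; among all compositions of the total length, equal spell
        durations minimize it and hence maximize T*."""
        states = [0, 1, 0, 1]
        total = 12
        best, best_t = None, -np.inf
        for cut in itertools.product(range(1, total), repeat=3):
            durs = [cut[0], cut[1] - cut[0], cut[2] - cut[1], total - cut[2]]
            if min(durs) < 1:
                continue
            t = Trajectory.from_pairs(
                list(zip(states, durs)), id="x", merge_adjacent=False
            )
            t_star, _ = turbulence(t, 4)
            if t_star > best_t:
                best_t, best = t_star, tuple(durs)
        assert best == (3, 3, 3, 3)

    def test_order_matters_for_turbulence_but_not_entropy(self):
        """A witness pair with identical day-level occupancy but different
        spell arrangements: entropy ties, turbulence does not."""
        t1 = Trajectory.from_pairs(
            [(0, 2), (16, 2), (0, 2), (16, 2)], id="x", merge_adjacent=False
        )
        t2 = Trajectory.from_pairs([(0, 4), (16, 4)], id="y")
        assert entropy_norm(t1, 25) == pytest.approx(entropy_norm(t2, 25))
        assert turbulence(t1, 25)[0] != pytest.approx(turbulence(t2, 25)[0])

    def test_bounds_on_random_trajectories(self):
        rng = np.random.default_rng(2024)
        for _ in range(200):
            t = random_trajectory(rng)
            t_star, t_n = turbulence(t, 25)
            assert t_star >= 1.0 - 1e-9
            assert -1e-9 <= t_n <= 1.0 + 1e-9


class TestIntegration:
    def test_whole_trajectory_spell_scores_one(self):
        t = Trajectory.from_pairs([(16, 9)], id="x")
        assert integration_index(t, 0) == pytest.approx(1.0)

    def test_first_spell_of_sequence_v(self, seq_v):
        assert integration_index(seq_v, 0) == pytest.approx(105 / 97020)

    def test_final_spell_beats_equal_initial_spell(self):
        t = Trajectory.from_pairs([(0, 10), (16, 30), (0, 10)], id="x")
        assert integration_index(t, 2) > integration_index(t, 0)


class TestDegradation:
    def test_pure_worsening(self, seq_v):
        assert degradation_index(seq_v) == 1.0

    def test_pure_improvement_by_symmetry(self):
        rev = Trajectory.from_pairs([(511, 426), (0, 14)], id="x")
        assert degradation_index(rev) == -1.0

    def test_lateral_only(self):
        t = Trajectory.from_pairs([(16, 5), (4, 5)], id="x")  # B <-> G, severity 1
        assert degradation_index(t) == 0.0

    def test_no_transitions(self):
        assert degradation_index(Trajectory.from_pairs([(0, 5)], id="x")) == 0.0


class TestComplexityAndInsecurity:
    def test_single_state_complexity_zero(self):
        assert complexity_index(Trajectory.from_pairs([(0, 50)], id="x"), 25) == 0.0

    def test_sequence_v_complexity(self, seq_v):
        expected = math.sqrt((1 / 439) * entropy_norm(seq_v, 25))
        assert complexity_index(seq_v, 25) == pytest.approx(expected)
        assert round(complexity_index(seq_v, 25), 5) == pytest.approx(0.00999)

    def test_daily_alternation_hits_transition_ceiling(self):
        t = Trajectory.from_pairs(
            [(0, 1), (16, 1)] * 3, id="x", merge_adjacent=False
        )
        assert complexity_index(t, 25) == pytest.approx(
            math.sqrt(entropy_norm(t, 25))
        )

    def test_insecurity_of_sequence_v(self, seq_v):
        assert round(insecurity_index(seq_v, 25), 2) == 1.01

    def test_all_healthy_trajectory_scores_zero(self):
        assert insecurity_index(Trajectory.from_pairs([(0, 99)], id="x"), 25) == 0.0

    def test_strict_improvement_goes_negative(self):
        t = Trajectory.from_pairs([(511, 200), (0, 200)], id="x")
        assert insecurity_index(t, 25) < 0.0


class TestIndicatorBounds:
    @given(st.integers(0, 10_000))
    @settings(max_examples=60, derandomize=True)
    def test_randomized_bounds(self, seed):
        rng = np.random.default_rng(seed)
        t = random_trajectory(rng)
        row = indicator_row(t, 25)
        assert 0.0 <= row["entropy_norm"] <= 1.0
        assert -1e-9 <= row["turbulence_norm"] <= 1.0 + 1e-9
        assert -1.0 <= row["degradation"] <= 1.0
        assert 0.0 <= row["complexity"] <= 1.0
        assert 0.0 <= row["integration"] <= 1.0
        assert row["recurrence"] >= 1.0
        assert row["n_visited"] <= row["n_spells"]


class TestSummaryTable:
    def test_single_trajectory_collapses(self):
        pool = aggregate_weighted([Trajectory.from_pairs([(0, 5), (16, 3)], id="x")])
        table = indicator_table(pool)
        for col in table.columns:
            assert table[col].nunique() == 1

    def test_weighted_mean(self):
        pool = aggregate_weighted(
            [
                Trajectory.from_pairs([(0, 10)], id="x", weight=3.0),
                Trajectory.from_pairs([(0, 30)], id="y", weight=1.0),
            ]
        )
        table = indicator_table(pool)
        assert table.loc["Mean", "length"] == pytest.approx((3 * 10 + 30) / 4)

    def test_toy_pool_matches_spreadsheet_recomputation(self, toy_pool):
        """Independent recomputation of the weighted summary: expand each
        weighted row, then take plain min/quantile/mean/max with weights
        handled by cumulative sums."""
        frame = indicators_frame(toy_pool)
        table = indicator_table(toy_pool)
        w = frame["weight"].to_numpy(float)
        for col in ("length", "entropy_norm", "insecurity"):
            v = frame[col].to_numpy(float)
            order = np.argsort(v, kind="mergesort")
            vs, ws = v[order], w[order]
            cw = np.cumsum(ws)
            for label, q in [("Q1", 0.25), ("Median", 0.5), ("Q3", 0.75)]:
                expected = vs[np.searchsorted(cw, q * cw[-1], side="left")]
                assert table.loc[label, col] == pytest.approx(expected)
            assert table.loc["Min", col] == pytest.approx(v.min())
            assert table.loc["Max", col] == pytest.approx(v.max())
            assert table.loc["Mean", col] == pytest.approx((v * w).sum() / w.sum())
        assert (table.loc["Min"] <= table.loc["Q1"]).all()
        assert (table.loc["Q1"] <= table.loc["Median"]).all()
        assert (table.loc["Median"] <= table.loc["Q3"]).all()
        assert (table.loc["Q3"] <= table.loc["Max"]).all()

    def test_empty_pool_rejected(self):
        from adltraj import SequencePool

        with pytest.raises(ValueError):
            indicator_table(SequencePool([], [0]))

    def test_weighted_quantile_edges(self):
        v, w = [1.0, 2.0, 3.0], [1.0, 1.0, 2.0]
        assert weighted_quantile(v, w, 0.0) == 1.0
        assert weighted_quantile(v, w, 1.0) == 3.0
        assert weighted_quantile(v, w, 0.5) == 2.0
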