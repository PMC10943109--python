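"""Shared fixtures: printed reference trajectories and small toy pools."""

import pytest

from adltraj import SequencePool, Trajectory, aggregate_weighted, parse_spell_string

# Reference trajectories as printed in the study's results section.
SEQ_I = "(476,974)-(92,83)-(16,245)-(476,323)"
SEQ_II = (
    "(509,941)-(511,87)-(509,259)-(511,88)-(509,81)-(511,422)-(509,83)"
    "-(511,161)-(509,84)-(511,259)-(509,84)-(511,251)"
)
SEQ_V = "(0,14)-(511,426)"


@pytest.fixture
def seq_i() -> Trajectory:
    return parse_spell_string(SEQ_I, id="130202")


@pytest.fixture
def seq_ii() -> Trajectory:
    return parse_spell_string(SEQ_II, id="53209")


@pytest.fixture
def seq_v() -> Trajectory:
    return parse_spell_string(SEQ_V, id="17793")


@pytest.fixture
def toy_pool() -> SequencePool:
    """Five hand-built trajectories over a 4-state alphabet, mixed weights."""
    trajs = [
        Trajectory.from_pairs([(0, 10), (16, 5)], id="a", weight=3.0),
        Trajectory.from_pairs([(0, 4), (20, 4), (0, 4)], id="b", weight=1.0),
        Trajectory.from_pairs([(16, 7)], id="c", weight=2.0),
        Trajectory.from_pairs([(20, 2), (52, 9)], id="d", weight=1.0),
        Trajectory.from_pairs([(52, 1), (20, 1), (52, 1), (20, 1)], id="e", weight=1.0),
    ]
    return aggregate_weighted(trajs, alphabet=[0, 16, 20, 52])
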