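from __future__ import annotations

import pytest

from trophinet import (
    AnalysisConfig,
    CoOccurrenceTable,
    DirectionObservation,
    SpeciesTaxon,
)


@pytest.fixture
def cfg() -> AnalysisConfig:
    return AnalysisConfig()


@pytest.fixture
def triple_world():
    """Three species, one site, everything up and co-occurring.

    A (predator, size 3), B (predator, size 2), C (non-predator, size 1):
    the minimal world in which greedy abduction must adopt (A, C) by the
    prey-size tie-break, then (B, C), leaving C's observation unexplained.
    """
    traits = {
        "A": SpeciesTaxon("A", "A", True, 3),
        "B": SpeciesTaxon("B", "B", True, 2),
        "C": SpeciesTaxon("C", "C", False, 1),
    }
    obs = [
        DirectionObservation("A", "s1", "up"),
        DirectionObservation("B", "s1", "up"),
        DirectionObservation("C", "s1", "up"),
    ]
    scores = {
        ("s1", frozenset(p)): 1
        for p in (("A", "B"), ("A", "C"), ("B", "C"))
    }
    return traits, obs, CoOccurrenceTable(scores)
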