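from __future__ import annotations

import sys
from pathlib import Path

import pytest

# make the sibling oracle helpers importable regardless of rootdir
sys.path.insert(0, str(Path(__file__).parent))

from oracles import make_matrix  # noqa: E402


@pytest.fixture
def ten_patient_matrix():
    """10 patients; X in rows 0-4, Y in rows 0-2 and 5-6 (a=3 b=2 c=2 d=3)."""
    sets = [set() for _ in range(10)]
    for i in range(5):
        sets[i].add("X00")
    for i in (0, 1, 2, 5, 6):
        sets[i].add("Y00")
    return make_matrix(sets)


@pytest.fixture
def planted_100_matrix():
    """100 patients: A and B together in 60, A alone in 20, B alone in 10."""
    sets = []
    sets += [{"A00", "B00"}] * 60
    sets += [{"A00"}] * 20
    sets += [{"B00"}] * 10
    sets += [set()] * 10
    return make_matrix(sets)
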