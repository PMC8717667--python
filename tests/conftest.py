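from datetime import date

import numpy as np
import pytest

from prevmap import synthetic as syn
from prevmap.cohort import PersonRecords
from prevmap.geography import adjacency_from_edges


@pytest.fixture
def path3():
    """A - B - C path graph."""
    return adjacency_from_edges([("A", "B"), ("B", "C")])


@pytest.fixture
def grid4():
    """4x4 rook lattice."""
    return syn.generate_lattice(4, 4, 0.0, seed=0)


@pytest.fixture
def lattice96():
    return syn.generate_lattice(12, 8, 0.15, seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_person(
    events,
    person_id="p1",
    sex="F",
    birth=date(1950, 6, 15),
    start=date(1995, 1, 1),
    end=None,
    end_reason=None,
    region="R1",
    years=range(1995, 2018),
):
    """Minimal person with full coverage and one region for all years."""
    return PersonRecords(
        person_id=person_id,
        sex=sex,
        birth_date=birth,
        coverage_spells=((start, end),),
        region_by_year={y: region for y in years},
        events=tuple(sorted(events)),
        end_reason=end_reason,
    )
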