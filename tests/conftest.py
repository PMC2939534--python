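import pytest

from tagscout import InsertModel, ReadKey, TagHit, scenario_wd40, search


def make_hit(
    q_start,
    q_end,
    strand="+",
    read_len=None,
    fragment="f1",
    mate=1,
    r_start=0,
    r_end=None,
    matches=None,
    score=None,
):
    """Fully aligned synthetic TagHit (default: alignment spans the read)."""
    length = q_end - q_start
    if read_len is None:
        read_len = length
    if r_end is None:
        r_end = r_start + length
    if matches is None:
        matches = length
    mismatches = length - matches
    if score is None:
        score = matches - 2 * mismatches
    return TagHit(
        read_key=ReadKey(fragment, mate),
        q_start=q_start,
        q_end=q_end,
        r_start=r_start,
        r_end=r_end,
        strand=strand,
        score=score,
        matches=matches,
        mismatches=mismatches,
        read_len=read_len,
    )


@pytest.fixture(scope="session")
def wd40():
    """The cross-species recovery scenario, seed 42 (shared: it is pure)."""
    return scenario_wd40(42)


@pytest.fixture(scope="session")
def wd40_result(wd40):
    return search(wd40.query, wd40.library, insert=wd40.insert)


@pytest.fixture(scope="session")
def unrelated_result(wd40):
    return search(wd40.query, wd40.unrelated_library, insert=wd40.insert)


@pytest.fixture
def insert_900_1100():
    return InsertModel(mean=1000, sd=50, L_min=900, L_max=1100)
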