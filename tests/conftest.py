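import pytest

from ddiscreen.contingency import CaseReport, ContingencyTable4x2, TripleKey

EVENT = "Stevens-Johnson syndrome"
OTHER = "Other adverse events (pooled)"


def case(cid, drugs=(), events=()):
    return CaseReport(cid, frozenset(drugs), frozenset(events))


@pytest.fixture
def hand_cases():
    """12-case fixture with a hand-tallied 4x2 table for (a, b, EVENT)."""
    return [
        case("1", {"a", "b"}, {EVENT}),
        case("2", {"a", "b"}, {OTHER}),
        case("3", {"a"}, {EVENT}),
        case("4", {"a"}),
        case("5", {"a"}, {OTHER}),
        case("6", {"b"}, {EVENT}),
        case("7", {"b", "c"}, {OTHER}),
        case("8", {"c"}, {EVENT}),
        case("9", events={EVENT}),
        case("10"),
        case("11", {"c"}, {OTHER}),
        case("12", {"a", "b"}, {EVENT, OTHER}),
    ]


#: hand tally of the fixture above for the triple (a, b, EVENT)
HAND_TABLE = ContingencyTable4x2(
    n111=2, n110=1, n101=1, n100=2, n011=1, n010=1, n001=2, n000=2
)


def table_from_f(n11p, f11, n10p, f10, n01p, f01, n00p, f00):
    """Build an integer table realising the given row sizes and f-cells exactly."""
    cells = []
    for n, f in ((n11p, f11), (n10p, f10), (n01p, f01), (n00p, f00)):
        k = f * n
        assert abs(k - round(k)) < 1e-9, "f*n must be an integer for an exact table"
        cells.extend([round(k), n - round(k)])
    return ContingencyTable4x2(*cells)


def tk(i, event=EVENT):
    """A distinct canonical triple for universe-building in tests."""
    return TripleKey(f"d{i:04d}", "zzz", event)
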