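"""Report-level case assembly and 4x2 contingency tables.

Spontaneous-reporting-system (SRS) databases such as JADER ship as a
set of csv tables keyed by a case identifier.  This module reads those
tables into case-level records (one case = one report carrying a set of
suspect drugs and a set of adverse-event preferred terms), enumerates
(drug1, drug2, event) triples, and tallies the eight-cell 4x2
contingency table that every downstream detector consumes::

                        target AE   other AEs
    both drugs            n111        n110
    only drug 1           n101        n100
    only drug 2           n011        n010
    neither drug          n001        n000

Row marginals (n11p, n10p, n01p, n00p), column marginals (np1, np0) and
the grand total (nppp) are always derived from the cells, never stored.
"""

from __future__ import annotations

import enum
import logging
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "CaseReport",
    "TripleKey",
    "ContingencyTable4x2",
    "SubsetView",
    "Perspective",
    "ColumnMap",
    "JADER_COLUMNS",
    "FormatError",
    "normalize_drug",
    "normalize_event",
    "read_cases",
    "enumerate_triples",
    "tabulate",
    "tabulate_all",
    "subset_view",
    "tables_to_frame",
    "frame_to_tables",
]


class FormatError(ValueError):
    """Raised when an input table does not match the expected layout."""


def normalize_drug(name: str) -> str:
    """Normalize a drug name: strip surrounding whitespace and case-fold."""
    return name.strip().casefold()


def normalize_event(term: str) -> str:
    """Normalize an adverse-event preferred term: strip whitespace only.

    Preferred terms are controlled vocabulary, so case is preserved.
    """
    return term.strip()


@dataclass(frozen=True)
class CaseReport:
    """One spontaneous report: a case id plus its suspect drugs and events."""

    case_id: str
    suspect_drugs: frozenset[str] = field(default_factory=frozenset)
    events: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.case_id:
            raise ValueError("case_id must be non-empty")
        object.__setattr__(self, "suspect_drugs", frozenset(self.suspect_drugs))
        object.__setattr__(self, "events", frozenset(self.events))
        if any(not d for d in self.suspect_drugs):
            raise ValueError(f"case {self.case_id!r}: empty drug name")
        if any(not e for e in self.events):
            raise ValueError(f"case {self.case_id!r}: empty event term")


@dataclass(frozen=True, order=True)
class TripleKey:
    """A canonical (drug1, drug2, event) triple; drug order is lexicographic."""

    drug1: str
    drug2: str
    event: str

    def __post_init__(self) -> None:
        if self.drug1 == self.drug2:
            raise ValueError("drug1 and drug2 must differ")
        if self.drug1 > self.drug2:
            raise ValueError(
                f"triple not canonical: {self.drug1!r} > {self.drug2!r}; "
                "use TripleKey.make()"
            )
        if not (self.drug1 and self.drug2 and self.event):
            raise ValueError("triple components must be non-empty")

    @classmethod
    def make(cls, drug_a: str, drug_b: str, event: str) -> "TripleKey":
        """Build a canonical triple regardless of the drug argument order."""
        d1, d2 = sorted((drug_a, drug_b))
        return cls(d1, d2, event)


class Perspective(enum.Enum):
    """Which drug's user group defines the 2x2 subset."""

    WITHIN_D1_USERS = "within_d1_users"
    WITHIN_D2_USERS = "within_d2_users"


@dataclass(frozen=True)
class ContingencyTable4x2:
    """Eight cell counts of the 4x2 report table for one triple."""

    n111: int
    n110: int
    n101: int
    n100: int
    n011: int
    n010: int
    n001: int
    n000: int

    def __post_init__(self) -> None:
        for name in self.CELLS:
            value = getattr(self, name)
            if value < 0 or value != int(value):
                raise ValueError(f"cell {name} must be a non-negative integer")

    CELLS = ("n111", "n110", "n101", "n100", "n011", "n010", "n001", "n000")

    # --- derived marginals -------------------------------------------------
    @property
    def n11p(self) -> int:
        return self.n111 + self.n110

    @property
    def n10p(self) -> int:
        return self.n101 + self.n100

    @property
    def n01p(self) -> int:
        return self.n011 + self.n010

    @property
    def n00p(self) -> int:
        return self.n001 + self.n000

    @property
    def np1(self) -> int:
        return self.n111 + self.n101 + self.n011 + self.n001

    @property
    def np0(self) -> int:
        return self.n110 + self.n100 + self.n010 + self.n000

    @property
    def nppp(self) -> int:
        return self.np1 + self.np0

    def cells(self) -> dict[str, int]:
        return {name: getattr(self, name) for name in self.CELLS}

    def swap_drugs(self) -> "ContingencyTable4x2":
        """The table for the same triple with drug1/drug2 roles exchanged."""
        return ContingencyTable4x2(
            n111=self.n111, n110=self.n110,
            n101=self.n011, n100=self.n010,
            n011=self.n101, n010=self.n100,
            n001=self.n001, n000=self.n000,
        )


@dataclass(frozen=True)
class SubsetView:
    """2x2 view of the 4x2 table restricted to one drug's user group."""

    N11: int
    N10: int
    N01: int
    N00: int
    perspective: Perspective

    def counts(self) -> tuple[int, int, int, int]:
        return (self.N11, self.N10, self.N01, self.N00)


def subset_view(table: ContingencyTable4x2, perspective: Perspective) -> SubsetView:
    """Project the 4x2 table onto the 2x2 subset for one drug's users.

    Within drug-1 users the exposure of interest is drug 2 and vice
    versa; the co-exposure row (N11, N10) is shared between both views.
    """
    if perspective is Perspective.WITHIN_D1_USERS:
        return SubsetView(table.n111, table.n110, table.n101, table.n100, perspective)
    if perspective is Perspective.WITHIN_D2_USERS:
        return SubsetView(table.n111, table.n110, table.n011, table.n010, perspective)
    raise ValueError(f"invalid perspective: {perspective!r}")


# ---------------------------------------------------------------------------
# csv ingestion
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ColumnMap:
    """Column names of the demo/drug/reac tables plus the suspect-role value."""

    case_id: str = "識別番号"
    drug_name: str = "医薬品（一般名）"
    drug_role: str = "医薬品の関与"
    suspect_role_value: str = "被疑薬"
    event_pt: str = "有害事象"


#: Default headers matching the JADER csv distribution.
JADER_COLUMNS = ColumnMap()

TableLike = "pd.DataFrame | str | Path"


def _load(table: "pd.DataFrame | str | Path", required: Sequence[str], label: str) -> pd.DataFrame:
    if isinstance(table, (str, Path)):
        df = pd.read_csv(table, dtype=str, encoding="utf-8")
    else:
        df = table
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{label} table is missing column(s): {missing}")
    return df


def read_cases(
    demo_table: "pd.DataFrame | str | Path",
    drug_table: "pd.DataFrame | str | Path",
    reac_table: "pd.DataFrame | str | Path",
    columns: ColumnMap = JADER_COLUMNS,
) -> list[CaseReport]:
    """Assemble one :class:`CaseReport` per case id in the demo table.

    Only drug rows whose role column equals the configured suspect-role
    value contribute to ``suspect_drugs``; concomitant rows are dropped.
    Cases with no suspect drug or no event are retained with empty sets
    (they still populate the n000-type cells).  Duplicate case ids in the
    demo table keep the last-seen row (JADER ships quarterly revisions);
    a warning is logged.  Drug/event rows referencing case ids absent
    from the demo table are ignored with a warning.
    """
    demo = _load(demo_table, [columns.case_id], "demo")
    drug = _load(drug_table, [columns.case_id, columns.drug_name, columns.drug_role], "drug")
    reac = _load(reac_table, [columns.case_id, columns.event_pt], "reac")

    ids: list[str] = []
    seen: set[str] = set()
    for raw in demo[columns.case_id].astype(str):
        cid = raw.strip()
        if not cid or cid == "nan":
            continue
        if cid in seen:
            logger.warning("duplicate case id %r in demo table; keeping last-seen row", cid)
            continue
        seen.add(cid)
        ids.append(cid)

    drugs_by_case: dict[str, set[str]] = {cid: set() for cid in seen}
    events_by_case: dict[str, set[str]] = {cid: set() for cid in seen}

    suspect = drug[drug[columns.drug_role].astype(str).str.strip() == columns.suspect_role_value]
    orphans = 0
    for cid, name in zip(suspect[columns.case_id].astype(str), suspect[columns.drug_name].astype(str)):
        cid = cid.strip()
        norm = normalize_drug(name)
        if not norm or norm == "nan":
            continue
        if cid not in drugs_by_case:
            orphans += 1
            continue
        drugs_by_case[cid].add(norm)

    for cid, term in zip(reac[columns.case_id].astype(str), reac[columns.event_pt].astype(str)):
        cid = cid.strip()
        norm = normalize_event(term)
        if not norm or norm == "nan":
            continue
        if cid not in events_by_case:
            orphans += 1
            continue
        events_by_case[cid].add(norm)

    if orphans:
        logger.warning("%d drug/event rows referenced case ids absent from the demo table", orphans)

    return [
        CaseReport(cid, frozenset(drugs_by_case[cid]), frozenset(events_by_case[cid]))
        for cid in ids
    ]


# ---------------------------------------------------------------------------
# triple enumeration and tabulation
# ---------------------------------------------------------------------------

def enumerate_triples(cases: Iterable[CaseReport], target_event: str) -> list[TripleKey]:
    """Every canonical drug pair co-reported with ``target_event`` at least once.

    A pair enters the universe iff some case lists both drugs as suspect
    and the target event (n111 >= 1).  The result is sorted for
    determinism.
    """
    if not target_event:
        raise ValueError("target_event must be non-empty")
    target = normalize_event(target_event)
    found: set[TripleKey] = set()
    for case in cases:
        if target not in case.events or len(case.suspect_drugs) < 2:
            continue
        drugs = sorted(case.suspect_drugs)
        for i, d1 in enumerate(drugs):
            for d2 in drugs[i + 1:]:
                found.add(TripleKey(d1, d2, target))
    return sorted(found)


def tabulate(cases: Iterable[CaseReport], triple: TripleKey) -> ContingencyTable4x2:
    """Tally the 4x2 table for one triple; each case lands in exactly one cell."""
    return tabulate_all(cases, [triple])[triple]


def tabulate_all(
    cases: Iterable[CaseReport], triples: Sequence[TripleKey]
) -> dict[TripleKey, ContingencyTable4x2]:
    """One pass over cases, tallying a 4x2 table per triple."""
    counts = {t: [0] * 8 for t in triples}
    # cell order mirrors ContingencyTable4x2.CELLS:
    # (d1, d2, ev) -> index: 111,110,101,100,011,010,001,000
    for case in cases:
        drugs = case.suspect_drugs
        events = case.events
        for t in triples:
            has1 = t.drug1 in drugs
            has2 = t.drug2 in drugs
            ev = t.event in events
            idx = (0 if has1 and has2 else 2 if has1 else 4 if has2 else 6) + (0 if ev else 1)
            counts[t][idx] += 1
    return {t: ContingencyTable4x2(*c) for t, c in counts.items()}


# ---------------------------------------------------------------------------
# tidy frame round-trip
# ---------------------------------------------------------------------------

TABLE_FRAME_COLUMNS = ["drug1", "drug2", "event", *ContingencyTable4x2.CELLS]


def tables_to_frame(tables: Mapping[TripleKey, ContingencyTable4x2]) -> pd.DataFrame:
    """Tidy frame: one row per triple, eight cell columns; sorted by triple."""
    rows = [
        {"drug1": t.drug1, "drug2": t.drug2, "event": t.event, **tables[t].cells()}
        for t in sorted(tables)
    ]
    return pd.DataFrame(rows, columns=TABLE_FRAME_COLUMNS)


def frame_to_tables(frame: pd.DataFrame) -> dict[TripleKey, ContingencyTable4x2]:
    missing = [c for c in TABLE_FRAME_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(f"contingency frame is missing column(s): {missing}")
    out: dict[TripleKey, ContingencyTable4x2] = {}
    for row in frame.itertuples(index=False):
        key = TripleKey.make(str(row.drug1), str(row.drug2), str(row.event))
        out[key] = ContingencyTable4x2(
            *(int(getattr(row, c)) for c in ContingencyTable4x2.CELLS)
        )
    return out
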