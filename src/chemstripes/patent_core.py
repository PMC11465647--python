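"""Parsing, validation, deduplication and date assignment for patent records.

Patent publications are identified by strings of the form ``OFFICE-NUMBER-KIND``
(e.g. ``US-1257524-A``): a two-letter patent-office code, a document number and
a kind code distinguishing publication stages (application ``A1``, grant ``B2``,
...). One invention may appear as several publications of the same
office+number family differing only in kind code, so counting can be done per
publication or per family. Every record carries up to three dates — priority,
filing, publication — and downstream year binning picks the first available
role from a configurable preference order (priority dates are what most users
of PubChem's patent data expect, but they can be absent).
"""

from __future__ import annotations

import csv
import json
import re
from dataclasses import dataclass, field, replace
from datetime import date
from pathlib import Path
from typing import Iterable, Iterator, Sequence

__all__ = [
    "PatentIdentifier",
    "PatentRecord",
    "FamilyKey",
    "DatePreference",
    "DEFAULT_DATE_PREFERENCE",
    "DATE_ROLES",
    "PatentParseError",
    "parse_patent_identifier",
    "family_key",
    "dedupe_records",
    "assign_date",
    "assign_year",
    "read_records",
    "write_records",
    "read_cid_list",
]

_OFFICE_RE = re.compile(r"^[A-Z]{2}$")
_NUMBER_RE = re.compile(r"^[0-9]+$")
_KIND_RE = re.compile(r"^[A-Z][0-9]?$")

DATE_ROLES = ("priority", "filing", "publication")


class PatentParseError(ValueError):
    """Raised when a deposited patent-identifier string cannot be parsed."""


@dataclass(frozen=True, order=True)
class PatentIdentifier:
    """One patent publication: office code, document number, kind code.

    The canonical string form is ``OFFICE-NUMBER-KIND``; leading zeros in the
    document number are significant and preserved.
    """

    office: str
    number: str
    kind: str

    def __post_init__(self) -> None:
        if not _OFFICE_RE.match(self.office):
            raise PatentParseError(f"invalid office code {self.office!r}")
        if not _NUMBER_RE.match(self.number):
            raise PatentParseError(f"invalid document number {self.number!r}")
        if not _KIND_RE.match(self.kind):
            raise PatentParseError(f"invalid kind code {self.kind!r}")

    @property
    def raw(self) -> str:
        return f"{self.office}-{self.number}-{self.kind}"

    def __str__(self) -> str:
        return self.raw


@dataclass(frozen=True, order=True)
class FamilyKey:
    """Identifier with the kind code stripped: office + document number.

    Approximates a patent family (application/grant/re-examination documents
    of one invention at one office). Cross-office families are out of scope.
    """

    office: str
    number: str


@dataclass(frozen=True)
class PatentRecord:
    """A parsed patent publication with dates and linked compound CIDs."""

    identifier: PatentIdentifier
    priority_date: date | None = None
    filing_date: date | None = None
    publication_date: date | None = None
    cids: frozenset[int] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if (
            self.priority_date is None
            and self.filing_date is None
            and self.publication_date is None
        ):
            raise ValueError(
                f"record {self.identifier} has no date in any role"
            )
        if (
            self.priority_date is not None
            and self.publication_date is not None
            and self.priority_date > self.publication_date
        ):
            raise ValueError(
                f"record {self.identifier}: priority date "
                f"{self.priority_date} after publication {self.publication_date}"
            )
        object.__setattr__(self, "cids", frozenset(self.cids))
        if not self.cids:
            raise ValueError(f"record {self.identifier} links no CIDs")
        if any(c < 1 for c in self.cids):
            raise ValueError(f"record {self.identifier} has non-positive CID")

    def date_for(self, role: str) -> date | None:
        return getattr(self, f"{role}_date")


@dataclass(frozen=True)
class DatePreference:
    """Ordered date roles tried in turn when assigning a record to a year."""

    roles: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.roles:
            raise ValueError("date preference must name at least one role")
        if len(set(self.roles)) != len(self.roles):
            raise ValueError(f"duplicate roles in {self.roles}")
        unknown = set(self.roles) - set(DATE_ROLES)
        if unknown:
            raise ValueError(f"unknown date roles {sorted(unknown)}")

    def __iter__(self) -> Iterator[str]:
        return iter(self.roles)


#: Priority first (the preferred date for most users of this data), with
#: filing then publication as fallbacks so records lacking a priority date
#: are not silently dropped.
DEFAULT_DATE_PREFERENCE = DatePreference(("priority", "filing", "publication"))


def parse_patent_identifier(raw: str) -> PatentIdentifier:
    """Parse a deposited ``OFFICE-NUMBER-KIND`` string.

    Case of office and kind codes is normalised to upper; any other deviation
    from the three-segment shape is rejected loudly rather than coerced.

    >>> parse_patent_identifier("US-1257524-A")
    PatentIdentifier(office='US', number='1257524', kind='A')
    """
    if not isinstance(raw, str) or not raw:
        raise PatentParseError(f"not a patent identifier: {raw!r}")
    parts = raw.split("-")
    if len(parts) != 3:
        raise PatentParseError(
            f"malformed patent identifier {raw!r}: expected OFFICE-NUMBER-KIND"
        )
    office, number, kind = parts
    try:
        return PatentIdentifier(office.upper(), number, kind.upper())
    except PatentParseError as exc:
        raise PatentParseError(f"malformed patent identifier {raw!r}: {exc}") from None


def family_key(identifier: PatentIdentifier) -> FamilyKey:
    """Strip the kind code: publications sharing office+number share a key."""
    return FamilyKey(identifier.office, identifier.number)


def assign_date(record: PatentRecord, pref: DatePreference = DEFAULT_DATE_PREFERENCE) -> date | None:
    """The record's date under the first role in ``pref`` that is present."""
    for role in pref:
        d = record.date_for(role)
        if d is not None:
            return d
    return None


def assign_year(record: PatentRecord, pref: DatePreference = DEFAULT_DATE_PREFERENCE) -> int | None:
    """Year of :func:`assign_date`, or ``None`` if no preferred role has a date."""
    d = assign_date(record, pref)
    return None if d is None else d.year


def _merge(records: Sequence[PatentRecord], pref: DatePreference) -> PatentRecord:
    # keep the earliest-dated record (under pref) as the representative,
    # union the linked CIDs; ties broken by identifier for determinism
    far_future = date.max
    best = min(
        records,
        key=lambda r: (assign_date(r, pref) or far_future, r.identifier),
    )
    cids = frozenset().union(*(r.cids for r in records))
    return replace(best, cids=cids)


def dedupe_records(
    records: Iterable[PatentRecord],
    mode: str = "publication",
    pref: DatePreference = DEFAULT_DATE_PREFERENCE,
) -> list[PatentRecord]:
    """Collapse duplicate publications.

    mode="publication" keeps one record per full identifier (each deposited
    publication counted once); mode="family" keeps one per office+number
    family, so applications and grants of one invention collapse together.
    Either way the survivor carries the earliest date under ``pref`` and the
    union of linked CIDs, and output order is sorted by (office, number, kind).
    """
    if mode not in ("publication", "family"):
        raise ValueError(f"unknown dedupe mode {mode!r}")
    groups: dict[object, list[PatentRecord]] = {}
    for rec in records:
        key: object = (
            rec.identifier if mode == "publication" else family_key(rec.identifier)
        )
        groups.setdefault(key, []).append(rec)
    merged = [_merge(g, pref) for g in groups.values()]
    merged.sort(key=lambda r: r.identifier)
    return merged


# --------------------------------------------------------------------------
# serialization: newline-delimited JSON records
# --------------------------------------------------------------------------

def record_to_dict(record: PatentRecord) -> dict:
    out: dict = {"id": record.identifier.raw}
    for role in DATE_ROLES:
        d = record.date_for(role)
        if d is not None:
            out[f"{role}_date"] = d.isoformat()
    out["cids"] = sorted(record.cids)
    return out


def record_from_dict(obj: dict) -> PatentRecord:
    identifier = parse_patent_identifier(obj["id"])
    dates = {
        f"{role}_date": date.fromisoformat(obj[f"{role}_date"])
        for role in DATE_ROLES
        if f"{role}_date" in obj
    }
    return PatentRecord(identifier=identifier, cids=frozenset(obj["cids"]), **dates)


def write_records(records: Iterable[PatentRecord], path: str | Path) -> Path:
    """Write records as newline-delimited JSON (one object per line)."""
    path = Path(path)
    with path.open("w") as fh:
        for rec in records:
            fh.write(json.dumps(record_to_dict(rec), sort_keys=True))
            fh.write("\n")
    return path


def read_records(path: str | Path) -> list[PatentRecord]:
    """Read newline-delimited JSON records written by :func:`write_records`."""
    out = []
    with Path(path).open() as fh:
        for line in fh:
            line = line.strip()
            if line:
                out.append(record_from_dict(json.loads(line)))
    return out


def read_cid_list(path: str | Path) -> list[int]:
    """Read a CID list from plain text (one per line) or CSV with a CID column.

    The CSV column is matched case-insensitively; blank lines and ``#``
    comments in plain-text lists are ignored. Order is preserved, duplicates
    removed.
    """
    path = Path(path)
    cids: list[int] = []
    if path.suffix.lower() == ".csv":
        with path.open(newline="") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None:
                raise ValueError(f"{path}: empty CSV")
            col = next(
                (c for c in reader.fieldnames if c.strip().lower() == "cid"), None
            )
            if col is None:
                raise ValueError(f"{path}: no CID column (have {reader.fieldnames})")
            for row in reader:
                if row[col] and row[col].strip():
                    cids.append(int(row[col]))
    else:
        for line in path.read_text().splitlines():
            line = line.split("#", 1)[0].strip()
            if line:
                cids.append(int(line))
    seen: set[int] = set()
    unique = [c for c in cids if not (c in seen or seen.add(c))]
    if any(c < 1 for c in unique):
        raise ValueError(f"{path}: CIDs must be positive integers")
    return unique
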