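"""Regional attribution of patents via office codes.

Patent identifiers encode the *office* a document was published by, not where
its inventors live; this module uses the office code as the operational proxy
for region. Five data-rich focus regions (US, Europe, Japan, China, Korea) are
tracked individually, WIPO (``WO`` international filings) either separately or
folded into Other, and every unmapped office falls through to Other — the
mapping is total by construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import matplotlib.pyplot as plt
import pandas as pd

from .patent_core import (
    DEFAULT_DATE_PREFERENCE,
    DatePreference,
    PatentRecord,
    assign_year,
    dedupe_records,
)
from .stripes import DEFAULT_YEAR_RANGE, YearRange

__all__ = [
    "RegionMap",
    "DEFAULT_REGION_MAP",
    "FOCUS_REGIONS",
    "RegionBreakdown",
    "RegionSignature",
    "region_of",
    "regional_breakdown",
    "top_regions",
    "region_signatures",
    "exclusive_cids",
    "plot_breakdown",
]

FOCUS_REGIONS = ("US", "Europe", "Japan", "China", "Korea")
OTHER = "Other"
WIPO = "WIPO"

# stacked-plot colors: purple US, red Korea, green Japan, orange Europe,
# blue China, gray Other
REGION_COLORS = {
    "US": "#7b3294",
    "Korea": "#d7191c",
    "Japan": "#1a9641",
    "Europe": "#fdae61",
    "China": "#2c7bb6",
    WIPO: "#66c2a5",
    OTHER: "#999999",
}


@dataclass(frozen=True)
class RegionMap:
    """Total mapping office code -> region label (unknown offices -> Other)."""

    offices: Mapping[str, str]

    def region_of(self, office: str) -> str:
        return self.offices.get(office.upper(), OTHER)

    def labels(self, fold_wipo: bool = True) -> tuple[str, ...]:
        ordered = list(FOCUS_REGIONS)
        if not fold_wipo and WIPO in set(self.offices.values()):
            ordered.append(WIPO)
        ordered.append(OTHER)
        return tuple(ordered)

    @classmethod
    def from_json(cls, path: str | Path) -> "RegionMap":
        return cls(json.loads(Path(path).read_text()))

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(dict(self.offices), indent=2, sort_keys=True))
        return path


#: EP is the sole Europe office by default; national European offices map to
#: Other unless a custom map is supplied.
DEFAULT_REGION_MAP = RegionMap(
    {"US": "US", "EP": "Europe", "JP": "Japan", "CN": "China", "KR": "Korea",
     "WO": WIPO}
)


def region_of(office: str, region_map: RegionMap = DEFAULT_REGION_MAP) -> str:
    """Region label for an office code; never fails (Other is the fallback)."""
    return region_map.region_of(office)


@dataclass(frozen=True)
class RegionBreakdown:
    """Year x region count matrix; each dated in-range patent lands in
    exactly one cell, so rows sum to the yearly totals."""

    range: YearRange
    matrix: pd.DataFrame  # index: years, columns: region labels
    excluded: int = 0

    def to_tidy_csv(self, path: str | Path) -> Path:
        path = Path(path)
        tidy = (
            self.matrix.rename_axis("year")
            .reset_index()
            .melt(id_vars="year", var_name="region", value_name="count")
            .sort_values(["year", "region"], kind="stable")
        )
        tidy.to_csv(path, index=False)
        return path


def regional_breakdown(
    records: Iterable[PatentRecord],
    year_range: YearRange = DEFAULT_YEAR_RANGE,
    pref: DatePreference = DEFAULT_DATE_PREFERENCE,
    region_map: RegionMap = DEFAULT_REGION_MAP,
    fold_wipo: bool = True,
    dedupe_mode: str = "publication",
) -> RegionBreakdown:
    """Per-year, per-region counts of deduplicated dated records.

    fold_wipo=True merges WIPO international filings into Other, matching the
    usual stacked-plot grouping of "all others including world".
    """
    labels = region_map.labels(fold_wipo=fold_wipo)
    deduped = dedupe_records(list(records), mode=dedupe_mode, pref=pref)
    matrix = pd.DataFrame(0, index=list(year_range.years()), columns=list(labels))
    excluded = 0
    for rec in deduped:
        year = assign_year(rec, pref)
        if year is None or year not in year_range:
            excluded += 1
            continue
        region = region_map.region_of(rec.identifier.office)
        if fold_wipo and region == WIPO:
            region = OTHER
        if region not in matrix.columns:
            region = OTHER
        matrix.loc[year, region] += 1
    return RegionBreakdown(range=year_range, matrix=matrix, excluded=excluded)


def top_regions(
    records: Iterable[PatentRecord],
    n: int = 20,
    pref: DatePreference = DEFAULT_DATE_PREFERENCE,
    dedupe_mode: str = "publication",
) -> list[tuple[str, int]]:
    """Offices ranked by deduplicated patent count, ties broken alphabetically."""
    if n < 1:
        raise ValueError("n must be >= 1")
    deduped = dedupe_records(list(records), mode=dedupe_mode, pref=pref)
    counts: dict[str, int] = {}
    for rec in deduped:
        counts[rec.identifier.office] = counts.get(rec.identifier.office, 0) + 1
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return ranked[:n]


@dataclass(frozen=True)
class RegionSignature:
    """The set of regions in which one CID has at least one patent."""

    cid: int
    regions: frozenset[str]


def region_signatures(
    records: Iterable[PatentRecord],
    region_map: RegionMap = DEFAULT_REGION_MAP,
    dedupe_mode: str = "publication",
    pref: DatePreference = DEFAULT_DATE_PREFERENCE,
) -> list[RegionSignature]:
    """One signature per CID occurring in the deduplicated records."""
    deduped = dedupe_records(list(records), mode=dedupe_mode, pref=pref)
    by_cid: dict[int, set[str]] = {}
    for rec in deduped:
        region = region_map.region_of(rec.identifier.office)
        for cid in rec.cids:
            by_cid.setdefault(cid, set()).add(region)
    return [
        RegionSignature(cid=cid, regions=frozenset(regions))
        for cid, regions in sorted(by_cid.items())
    ]


def exclusive_cids(
    signatures: Iterable[RegionSignature], subset: Iterable[str]
) -> list[int]:
    """CIDs patented in *exactly* the given regions — present in every member
    of the subset and absent everywhere else. Sorted ascending."""
    wanted = frozenset(subset)
    if not wanted:
        raise ValueError("subset must be nonempty")
    return sorted(s.cid for s in signatures if s.regions == wanted)


def plot_breakdown(breakdown: RegionBreakdown, path: str | Path) -> Path:
    """Stacked-area plot of the year x region matrix."""
    path = Path(path)
    m = breakdown.matrix
    fig, ax = plt.subplots(figsize=(10, 5), dpi=100)
    ax.stackplot(
        m.index,
        [m[c].to_numpy() for c in m.columns],
        labels=list(m.columns),
        colors=[REGION_COLORS.get(c, "#cccccc") for c in m.columns],
    )
    ax.set_xlabel("year")
    ax.set_ylabel("patents")
    ax.legend(loc="upper left", fontsize="small")
    fig.savefig(path, metadata={"Software": "chemstripes"})
    plt.close(fig)
    return path
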