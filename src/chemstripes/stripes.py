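"""Yearly binning and the chemical-stripes visualization.

One vertical stripe per calendar year, colored by that year's deduplicated
patent (or literature-reference) count for a chemical or a set of chemical
forms. Colors are normalised per chemical between the minimum and maximum
count over the displayed range, so each plot spans the full palette; this
deliberately makes color comparable *within* one chemical's stripes only.
Two palettes: the default traffic-light scheme green -> yellow -> red, and a
colorblind-friendly blue -> red.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
from matplotlib.colors import LinearSegmentedColormap

from .patent_core import (
    DEFAULT_DATE_PREFERENCE,
    DatePreference,
    PatentRecord,
    assign_year,
    dedupe_records,
)

__all__ = [
    "YearRange",
    "DEFAULT_YEAR_RANGE",
    "YearlyCounts",
    "StripeSpec",
    "PALETTES",
    "bin_counts",
    "bin_years",
    "summarize_cids",
    "make_stripes",
    "render_png",
]


@dataclass(frozen=True)
class YearRange:
    """Inclusive range of calendar years."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"empty year range {self.start}–{self.end}")

    def years(self) -> range:
        return range(self.start, self.end + 1)

    def __len__(self) -> int:
        return self.end - self.start + 1

    def __contains__(self, year: object) -> bool:
        return isinstance(year, int) and self.start <= year <= self.end


DEFAULT_YEAR_RANGE = YearRange(1960, 2023)


@dataclass(frozen=True)
class YearlyCounts:
    """Per-year deduplicated counts for one CID or CID set.

    ``excluded`` counts records that were dated outside the range or carried
    no date under the active preference — reported, never silently dropped.
    """

    subject: tuple[int, ...]
    mode: str  # "patent" or "literature"
    range: YearRange
    counts: Mapping[int, int]
    excluded: int = 0

    def __post_init__(self) -> None:
        missing = [y for y in self.range.years() if y not in self.counts]
        if missing or len(self.counts) != len(self.range):
            raise ValueError("counts must be defined on exactly the range years")
        if any(v < 0 for v in self.counts.values()):
            raise ValueError("negative count")

    def values(self) -> np.ndarray:
        return np.array([self.counts[y] for y in self.range.years()])

    def total(self) -> int:
        return int(sum(self.counts.values()))


#: palette name -> ordered color stops (low count first)
PALETTES: dict[str, tuple[str, ...]] = {
    "traffic": ("#008000", "#ffff00", "#ff0000"),  # green via yellow to red
    "colorblind": ("#0000ff", "#ff0000"),  # blue to red
}


def _colormap(palette: str) -> LinearSegmentedColormap:
    try:
        stops = PALETTES[palette]
    except KeyError:
        raise ValueError(f"unknown palette {palette!r}; have {sorted(PALETTES)}")
    return LinearSegmentedColormap.from_list(palette, stops)


@dataclass(frozen=True)
class StripeSpec:
    """Render-ready stripes: one RGB color per year plus title metadata."""

    counts: YearlyCounts
    palette: str
    colors: Mapping[int, tuple[float, float, float]]
    title: Mapping[str, object] = field(default_factory=dict)


def bin_years(
    years_of_events: Iterable[int | None], year_range: YearRange
) -> tuple[dict[int, int], int]:
    """Tally assigned years into the range; return (counts, n_excluded)."""
    counts = {y: 0 for y in year_range.years()}
    excluded = 0
    for y in years_of_events:
        if y is not None and y in year_range:
            counts[y] += 1
        else:
            excluded += 1
    return counts, excluded


def bin_counts(
    records: Iterable[PatentRecord],
    year_range: YearRange = DEFAULT_YEAR_RANGE,
    pref: DatePreference = DEFAULT_DATE_PREFERENCE,
    dedupe_mode: str = "publication",
    subject: Sequence[int] = (),
    mode: str = "patent",
) -> YearlyCounts:
    """Deduplicate records and count them per assigned year.

    Records whose year (first present date role in ``pref``) falls outside
    the range, or that carry none of the preferred dates, are excluded and
    counted in ``YearlyCounts.excluded`` so that
    ``sum(counts) + excluded == len(deduplicated records)``.
    """
    deduped = dedupe_records(list(records), mode=dedupe_mode, pref=pref)
    counts, excluded = bin_years((assign_year(r, pref) for r in deduped), year_range)
    return YearlyCounts(
        subject=tuple(subject), mode=mode, range=year_range,
        counts=counts, excluded=excluded,
    )


def summarize_cids(
    per_cid_records: Mapping[int, Sequence[PatentRecord]],
    year_range: YearRange = DEFAULT_YEAR_RANGE,
    pref: DatePreference = DEFAULT_DATE_PREFERENCE,
    dedupe_mode: str = "publication",
) -> YearlyCounts:
    """Summarized stripes over several CIDs (salts, stereoisomers, ...).

    The union of all records is deduplicated by identifier before binning,
    so a patent mentioning several of the input CIDs counts exactly once.
    """
    if not per_cid_records:
        raise ValueError("summarize_cids needs at least one CID")
    pooled = [r for recs in per_cid_records.values() for r in recs]
    return bin_counts(
        pooled, year_range, pref, dedupe_mode,
        subject=sorted(per_cid_records),
    )


def make_stripes(counts: YearlyCounts, palette: str = "traffic") -> StripeSpec:
    """Assign one color per year by linear min–max normalization of counts.

    The year with the minimum count gets the palette's low endpoint (green for
    traffic, blue for colorblind), the maximum the high endpoint (red); a
    constant series — including all zeros — renders entirely at the low
    endpoint. Equal counts always receive equal colors.
    """
    cmap = _colormap(palette)
    values = counts.values().astype(float)
    lo, hi = values.min(), values.max()
    if hi > lo:
        positions = (values - lo) / (hi - lo)
    else:
        positions = np.zeros_like(values)
    colors = {
        y: tuple(cmap(t)[:3])
        for y, t in zip(counts.range.years(), positions)
    }
    return StripeSpec(counts=counts, palette=palette, colors=colors)


def render_png(
    spec: StripeSpec,
    path: str | Path,
    dpi: int = 100,
    figsize: tuple[float, float] = (10.0, 4.0),
) -> Path:
    """Render the stripes to PNG: one vertical stripe per year, no gaps."""
    path = Path(path)
    years = list(spec.counts.range.years())
    rgb = np.array([[spec.colors[y] for y in years]])  # 1 x n_years x 3
    fig, ax = plt.subplots(figsize=figsize, dpi=dpi)
    ax.imshow(
        rgb, aspect="auto", interpolation="nearest",
        extent=(years[0] - 0.5, years[-1] + 0.5, 0.0, 1.0),
    )
    ax.set_yticks([])
    ax.set_xlabel("year")
    meta = dict(spec.title)
    if meta:
        name = meta.get("name", "")
        formula = meta.get("formula", "")
        total = meta.get("total", spec.counts.total())
        ax.set_title(f"{name} {formula} — {total} {spec.counts.mode} records".strip())
    try:
        # metadata pinned so repeated renders are byte-identical
        fig.savefig(path, metadata={"Software": "chemstripes"})
    except OSError as exc:
        raise OSError(f"cannot write stripes PNG to {path}: {exc}") from exc
    finally:
        plt.close(fig)
    return path
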