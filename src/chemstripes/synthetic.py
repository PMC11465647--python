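"""Synthetic patent corpora with controlled planted structure.

Real patent–chemical incidence data shows long-term exponential growth,
shifting regional mixes (notably a rising share of Chinese filings),
kind-code multiplicity within patent families, an up-to-18-month lag between
priority and publication dates, a handful of heavily co-mentioned "hub"
chemicals, and occasional chemicals with atypical temporal patterns (abrupt
drops after regulation, transient peaks). This module emulates all of those
features from a single seeded generator and exposes the planted ground truth,
so every downstream stage — binning, regional breakdowns, network centrality,
outlier clustering — can be tested offline against known structure.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import date, timedelta
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .patent_core import PatentIdentifier, PatentRecord
from .stripes import YearRange

__all__ = [
    "CorpusSpec",
    "PlantedTruth",
    "generate_corpus",
    "truth_series",
    "planted_outlier_series",
]

#: offices drawn uniformly for patents assigned to the Other region
OTHER_OFFICES = ("CA", "AU", "BR", "IN", "RU")

REGION_OFFICE = {
    "US": "US", "Europe": "EP", "Japan": "JP", "China": "CN",
    "Korea": "KR", "WIPO": "WO",
}

#: default regional mix, loosely matching the relative data richness of the
#: major offices (US and Europe largest, then Japan/China/Korea, WIPO, rest)
DEFAULT_REGION_WEIGHTS: dict[str, float] = {
    "US": 0.30, "Europe": 0.20, "Japan": 0.15, "China": 0.12,
    "Korea": 0.08, "WIPO": 0.10, "Other": 0.05,
}


@dataclass(frozen=True)
class CorpusSpec:
    """Parameters of one synthetic corpus.

    growth_rate is the yearly multiplicative intensity factor (1.03 = 3%
    growth per year, a typical long-run patenting trend); region_drift maps a
    region to a yearly multiplier applied to its weight before renormalising,
    emulating e.g. the rising Chinese share. hub_cids are co-mentioned at
    hub_boost times the background sampling rate. outlier_cids maps a CID to
    ("abrupt_drop", year) — intensity falls to drop_factor from that year on —
    or ("peak", year) — a transient Gaussian bump of height peak_boost and
    width peak_width years. With probability duplicate_kind_prob a patent
    additionally emits a second kind-code publication of the same family.
    """

    n_cids: int = 200
    n_patents: int = 1000
    years: YearRange = YearRange(1960, 2023)
    growth_rate: float = 1.03
    region_weights: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_REGION_WEIGHTS)
    )
    region_drift: Mapping[str, float] | None = None
    mean_cids_per_patent: float = 3.0
    hub_cids: frozenset[int] = frozenset()
    hub_boost: float = 10.0
    outlier_cids: Mapping[int, tuple[str, int]] = field(default_factory=dict)
    drop_factor: float = 0.05
    peak_boost: float = 8.0
    peak_width: float = 2.0
    duplicate_kind_prob: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cids < 1 or self.n_patents < 1:
            raise ValueError("n_cids and n_patents must be >= 1")
        if not 1.0 <= self.mean_cids_per_patent <= self.n_cids:
            raise ValueError(
                f"mean_cids_per_patent={self.mean_cids_per_patent} infeasible "
                f"for n_cids={self.n_cids}"
            )
        if not 0.0 <= self.duplicate_kind_prob <= 1.0:
            raise ValueError("duplicate_kind_prob must lie in [0, 1]")
        total = sum(self.region_weights.values())
        if total <= 0 or any(w < 0 for w in self.region_weights.values()):
            raise ValueError("region_weights must be nonnegative with positive sum")
        unknown = set(self.region_weights) - (set(REGION_OFFICE) | {"Other"})
        if unknown:
            raise ValueError(f"unknown regions in weights: {sorted(unknown)}")
        bad = set(self.hub_cids) | set(self.outlier_cids)
        if any(not 1 <= c <= self.n_cids for c in bad):
            raise ValueError("hub/outlier cids must lie in 1..n_cids")
        for cid, (pattern, _year) in self.outlier_cids.items():
            if pattern not in ("abrupt_drop", "peak"):
                raise ValueError(f"unknown outlier pattern {pattern!r} for cid {cid}")

    @classmethod
    def from_json(cls, path: str | Path) -> "CorpusSpec":
        obj = json.loads(Path(path).read_text())
        if "years" in obj:
            obj["years"] = YearRange(*obj["years"])
        if "hub_cids" in obj:
            obj["hub_cids"] = frozenset(obj["hub_cids"])
        if "outlier_cids" in obj:
            obj["outlier_cids"] = {
                int(c): (p, int(y)) for c, (p, y) in obj["outlier_cids"].items()
            }
        return cls(**obj)


@dataclass(frozen=True)
class PlantedTruth:
    """The generator's ground truth, consistent with the emitted corpus."""

    cids: tuple[int, ...]
    years: YearRange
    intensities: np.ndarray  # cid x year expected mention counts
    hub_cids: frozenset[int]
    outlier_cids: Mapping[int, tuple[str, int]]
    patent_regions: tuple[str, ...]  # true region per base patent
    n_family_duplicates: int

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        obj = {
            "cids": list(self.cids),
            "years": [self.years.start, self.years.end],
            "intensities": self.intensities.tolist(),
            "hub_cids": sorted(self.hub_cids),
            "outlier_cids": {
                str(c): list(v) for c, v in sorted(self.outlier_cids.items())
            },
            "patent_regions": list(self.patent_regions),
            "n_family_duplicates": self.n_family_duplicates,
        }
        path.write_text(json.dumps(obj))
        return path


def _cid_weight_matrix(spec: CorpusSpec) -> np.ndarray:
    """Per-(cid, year) sampling weight encoding hubs and outlier patterns."""
    years = np.array(list(spec.years.years()), dtype=float)
    w = np.ones((spec.n_cids, len(years)))
    for cid in spec.hub_cids:
        w[cid - 1, :] *= spec.hub_boost
    for cid, (pattern, year) in spec.outlier_cids.items():
        if pattern == "abrupt_drop":
            w[cid - 1, years >= year] *= spec.drop_factor
        else:  # peak
            bump = spec.peak_boost * np.exp(
                -((years - year) ** 2) / (2.0 * spec.peak_width**2)
            )
            w[cid - 1, :] *= 1.0 + bump
    return w


def _region_probs(spec: CorpusSpec, year_index: int) -> tuple[list[str], np.ndarray]:
    regions = sorted(spec.region_weights)
    weights = np.array([spec.region_weights[r] for r in regions], dtype=float)
    if spec.region_drift:
        for i, r in enumerate(regions):
            mult = spec.region_drift.get(r)
            if mult:
                weights[i] *= mult**year_index
    return regions, weights / weights.sum()


def generate_corpus(spec: CorpusSpec) -> tuple[list[PatentRecord], PlantedTruth]:
    """Draw a full synthetic corpus; byte-identical for identical specs.

    Yearly patent totals follow the exponential growth model (multinomial
    over years); each patent gets an office from the (possibly drifting)
    regional mix, a priority date uniform in its year, a filing date 0–3
    months later, a publication date 0–18 months after priority, and a
    without-replacement CID sample weighted by the planted hub/outlier
    structure. Family duplicates re-emit the same office+number with a grant
    kind code and a later publication date.
    """
    # independent substreams so adding one feature never shifts the others
    ss = np.random.SeedSequence(spec.seed)
    rng_counts, rng_regions, rng_dates, rng_cids, rng_kinds = (
        np.random.default_rng(s) for s in ss.spawn(5)
    )

    years = list(spec.years.years())
    n_years = len(years)
    intensity = spec.growth_rate ** np.arange(n_years, dtype=float)
    p_year = intensity / intensity.sum()
    per_year = rng_counts.multinomial(spec.n_patents, p_year)

    w = _cid_weight_matrix(spec)
    records: list[PatentRecord] = []
    patent_regions: list[str] = []
    office_counter: dict[str, int] = {}
    n_dup = 0

    for yi, (year, n_y) in enumerate(zip(years, per_year)):
        if n_y == 0:
            continue
        regions, probs = _region_probs(spec, yi)
        region_draws = rng_regions.choice(len(regions), size=n_y, p=probs)
        p_cid = w[:, yi] / w[:, yi].sum()
        year_start = date(year, 1, 1)
        days_in_year = (date(year + 1, 1, 1) - year_start).days
        for region_idx in region_draws:
            region = regions[region_idx]
            patent_regions.append(region)
            if region == "Other":
                office = OTHER_OFFICES[rng_regions.integers(len(OTHER_OFFICES))]
            else:
                office = REGION_OFFICE[region]
            office_counter[office] = office_counter.get(office, 0) + 1
            number = f"{office_counter[office]:07d}"

            m = min(spec.n_cids, 1 + rng_cids.poisson(spec.mean_cids_per_patent - 1.0))
            chosen = rng_cids.choice(spec.n_cids, size=m, replace=False, p=p_cid)
            cids = frozenset(int(c) + 1 for c in chosen)

            priority = year_start + timedelta(
                days=int(rng_dates.integers(days_in_year))
            )
            filing = priority + timedelta(days=int(rng_dates.integers(0, 91)))
            publication = priority + timedelta(
                days=int(rng_dates.integers(0, 549))  # up to ~18 months
            )
            records.append(
                PatentRecord(
                    identifier=PatentIdentifier(office, number, "A1"),
                    priority_date=priority,
                    filing_date=filing,
                    publication_date=publication,
                    cids=cids,
                )
            )
            if rng_kinds.random() < spec.duplicate_kind_prob:
                n_dup += 1
                grant_pub = publication + timedelta(
                    days=int(rng_kinds.integers(0, 731))
                )
                records.append(
                    PatentRecord(
                        identifier=PatentIdentifier(office, number, "B1"),
                        priority_date=priority,
                        filing_date=filing,
                        publication_date=grant_pub,
                        cids=cids,
                    )
                )

    # expected mention intensity: E[patents in year] * E[cids per patent]
    # * relative sampling weight (without-replacement treated as independent)
    expected_patents = spec.n_patents * p_year
    rel = w / w.sum(axis=0, keepdims=True)
    intensities = rel * expected_patents[None, :] * spec.mean_cids_per_patent

    truth = PlantedTruth(
        cids=tuple(range(1, spec.n_cids + 1)),
        years=spec.years,
        intensities=intensities,
        hub_cids=frozenset(spec.hub_cids),
        outlier_cids=dict(spec.outlier_cids),
        patent_regions=tuple(patent_regions),
        n_family_duplicates=n_dup,
    )
    return records, truth


def truth_series(truth: PlantedTruth, cid: int) -> np.ndarray:
    """The generator's expected yearly mention intensity for one CID."""
    if cid not in truth.cids:
        raise ValueError(f"cid {cid} not in corpus (1..{len(truth.cids)})")
    return truth.intensities[truth.cids.index(cid)].copy()


def planted_outlier_series(
    n_smooth: int = 50,
    n_years: int = 64,
    noise: float = 0.25,
    seed: int = 0,
) -> tuple[np.ndarray, int]:
    """Z-normalised series set with one planted abrupt-drop outlier.

    ``n_smooth`` smooth exponential-growth series (rates drawn in 2–8% per
    year) plus one series that grows until a mid-range year then collapses to
    5% of its level. Gaussian noise of the given standard deviation is added
    in normalised units. Returns (matrix of shape (n_smooth+1, n_years),
    row index of the planted outlier).
    """
    rng = np.random.default_rng(seed)
    t = np.arange(n_years, dtype=float)
    rows = []
    for _ in range(n_smooth):
        rate = rng.uniform(0.02, 0.08)
        rows.append(np.exp(rate * t))
    drop_at = int(rng.integers(n_years // 3, 2 * n_years // 3))
    atypical = np.exp(0.05 * t)
    atypical[drop_at:] *= 0.05
    rows.append(atypical)
    raw = np.array(rows)
    mean = raw.mean(axis=1, keepdims=True)
    std = raw.std(axis=1, keepdims=True)
    z = (raw - mean) / std
    z += rng.normal(0.0, noise, size=z.shape)
    outlier_index = n_smooth
    # shuffle rows so the outlier is not always last
    order = rng.permutation(n_smooth + 1)
    return z[order], int(np.where(order == outlier_index)[0][0])
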