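"""Optional online layer: per-CID patent identifiers, compound info and
literature references from PubChem, with a verbatim response cache.

Every raw response is persisted to the cache before parsing, keyed by
(endpoint, cid, page), so parser changes can be re-run without refetching and
the whole stack runs offline from cached fixtures. Requests are rate-limited
(PubChem asks for no more than ~5 requests per second) and retried with
exponential backoff before failing hard. Pagination is transparent; a partial
page failure aborts the whole fetch rather than silently truncating counts.
"""

from __future__ import annotations

import json
import logging
import time
import urllib.error
import urllib.parse
import urllib.request
from dataclasses import dataclass
from datetime import date
from pathlib import Path

from .patent_core import PatentParseError, PatentRecord, parse_patent_identifier

__all__ = [
    "CompoundInfo",
    "LiteratureReference",
    "PubChemClient",
    "PubChemError",
    "OfflineCacheMiss",
    "fetch_patent_records",
    "fetch_compound_info",
    "fetch_literature_years",
    "default_cache_dir",
]

logger = logging.getLogger(__name__)

PUG_REST = "https://pubchem.ncbi.nlm.nih.gov/rest/pug"
SDQ_AGENT = "https://pubchem.ncbi.nlm.nih.gov/sdq/sdqagent.cgi"

PAGE_SIZE = 10_000


class PubChemError(RuntimeError):
    """Unrecoverable fetch or parse failure."""


class OfflineCacheMiss(PubChemError):
    """Offline mode was requested but the cache holds no response for the CID."""


@dataclass(frozen=True)
class CompoundInfo:
    """Name, formula and service-reported patent/literature counts for a CID."""

    cid: int
    name: str
    molecular_formula: str
    patent_count: int
    literature_count: int

    def __post_init__(self) -> None:
        if self.cid < 1:
            raise ValueError(f"invalid cid {self.cid}")
        if self.patent_count < 0 or self.literature_count < 0:
            raise ValueError("counts must be nonnegative")


@dataclass(frozen=True)
class LiteratureReference:
    """One consolidated reference; year absent when the source omits it."""

    refid: str
    year: int | None = None

    def __post_init__(self) -> None:
        if self.year is not None and not 1800 <= self.year <= 2100:
            raise ValueError(f"implausible reference year {self.year}")


def default_cache_dir() -> Path:
    return Path.home() / ".cache" / "chemstripes"


class PubChemClient:
    """Cached PubChem access; set ``offline=True`` to forbid network use."""

    def __init__(
        self,
        cache_dir: str | Path | None = None,
        offline: bool = False,
        rate_limit: float = 5.0,
        max_retries: int = 3,
        timeout: float = 30.0,
    ) -> None:
        self.cache_dir = Path(cache_dir) if cache_dir else default_cache_dir()
        self.offline = offline
        self.min_interval = 1.0 / rate_limit if rate_limit > 0 else 0.0
        self.max_retries = max_retries
        self.timeout = timeout
        self._last_request = 0.0
        self.skipped_identifiers = 0

    # -- caching / transport ------------------------------------------------

    def _cache_path(self, endpoint: str, cid: int, page: int = 1) -> Path:
        return self.cache_dir / endpoint / f"cid{cid}_page{page}.json"

    def _fetch_url(self, url: str) -> str:
        wait = max(0.0, self._last_request + self.min_interval - time.monotonic())
        if wait:
            time.sleep(wait)
        delay = 1.0
        for attempt in range(self.max_retries):
            self._last_request = time.monotonic()
            try:
                with urllib.request.urlopen(url, timeout=self.timeout) as resp:
                    return resp.read().decode("utf-8")
            except (urllib.error.URLError, TimeoutError) as exc:
                if attempt == self.max_retries - 1:
                    raise PubChemError(f"fetch failed for {url}: {exc}") from exc
                logger.warning("retrying %s after error: %s", url, exc)
                time.sleep(delay)
                delay *= 2.0
        raise PubChemError(f"fetch failed for {url}")  # pragma: no cover

    def _get(self, endpoint: str, cid: int, url: str, page: int = 1) -> dict:
        path = self._cache_path(endpoint, cid, page)
        if path.exists():
            return json.loads(path.read_text())
        if self.offline:
            raise OfflineCacheMiss(
                f"offline mode: no cached {endpoint} response for cid {cid} "
                f"(expected {path})"
            )
        body = self._fetch_url(url)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(body)  # persist verbatim before parsing
        return json.loads(body)

    def _sdq_pages(self, endpoint: str, collection: str, cid: int,
                   fields: list[str]) -> list[dict]:
        """Collect all rows of a paginated SDQ table query."""
        rows: list[dict] = []
        page = 1
        while True:
            query = {
                "select": fields,
                "collection": collection,
                "where": {"ands": [{"cid": str(cid)}]},
                "start": (page - 1) * PAGE_SIZE + 1,
                "limit": PAGE_SIZE,
            }
            url = (
                f"{SDQ_AGENT}?infmt=json&outfmt=json&query="
                + urllib.parse.quote(json.dumps(query))
            )
            obj = self._get(endpoint, cid, url, page)
            try:
                out = obj["SDQOutputSet"][0]
                total = int(out.get("totalCount", 0))
                rows.extend(out.get("rows", []))
            except (KeyError, IndexError, TypeError) as exc:
                raise PubChemError(
                    f"unexpected {endpoint} response shape for cid {cid}: {exc}"
                ) from exc
            if len(rows) >= total or not out.get("rows"):
                return rows
            page += 1

    def _sdq_total(self, endpoint: str, collection: str, cid: int) -> int:
        query = {
            "select": ["cid"], "collection": collection,
            "where": {"ands": [{"cid": str(cid)}]}, "start": 1, "limit": 1,
        }
        url = (
            f"{SDQ_AGENT}?infmt=json&outfmt=json&query="
            + urllib.parse.quote(json.dumps(query))
        )
        obj = self._get(f"{endpoint}_count", cid, url)
        try:
            return int(obj["SDQOutputSet"][0]["totalCount"])
        except (KeyError, IndexError, TypeError) as exc:
            raise PubChemError(
                f"unexpected count response for cid {cid}: {exc}"
            ) from exc

    # -- public API ---------------------------------------------------------

    def fetch_patent_records(self, cid: int) -> list[PatentRecord]:
        """Depositor-supplied patent identifiers with dates for one CID.

        Unparseable identifiers and dateless rows are skipped with a logged
        warning and counted in ``skipped_identifiers``.
        """
        if cid < 1:
            raise ValueError(f"invalid cid {cid}")
        rows = self._sdq_pages(
            "patent", "patent", cid,
            ["patentid", "prioritydate", "filingdate", "publicationdate"],
        )
        records: list[PatentRecord] = []
        for row in rows:
            try:
                identifier = parse_patent_identifier(row["patentid"])
                dates = {
                    f"{role}_date": date.fromisoformat(row[key][:10])
                    for role, key in (
                        ("priority", "prioritydate"),
                        ("filing", "filingdate"),
                        ("publication", "publicationdate"),
                    )
                    if row.get(key)
                }
                records.append(
                    PatentRecord(identifier=identifier, cids=frozenset({cid}),
                                 **dates)
                )
            except (PatentParseError, KeyError, ValueError) as exc:
                self.skipped_identifiers += 1
                logger.warning(
                    "cid %d: skipping unparseable patent row %r (%s)",
                    cid, row.get("patentid"), exc,
                )
        return records

    def fetch_compound_info(self, cid: int) -> CompoundInfo:
        """Preferred name, Hill formula and service-reported counts.

        Counts are taken as reported by the service (table totals), not
        recomputed from fetched rows.
        """
        if cid < 1:
            raise ValueError(f"invalid cid {cid}")
        url = f"{PUG_REST}/compound/cid/{cid}/property/Title,MolecularFormula/JSON"
        obj = self._get("compound", cid, url)
        try:
            props = obj["PropertyTable"]["Properties"][0]
        except (KeyError, IndexError, TypeError) as exc:
            raise PubChemError(
                f"unexpected compound response for cid {cid}: {exc}"
            ) from exc
        return CompoundInfo(
            cid=cid,
            name=str(props.get("Title", "")),
            molecular_formula=str(props.get("MolecularFormula", "")),
            patent_count=self._sdq_total("patent", "patent", cid),
            literature_count=self._sdq_total("refs", "consolidatedcompoundliterature", cid),
        )

    def fetch_literature_years(self, cid: int) -> list[LiteratureReference]:
        """Consolidated references with publication years (absent years kept)."""
        if cid < 1:
            raise ValueError(f"invalid cid {cid}")
        rows = self._sdq_pages(
            "refs", "consolidatedcompoundliterature", cid, ["refid", "year"]
        )
        refs = []
        for row in rows:
            year = row.get("year")
            refs.append(
                LiteratureReference(
                    refid=str(row.get("refid", "")),
                    year=int(year) if year not in (None, "") else None,
                )
            )
        return refs


# module-level conveniences mirroring the client methods

def fetch_patent_records(cid: int, cache_dir: str | Path | None = None,
                         offline: bool = False) -> list[PatentRecord]:
    return PubChemClient(cache_dir, offline=offline).fetch_patent_records(cid)


def fetch_compound_info(cid: int, cache_dir: str | Path | None = None,
                        offline: bool = False) -> CompoundInfo:
    return PubChemClient(cache_dir, offline=offline).fetch_compound_info(cid)


def fetch_literature_years(cid: int, cache_dir: str | Path | None = None,
                           offline: bool = False) -> list[LiteratureReference]:
    return PubChemClient(cache_dir, offline=offline).fetch_literature_years(cid)
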