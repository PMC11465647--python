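import json
from datetime import date

import pytest

from chemstripes.patent_core import PatentIdentifier, PatentRecord
from chemstripes.synthetic import CorpusSpec, generate_corpus


def record(raw: str, cids={1}, priority=None, filing=None, publication=None):
    """Terse record builder for hand-written cases."""
    office, number, kind = raw.split("-")
    if priority is None and filing is None and publication is None:
        priority = date(2000, 1, 1)
    return PatentRecord(
        identifier=PatentIdentifier(office, number, kind),
        priority_date=priority,
        filing_date=filing,
        publication_date=publication,
        cids=frozenset(cids),
    )


@pytest.fixture(scope="session")
def small_corpus():
    """1,000 patents x 200 CIDs with hubs, outliers and kind duplicates."""
    spec = CorpusSpec(
        n_cids=200,
        n_patents=1000,
        hub_cids=frozenset({5, 6, 7}),
        outlier_cids={10: ("abrupt_drop", 2001), 11: ("peak", 1990)},
        seed=42,
    )
    records, truth = generate_corpus(spec)
    return spec, records, truth


@pytest.fixture
def pubchem_cache(tmp_path):
    """Warm cache directory with fixture responses for CIDs 9554 and 26255.

    CID 9554's patent table deliberately contains one malformed identifier
    and CID 26255's reference table one undated reference.
    """
    def sdq(rows, total=None):
        return json.dumps(
            {"SDQOutputSet": [{"totalCount": total if total is not None
                               else len(rows), "rows": rows}]}
        )

    cache = tmp_path / "cache"
    (cache / "patent").mkdir(parents=True)
    (cache / "patent" / "cid9554_page1.json").write_text(sdq([
        {"patentid": "US-1257524-A", "prioritydate": "1913-01-28",
         "publicationdate": "1918-02-26"},
        {"patentid": "EP-0000001-B1", "prioritydate": "1999-05-01",
         "filingdate": "1999-06-01", "publicationdate": "2000-09-01"},
        {"patentid": "PFOS", "prioritydate": "1950-01-01"},  # malformed
    ]))
    (cache / "patent_count").mkdir()
    (cache / "patent_count" / "cid26255_page1.json").write_text(sdq([], total=7))
    (cache / "refs").mkdir()
    (cache / "refs" / "cid26255_page1.json").write_text(sdq([
        {"refid": "r1", "year": 1999},
        {"refid": "r2", "year": 1999},
        {"refid": "r3", "year": 2001},
        {"refid": "r4"},  # undated, retained
    ]))
    (cache / "refs_count").mkdir()
    (cache / "refs_count" / "cid26255_page1.json").write_text(sdq([], total=4))
    (cache / "compound").mkdir()
    (cache / "compound" / "cid26255_page1.json").write_text(json.dumps(
        {"PropertyTable": {"Properties": [
            {"CID": 26255, "Title": "Tetrafluoroborate",
             "MolecularFormula": "BF4-"}
        ]}}
    ))
    return cache
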