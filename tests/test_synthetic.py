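"""Generator determinism, planted structure and end-to-end recovery."""

import numpy as np
import pytest
from scipy import stats

from chemstripes.patent_core import dedupe_records, write_records
from chemstripes.stripes import YearRange, bin_counts
from chemstripes.synthetic import (
    CorpusSpec,
    generate_corpus,
    planted_outlier_series,
    truth_series,
)


class TestSpecValidation:
    def test_infeasible_mean_cids_rejected(self):
        with pytest.raises(ValueError, match="infeasible"):
            CorpusSpec(n_cids=2, mean_cids_per_patent=5.0)

    def test_bad_outlier_pattern_rejected(self):
        with pytest.raises(ValueError, match="pattern"):
            CorpusSpec(outlier_cids={1: ("linear", 2000)})

    def test_out_of_range_hub_rejected(self):
        with pytest.raises(ValueError):
            CorpusSpec(n_cids=10, hub_cids=frozenset({11}))

    def test_json_roundtrip(self, tmp_path):
        path = tmp_path / "spec.json"
        path.write_text(
            '{"n_cids": 20, "n_patents": 50, "years": [1990, 2000],'
            ' "hub_cids": [1, 2], "outlier_cids": {"3": ["peak", 1995]},'
            ' "seed": 9}'
        )
        spec = CorpusSpec.from_json(path)
        assert spec.years == YearRange(1990, 2000)
        assert spec.hub_cids == {1, 2}
        assert spec.outlier_cids == {3: ("peak", 1995)}


class TestDeterminism:
    def test_same_seed_byte_identical_corpus(self, tmp_path):
        spec = CorpusSpec(n_cids=50, n_patents=200, seed=3)
        a, _ = generate_corpus(spec)
        b, _ = generate_corpus(spec)
        pa = write_records(a, tmp_path / "a.ndjson")
        pb = write_records(b, tmp_path / "b.ndjson")
        assert pa.read_bytes() == pb.read_bytes()

    def test_different_seed_differs(self):
        a, _ = generate_corpus(CorpusSpec(n_cids=50, n_patents=200, seed=3))
        b, _ = generate_corpus(CorpusSpec(n_cids=50, n_patents=200, seed=4))
        assert a != b


class TestCorpusStructure:
    def test_no_duplicates_makes_dedupe_modes_coincide(self):
        spec = CorpusSpec(n_cids=30, n_patents=300, duplicate_kind_prob=0.0,
                          seed=1)
        records, _ = generate_corpus(spec)
        assert dedupe_records(records, "family") == dedupe_records(
            records, "publication"
        )

    def test_family_duplicates_counted_in_truth(self):
        spec = CorpusSpec(n_cids=30, n_patents=300, duplicate_kind_prob=0.5,
                          seed=1)
        records, truth = generate_corpus(spec)
        assert len(records) == spec.n_patents + truth.n_family_duplicates
        assert truth.n_family_duplicates > 0
        fam = dedupe_records(records, "family")
        assert len(fam) == spec.n_patents

    def test_publication_lag_within_18_months(self):
        records, _ = generate_corpus(CorpusSpec(n_cids=20, n_patents=200, seed=2))
        for r in records:
            lag = (r.publication_date - r.priority_date).days
            if r.identifier.kind == "A1":
                assert 0 <= lag <= 548  # up to ~18 months
            else:
                assert 0 <= lag <= 548 + 730  # grants publish up to 2 y later

    def test_flat_growth_yields_uniform_years(self):
        # chi-square goodness of fit against the uniform year distribution,
        # pooled over seeds; p must not be catastrophically small
        spec_years = YearRange(2000, 2009)
        pooled = np.zeros(10)
        for seed in range(20):
            spec = CorpusSpec(n_cids=20, n_patents=500, years=spec_years,
                              growth_rate=1.0, duplicate_kind_prob=0.0,
                              seed=seed)
            records, _ = generate_corpus(spec)
            yc = bin_counts(records, spec_years)
            pooled += yc.values()
        p = stats.chisquare(pooled).pvalue
        assert p > 0.001

    def test_region_frequencies_match_weights(self):
        weights = {"US": 0.5, "China": 0.3, "Japan": 0.2}
        spec = CorpusSpec(n_cids=20, n_patents=2000, region_weights=weights,
                          region_drift=None, duplicate_kind_prob=0.0, seed=6)
        _, truth = generate_corpus(spec)
        counts = {r: truth.patent_regions.count(r) for r in weights}
        expected = [weights[r] * spec.n_patents for r in sorted(weights)]
        observed = [counts[r] for r in sorted(weights)]
        assert stats.chisquare(observed, expected).pvalue > 0.001

    def test_region_drift_shifts_mix_over_time(self):
        spec = CorpusSpec(n_cids=20, n_patents=3000,
                          region_drift={"China": 1.06}, seed=8)
        records, _ = generate_corpus(spec)
        early = [r for r in records if r.priority_date.year < 1990]
        late = [r for r in records if r.priority_date.year >= 2010]
        frac = lambda recs: sum(
            r.identifier.office == "CN" for r in recs) / len(recs)
        assert frac(late) > frac(early)


class TestTruthSeries:
    def test_abrupt_drop_reshapes_intensity(self):
        spec = CorpusSpec(n_cids=20, n_patents=100,
                          outlier_cids={4: ("abrupt_drop", 2001)}, seed=0)
        _, truth = generate_corpus(spec)
        series = truth_series(truth, 4)
        years = np.array(list(spec.years.years()))
        before = series[years == 2000][0]
        after = series[years == 2001][0]
        # growth alone moves intensity by ~3%; the planted drop dominates
        assert after < before * 0.1

    def test_smooth_cid_monotone_growth(self):
        spec = CorpusSpec(n_cids=20, n_patents=100, growth_rate=1.05, seed=0)
        _, truth = generate_corpus(spec)
        series = truth_series(truth, 1)
        assert (np.diff(series) > 0).all()

    def test_unknown_cid_rejected(self):
        _, truth = generate_corpus(CorpusSpec(n_cids=5, n_patents=10, seed=0))
        with pytest.raises(ValueError):
            truth_series(truth, 99)

    def test_total_intensity_matches_expected_mentions(self):
        spec = CorpusSpec(n_cids=50, n_patents=400, seed=0)
        records, truth = generate_corpus(spec)
        assert truth.intensities.sum() == pytest.approx(
            spec.n_patents * spec.mean_cids_per_patent
        )


def test_end_to_end_recovery_binned_counts_track_truth():
    """Observed per-CID yearly counts correlate with planted intensities.

    Sized so sampling noise does not swamp the yearly growth signal: 20 CIDs
    sharing 20,000 patents gives roughly 1,500 mentions per CID over 64
    years. Both a smooth-growth CID and a planted abrupt-drop CID must track
    their true intensity curves (Pearson r > 0.9) in nearly all seeds.
    """
    ok = 0
    seeds = range(8)
    for seed in seeds:
        spec = CorpusSpec(n_cids=20, n_patents=20_000, seed=seed,
                          duplicate_kind_prob=0.0,
                          outlier_cids={7: ("abrupt_drop", 1995)})
        records, truth = generate_corpus(spec)
        r_values = []
        for cid in (1, 7):
            mine = [r for r in records if cid in r.cids]
            observed = bin_counts(mine, spec.years).values()
            expected = truth_series(truth, cid)
            r_values.append(stats.pearsonr(observed, expected).statistic)
        if all(r > 0.9 for r in r_values):
            ok += 1
    assert ok >= len(seeds) - 1


def test_planted_outlier_series_shape_and_determinism():
    a, idx_a = planted_outlier_series(n_smooth=20, seed=5)
    b, idx_b = planted_outlier_series(n_smooth=20, seed=5)
    np.testing.assert_array_equal(a, b)
    assert idx_a == idx_b
    assert a.shape == (21, 64)
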