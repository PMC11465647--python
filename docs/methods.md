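# Methods

## Data model

A patent *publication* is identified as `OFFICE-NUMBER-KIND`: a two-letter
office code, a digit string (leading zeros significant), and a kind code of
one letter plus an optional digit (`A`, `A1`, `B2`, ...). Kind codes mark
publication stages — application, grant, re-examination — of one invention,
so several publications can share an office+number *family*. Parsing is
strict: any string not matching that shape is rejected with an error naming
the offending value rather than coerced, because patent corpora extracted by
text mining contain misrecognised tokens (chemical names inside inventor
surnames, for example) and silent coercion would launder them into counts.

Each record carries up to three dates. Year assignment walks a configurable
preference order, default `(priority, filing, publication)`: the priority
date is the earliest claim and best reflects when the invention happened,
but it is reported with a lag of up to ~18 months and is sometimes absent,
so filing and publication act as fallbacks instead of dropping the record.

Deduplication has two modes. `publication` (default) counts each deposited
identifier once — the natural granularity of per-compound patent-identifier
lists. `family` collapses office+number families, counting inventions
rather than documents. In both modes the surviving record carries the
earliest date under the active preference and the union of linked CIDs;
survivors are emitted sorted by (office, number, kind) for reproducibility.
Which mode a published count used is often unknowable, so both are exposed
and recorded in outputs. Records with no usable date or a year outside the
requested range are excluded *at binning time*, and the exclusion count is
reported alongside every per-year table, so one parsed corpus serves any
date range and `sum(counts) + excluded == deduplicated total` always holds.

## Stripes

Counts are mapped to colors by linear min–max normalisation *per chemical*
over the displayed range: the minimum-count year gets the low palette
endpoint, the maximum the high endpoint, and a constant series (including
all zeros) renders entirely at the low endpoint. Consequences, documented
deliberately:

- colors are not comparable across chemicals (each plot spans the full
  palette regardless of absolute magnitude);
- normalisation uses the displayed range, not the full data range, so
  cropping the range can recolor the remaining years.

The default palette is a traffic-light ramp green `#008000` → yellow
`#ffff00` (pinned at the 50% point) → red `#ff0000`; the colorblind variant
is blue `#0000ff` → red `#ff0000`. Years with zero patents are ordinary
minimum-count years, not "no data": genuinely unusable records are visible
only through the logged exclusion count, since the figure itself does not
distinguish the two cases.

## Regional attribution

Identifiers encode the *publishing office*, not inventor locations, so the
office code is the operational proxy for region: US→US, EP→Europe,
JP→Japan, CN→China, KR→Korea, WO→WIPO, everything else →Other (the map is
total; a custom JSON map can redirect national European offices into Europe
if desired — by default only EP counts as Europe). Analyses phrased as
"by region" elsewhere may have used inventor geography; this package does
not guess at that and states the office-code caveat here instead. WIPO
folding into Other is a flag: default on for breakdown plots (five focus
regions + Other), off for top-office rankings where WO is informative.

Because each patent has exactly one office, the year × region breakdown is
a partition: every dated in-range deduplicated record contributes to exactly
one cell, rows sum to yearly totals, and the grand total plus exclusions
equals the deduplicated record count. Region-exclusive queries use *exact*
signature matching — a CID qualifies for subset S only if it has ≥1 patent
in every member of S and none anywhere else — which makes the nonempty
subset cells of any k regions pairwise disjoint and a cover of all CIDs
whose signature lies within those regions.

## Co-occurrence networks and centrality

The patent–CID incidence is projected onto the CID list: for each
deduplicated patent (optionally restricted to one region first) every
unordered pair of its listed CIDs gains +1 edge weight. All list CIDs stay
as nodes even when isolated, so list coverage is visible; total edge weight
equals Σ over patents of C(m, 2) with m the patent's listed CIDs, a
conservation law used in the tests. Patents mentioning a single listed CID
create no edges (the restriction is mathematically equivalent to filtering
them out beforehand).

Degree centrality is reported in both unweighted (neighbor count) and
weighted ("strength", incident-weight sum) variants; the variant used is
recorded in the result object. PageRank runs on the weighted undirected
graph, each edge acting as two directed arcs with transition probability
proportional to weight; isolated nodes are dangling and redistribute their
mass uniformly. The implementation is sparse power iteration,
`x ← (1−d)/n + d(Wᵀ(x/s) + dangling_mass/n)`, with damping d = 0.85 (the
canonical choice), L1 stopping tolerance 1e-10, and a 200-iteration cap
that raises an error reporting the residual instead of returning an
unconverged vector; scores are renormalised to sum exactly to 1. The test
suite checks it against an independent dense Google-matrix iteration rather
than against itself. Top-k extraction sorts by descending score with ties
broken by ascending CID, so rankings are reproducible.

## Series clustering and outliers

Shape, not magnitude, distinguishes an atypical patent history, so rows are
z-normalised (population standard deviation; a constant row has no shape
and maps to the zero vector, flagged so downstream code can ignore or
report it — this also keeps zero-variance rows from producing NaNs).
Clustering is Euclidean k-means with k-means++ initialisation, 10 restarts
keeping the lowest inertia, and an explicit seed, making runs deterministic
and auditable; k, seed, distance and inertia are recorded in the result.
When k is unspecified it is chosen by maximal mean silhouette over 2–8.
These are explicit design choices, not reconstructions of any published
pipeline, and simpler alternatives were preferred throughout (no
dynamic-time-warping distance, no change-point models).

The outlier score of a series is the Euclidean distance to its cluster
centroid. One guard: a singleton cluster's member *is* its centroid and
would score 0, hiding exactly the strongest outliers (k-means++ likes to
seed far-away points); singleton members are therefore scored by distance
to the nearest *other* centroid. For clusters of size ≥ 2 the score is zero
iff the series equals its centroid exactly.

## Synthetic corpus generator

The generator emulates the structures the analyses are meant to detect:

- **Growth**: yearly patent totals are multinomial over the range with
  intensity ∝ `growth_rate^(year − start)`; default 1.03 (≈3%/yr, a typical
  long-run patenting growth rate).
- **Regions**: each patent draws a region from a weight map (defaults
  roughly matching the data richness of the major offices: US 0.30,
  Europe 0.20, Japan 0.15, China 0.12, Korea 0.08, WIPO 0.10, Other 0.05);
  an optional per-region yearly drift multiplier (default China ×1.04/yr,
  renormalised) emulates the shifting mix. Other-region patents draw an
  office uniformly from CA/AU/BR/IN/RU.
- **Dates**: priority uniform within the patent's year; filing 0–3 months
  later; publication 0–18 months after priority, mirroring the real
  priority-to-publication lag so date-preference differences are visible.
- **Families**: with probability `duplicate_kind_prob` (default 0.1) a
  patent emits a second publication of the same family (kind B1, later
  publication date), so publication- and family-mode counts differ.
- **Hubs**: hub CIDs are sampled with `hub_boost` (default 10×) the
  background weight, concentrating co-mentions on them.
- **Outliers**: an `abrupt_drop(year)` CID's sampling weight falls to
  `drop_factor` (default 0.05) from that year on; a `peak(year)` CID gets a
  Gaussian bump (height 8, width 2 years). CIDs per patent:
  1 + Poisson(mean − 1), default mean 3, sampled without replacement.

All randomness flows from one seed through independent spawned substreams
(counts, regions, dates, CID sampling, kind duplication), so adding a
feature never shifts the other draws and identical specs give byte-identical
corpora. The exposed truth includes per-CID expected yearly mention
intensities (treating without-replacement sampling as independent — accurate
for mean_cids ≪ n_cids), hub and outlier membership, true regions, and the
family-duplicate count.

What the generator does **not** emulate: patent text (titles, abstracts),
name-misrecognition artifacts, depositor discontinuities ("blips"),
cross-office families, or the incompleteness of recent years. Passing tests
therefore demonstrate the correctness of the computations on data with the
modeled structures, not robustness to those real-data artifacts.

A lighter series-level generator (`planted_outlier_series`) produces 50
smooth exponential-growth series (rates 2–8%/yr over 64 years) plus one
abrupt-drop series, z-normalised with Gaussian noise σ = 0.25 in normalised
units, for outlier-recovery measurements without a full corpus.

## Verification problem sizes

The verification script and acceptance-style tests use: 100 random weighted
graphs of ≤50 nodes for the PageRank oracle comparison (max |Δ| < 1e-8);
one 1,000-patent × 200-CID corpus for exact co-occurrence weight checks;
100 seeded 1,000-patent corpora with 3 planted 10×-boost hubs for strength
recovery (≥95% required); 50 seeded runs of the 51-series outlier setting
(≥90% top-1 required); and a 2,000-patent corpus for the conservation
suite. The end-to-end intensity-recovery property test uses 20 CIDs sharing
20,000 patents, sized so that Poisson counting noise (≈√λ per year) is
small against the growth signal and Pearson r > 0.9 is achievable per CID.

## Limitations

- Office codes are a proxy for region; inventor geography is out of scope.
- Only office+number families are collapsed; cross-office (INPADOC-style)
  families are not resolved, so the same invention filed in several
  countries counts once per office.
- Patent title/abstract text, name-recognition scoring and artifact
  correction are upstream of this package.
- Centrality rankings are context-dependent and sensitive to small network
  changes; they order chemicals for inspection, they do not measure
  importance in any causal sense.
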