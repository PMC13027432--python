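# Methods

`ptmatlas` analyzes residue-level post-translational modification (PTM)
annotations on a cohort of enzymes. This note documents the models,
conventions, and numerical choices the package holds fixed, and what the
bundled synthetic cohorts do and do not emulate.

## Coordinates and harmonization

All positions are 1-based and all intervals (windows, regions) are closed,
following UniProt convention. Harmonization groups raw records by exact
(accession, position, modification type). Detection counts sum across
sources, with every contributing source record counting at least one
report; a source dialect without study counts therefore contributes 1 per
row, and sites are retained regardless of how many studies support them.
Records whose annotated residue conflicts with the reference sequence at
that position are excluded and itemized with a reason code rather than
remapped: the package cannot reproduce the isoform or release drift that
produced the conflict, so silent remapping would manufacture data.
Conflicting functional notes across sources are all kept, pipe-joined in
sorted order. Because `harmonize_sites` also accepts already-harmonized
sites (contributing their full detection count and source set), the
operation is exactly idempotent and invariant to input order.

The PTM-type vocabulary ships 27 canonical type names with a synonym
table; unknown spellings pass through lower-cased and flagged
nonstandard, never silently reclassified.

## Enzyme-level metrics

* **PTM density** = unique (position, type) records / sequence length.
  Modification-specific densities partition it exactly: summed over
  types they equal the total, which is asserted as a property test.
* **PTM potentiality rate (PPR)** = unique sites of a type / residues
  chemically eligible for that type. "Observed events" is interpreted
  as unique sites (not cumulative detections) for consistency with the
  density numerator. When a sequence has no eligible residue the value
  is undefined (`None`/NaN), which propagates as missing — it is only
  imputed (as 0, with a missingness report) when the clustering matrix
  must be complete, on the reasoning that no eligible residue means no
  modification capacity. The default eligibility map follows standard
  residue chemistry (S/T/Y phosphorylation; K acetylation,
  ubiquitination, sumoylation, neddylation and the acyl marks; K/R
  methylation; C for the cysteine chemistries; M sulfoxidation;
  N N-glycosylation; S/T O-glycosylation; P/K hydroxylation); types
  outside the table fall back to the residues actually observed for
  that type in the catalog. The map is config-overridable.
* **Predominant sites**: per enzyme and PTM type, sites are ranked by
  detection count descending with ties broken by ascending position
  (for determinism), and accumulated until the cumulative count first
  reaches the threshold fraction (default 60%) of total detections; the
  crossing site is included. Because the ranking is independent of the
  threshold, predominant sets nest across thresholds, and the 50/60/70%
  sensitivity scan reports per-enzyme counts, Spearman rank agreement
  between thresholds, and top-decile overlap.
* **Quartiles** use the linear-interpolation convention between order
  statistics; quartile values are convention-sensitive, so the
  convention is fixed here and in the tests. The right-skew indicator
  is simply mean > median.

## Sequence architecture

* **Hotspots**: the window around each site spans seven residues
  upstream and downstream, clipped to the sequence. A window qualifies
  when it holds at least five unique (position, type) records besides
  the central record itself — a dual-modified residue contributes two,
  and only the central record (not co-located records) is excluded.
  Qualifying windows that share residues are merged; each maximal
  merged interval is one hotspot region. Note that the merged-region
  count is *not* monotone in the neighbor threshold: lowering it can
  bridge two regions into one. The monotone quantities (qualifying
  seeds, covered extent) are what the property tests assert.
* **Crosstalk**: the headline definition is residue-level — a single
  position carrying two or more distinct PTM types. A window mode
  (±7 residues, the same window as hotspots) is provided for the looser
  "within or near the same window" reading; "near" is otherwise
  undefined, so the same half-window is reused and documented as an
  interpretation.
* **Localization** is multi-label: a site receives every region type
  covering its position, with `unannotated` only when none does. The
  per-region-type enrichment table reports observed sites, covered
  residues, and in-region vs out-of-region site rates independently per
  label (region types overlap, so no precedence hierarchy is imposed).
* **Variant overlap** joins variant positions to PTM-bearing positions;
  each overlapped position records its variant records and whether any
  is missense.

## Statistics

Spearman correlations use midrank ties with p-values from the
large-sample t approximation, missing values deleted pairwise (never
imputed). Mann-Whitney U is oriented on the first group (pairs won plus
half ties). For combined samples of 16 or fewer the two-sided p-value is
computed by exhaustive enumeration of all group assignments of the
pooled sample — valid under ties, with extremeness defined symmetrically
as |U − n_a·n_b/2| — and larger samples use the tie-corrected normal
approximation. The switch point is arbitrary but documented and fixed.
Benjamini-Hochberg adjustment is applied per analysis family (one
correlation matrix, one contrast family, one enrichment run). Pathway
enrichment is an upper-tail hypergeometric test with the full cohort as
background.

## Clustering

The feature matrix concatenates three blocks with recorded provenance:
numeric metrics (z-scored after filtering), TF-IDF text features over
the concatenated descriptors (raw term counts, idf = ln((1+N)/(1+df))+1,
rows L2-normalized, minimum document frequency 2, tokenized on
non-alphanumerics after lower-casing), and one-hot pathway/EC-class
indicators. Only the numeric block is z-scored; the TF-IDF rows are
already unit-norm and the one-hot block keeps its 0/1 scale (a global
scaling flag exists for sensitivity checks). Zero-variance columns and
columns nonzero in fewer than 1% of rows are dropped, with every drop
logged. Clustering (Ward on Euclidean distance, and seeded k-means++
with 10 restarts) runs on the full filtered matrix; k is selected by the
mean silhouette over k = 2–10 for the configured method. PCA is
computed for visualization only and never feeds back into clustering;
component signs are not identified, so determinism is asserted up to
sign.

## The synthetic cohort generator

The generator emulates the statistical shape of a real multi-database
PTM catalog without using one:

* **Burden**: a per-enzyme site rate drawn from a gamma family drives a
  binomial placement over eligible residues, with at most one base type
  per residue so that multi-type residues arise only from explicit
  crosstalk injection (hence `crosstalk_rate = 0` implies none). The
  default gamma shape (14) keeps within-group burden concentrated
  (CV ≈ 0.27); the strong cohort-level right skew is carried by the
  planted two-group mixture — a PTM-enriched minority (default 15% of
  enzymes at 3× density, burst and crosstalk rates) against a sparse
  majority — which mirrors the view that dense PTM regulation
  concentrates on a discrete enzyme subset rather than spreading as a
  long within-group tail.
* **Hotspots** come from planted bursts (Poisson number per enzyme,
  dense placement inside a 15-residue window), recorded in the truth
  object so recovery is testable against known locations. Bursts with
  six or more realized sites are the positive controls; about 90% of
  them intersect a detected hotspot (a six-site burst spread across the
  full window can legitimately fail the five-neighbor rule).
* **Detection counts** are geometric (heavy-tailed); sources are random
  subsets of three database tags; per-site functional notes appear at a
  low rate.
* **Domains**: 2–3 non-overlapping intervals each spanning 12–20% of
  the sequence. Site placement is biased so the expected in-domain site
  fraction equals the configured target (default 0.40) via
  probability-weighted zone rescaling with per-residue probabilities
  capped at 0.95; a few proportional-fitting rounds let unclipped
  residues absorb the capped mass so the target holds in expectation.
* **Tracks and labels**: variants land on PTM positions at the overlap
  rate (predominantly missense) and elsewhere at a background rate;
  pathway labels are drawn from group-specific pools with mild
  cross-contamination, with the "core" label attached to enriched
  enzymes at 0.8 versus 0.05 for sparse ones; rate-limiting flags
  (default 8% of the cohort) are a subset of the enriched group;
  mitochondrial flags are independent. Text descriptors mix
  group-specific and shared vocabulary plus domain names.

Everything is reproducible from the single config seed, and the
generator records its own conditional placement expectation (sum of
per-residue probabilities) so the binomial machinery can be audited
directly.

What the generator does **not** emulate: realistic sequence evolution
or composition bias, mass-spectrometry noise and enrichment-protocol
bias, isoforms, correlated annotation depth between databases, or any
real pathway topology. Passing tests therefore demonstrate that the
pipeline's operations are correct and that planted structure of the
stated strength is recoverable — not that real cohorts contain such
structure.

## Problem sizes and runtime choices

Tests run the full pipeline at two scales chosen as representative:
200 enzymes for oracle-equivalence and property suites, and 771 enzymes
(a full metabolic-enzyme catalog scale) for planted-structure recovery.
The type-I calibration uses 500 independent replicates of 200-enzyme
null cohorts (multiplier 1) and checks the pooled nominal p < 0.05 rate
against binomial 99% bounds computed at the replicate count, which is
conservative given within-replicate dependence between feature
contrasts.

## Known limitations

* Residue-mismatch exclusion discards sites that a release-aware
  lift-over could rescue; the rejection report quantifies the loss.
* The hotspot merge rule (maximal union of qualifying windows) is one
  of several defensible consolidations; region counts depend on it.
* The exact Mann-Whitney enumeration is exponential in the combined
  sample size and is therefore capped at 16, past which the normal
  approximation is used.
* With only the numeric block z-scored, the numeric block dominates
  Euclidean distances; the TF-IDF and one-hot blocks mostly refine
  boundaries. The optional global-scaling flag rebalances this at the
  cost of leaving the stated convention.
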