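# Methods

This note documents the models and procedures barcodiv implements, the
defaults it ships, the numerical choices that are not visible from the API,
and what the synthetic-community tests do and do not demonstrate.

## Sequence quality grades

Recovered COI barcodes are graded twice. The *BIN grade* (length strictly
greater than 500 bp, ambiguous fraction strictly below 1%) marks sequences
reliable enough to act as standalone species proxies. The *MOTU grade*
(length of 300 bp or longer, same ambiguity bound) marks sequences usable
in threshold clustering. The boundary semantics are deliberate: 500 bp
exactly fails the BIN grade, 300 bp exactly passes the MOTU grade, and an
ambiguity fraction of exactly 1% fails both. Every residue outside
{A,C,G,T} counts as ambiguous — 'N' and the partial IUPAC codes alike —
because a QC bound phrased in terms of ambiguous sites has no reason to
treat a two-fold ambiguity as half an N. Relaxing any bound can only grow
the passing set, and every BIN-grade sequence is MOTU-grade; both
properties are tested.

Success homogeneity across orders uses the Pearson χ² statistic on the
order × {recovered, failed} table without continuity correction
(df = orders − 1). If a column of the table is all zero (every specimen
succeeded, or every one failed) the rates are equal by construction and
the test returns statistic 0, p = 1 with a warning rather than erroring.
Expected cells below 1 attach a warning but do not suppress the result.

## Pairwise distances and MOTU delineation

The distance between two barcodes is the **absolute number of nucleotide
differences**, not a percentage. The default threshold of 15 changes is
therefore ~2.3% of a full 648 bp barcode but a larger fraction of a 300 bp
one; short sequences cluster more readily. This is the convention of
absolute-cutoff MOTU tools and is kept faithfully rather than silently
converted to a proportion.

Distances come from a global alignment with free terminal overhangs
(Biopython's pairwise aligner; match +1, mismatch −1, gap open −3, gap
extend −1, end gaps 0 — the parameters are exposed in the API because no
single canonical set exists for this step). Counting rules over the
alignment columns:

* the *core region* runs from the first to the last column where both
  sequences have a residue; columns outside it are terminal overhang and
  free, so an exact substring is at distance zero;
* columns where either residue is ambiguous are excluded from both the
  difference count and the compared-site count;
* internal gap columns count one difference each, since COI barcodes are
  length-conserved and indels there signal real divergence;
* a pair with no aligned overlap has an undefined distance and is treated
  as above any threshold, never as close.

For equal-length sequences the positionwise (Hamming) comparison with the
same masking rules is used as an exact fast path; this is valid because
both the synthetic data and real co-aligned barcode matrices place
homologous sites at equal coordinates, and the test suite checks the two
paths agree on such inputs. `distance_matrix` applies the fast path per
equal-length block (vectorized) and the aligner across blocks, so the
common case is O(n²) byte comparisons rather than O(n²) alignments.

MOTUs are the connected components of the graph joining pairs at distance
≤ threshold — single linkage at the cutoff. Components make tie-breaking
irrelevant; labels are assigned contiguously by first-seen specimen order
so the labeling is deterministic, while the member-sets are invariant to
input order. Partitions refine monotonically as the threshold drops
(tested across 0..50 against a union-find oracle).

## Richness estimation

Accumulation curves are specimen-based: each of 1000 iterations draws a
full Fisher–Yates permutation of the specimens and records the number of
distinct MOTUs among the first n. Streams are seeded per
(group, iteration) with a CRC32-keyed seed sequence, so curves are
reproducible regardless of execution order or platform. The closed-form
hypergeometric rarefaction

E[S(n)] = S_obs − Σᵢ C(N−Nᵢ, n) / C(N, n)

is implemented with log-binomials (overflow-safe for any N) and serves
both as a fast exact alternative and as the oracle the Monte-Carlo curve
must match within 3 Monte-Carlo standard errors at every n.

The terminal slope is computed on the **mean** curve — (S̄(N) −
S̄(N−w))/w with window w = 10 — not as an average of per-iteration slopes,
because the completeness diagnostic is a property of the expected curve.
Categories use strict inequalities: slope > 0.1 very undersampled,
> 0.01 modestly undersampled, otherwise well sampled; a group with N ≤ w
cannot be sloped and the error message directs the caller to pool it.
Families qualify for separate analysis when they have more than 100
specimens *or* more than 10 MOTUs (strict), the rest pooling into one
"Others" group per order.

Chao1 is computed from singletons f₁ and doubletons f₂:

* classic: S_obs + f₁²/(2 f₂) (f₂ > 0), else S_obs + f₁(f₁−1)/2;
* bias-corrected (default): S_obs + f₁(f₁−1)/(2(f₂+1)).

The default matches the behavior of the standard community-ecology
implementations (the frozen cross-check in the tests reproduces R
vegan's point estimate). Standard errors use the Chao (1987) variance
family as implemented in EstimateS/SpadeR, written out in the `chao1`
docstring; note that other implementations use a delta-method variance
that differs slightly in the third decimal — the point estimates agree,
the SEs are formula-variant. With f₁ = 0 the estimate is S_obs exactly
and the SE is 0.

A caution the synthetic experiments make visible: Chao1's extrapolation
assumes observed singletons imply unseen species in a larger assemblage.
In a finite simulated community whose log-series abundance draws *are*
the community, many singletons are genuinely unique individuals, and
Chao1 overshoots the true pool size (by ~30% in the default noisy
scenario). The estimator-recovery acceptance test therefore uses uniform
detectability (multinomial sampling from an equal-abundance pool), where
the estimator is consistent and lands within 10% of truth.

Increase accounting (`richness_increase`) requires the core MOTU set to be
a subset of the augmented one and reports additional MOTUs and the percent
increase over the core. All report percentages round half-up (ties away
from zero), matching survey-table convention; slopes print to 3 decimals,
success rates to 1, Chao estimates to integers.

## Community structure

Analytical units are site or substrate aggregates of the systematic
survey (a year/method filter is applied before aggregation; pitfall
transects enter the substrate analysis pooled as a single "pitfall"
substrate, giving 8 substrate units). The Hellinger transform
√(yᵢⱼ/yᵢ·) gives every row unit sum of squares; Bray-Curtis is
Σ|u−v|/Σ(u+v).

Two readings of "Hellinger-transformed abundances and Bray-Curtis
dissimilarities" exist: dendrograms here use Bray-Curtis **on** the
Hellinger-transformed matrix (the couple reading), while ANOSIM runs on
raw-count Bray-Curtis (common practice in the standard ecology package);
a `transform` switch preserves both readings for either analysis.

Complete-linkage agglomeration is delegated to SciPy (cluster distance =
maximum pairwise dissimilarity; merge heights monotone) and verified
against a naive O(n³) oracle by cophenetic distances. Dendrograms
serialize to Newick as ultrametric trees: an internal node merging at
height h sits at h/2, so leaf-to-leaf path lengths reproduce cophenetic
distances; a single leaf serializes as `label:0.0;`.

ANOSIM ranks all n(n−1)/2 dissimilarities with mid-ranks for ties and
computes R = (r̄_between − r̄_within)/(M/2). The p-value counts uniformly
random relabelings (within the observed group-size profile) with
R ≥ R_observed, including the observed labeling in numerator and
denominator, so the minimum p at 999 permutations is 1/1000. The
permutation stream is seeded and platform-independent. Groups of size 1
are rejected (their within-group ranks are undefined).

## Synthetic communities

The generator emulates the statistical structure the analysis assumes,
with defaults chosen as the study conditions of a subarctic mite survey:

| parameter | default | rationale |
|---|---|---|
| n_species | 900 | fauna of ~900 species-proxies |
| barcode_length | 648 bp | full COI barcode |
| min_interspecific | 30 changes | interspecific divergence well above the cutoff |
| max_intraspecific | 5 changes | intraspecific variation < 1% |
| abundance model | log-series, p = 0.96 | rare-species-rich; mean ≈ 7 specimens/species |
| n_sites | 10 (5 forested) | survey design |
| n_substrates | 8 | 7 substrates + pooled pitfalls |
| turnover | 0.7 | strong forested/non-forested separation (ANOSIM significant; R saturates near 1 at desk scale because site aggregates average away sampling noise) |
| per-order success | 0.765 / 0.804 / 0.682 | survey-typical 68–80% |
| truncation, ambiguity rates | 0.02, 0.01 | ~1–2% of recovered sequences fail QC |

Species references are mutated copies of one shared ancestor (each species
mutates 1–3× `min_interspecific` random positions; candidates closer than
`min_interspecific` to an accepted reference are rejection-resampled, with
a hard attempt cap so infeasible configurations error instead of looping).
Intraspecific variants are independent substitutions from the reference —
a star genealogy, not a coalescent; adequate for testing threshold
clustering, not for phylogeographic realism. Each species has a site-type
and substrate affinity; a specimen falls inside its affinity with
probability (1+turnover)/2. Truncation keeps a prefix (so truncated
sequences stay co-aligned with full-length ones); ambiguity artifacts are
runs of 5–20 N's, usually pushing a sequence over the 1% bound.

A configuration is **identifiable** when max_intraspecific < threshold <
min_interspecific; then any two conspecific specimens differ by at most
2·max_intraspecific = 10 < 15 and any two heterospecifics by at least
min_interspecific − 2·max_intraspecific = 20 > 15, so threshold clustering
must recover the species partition exactly. This gate is validated at
config construction and forms the central end-to-end test; with the same
config and seed the generator's outputs are byte-identical.

What the generator does **not** emulate: codon structure and
transition/transversion bias, rate variation among lineages, geographic
isolation-by-distance, phoresy, and the barcode-gap erosion real complexes
show. Passing the end-to-end tests therefore demonstrates correctness of
the pipeline's logic under a clean barcode gap, not robustness of the 15-
change threshold on difficult real faunas.

## Problem sizes

The shipped tests and the acceptance script run scaled-down surveys
(40–200 species, a few hundred to ~1100 specimens; accumulation curves at
100–1000 iterations; ANOSIM at 99–999 permutations), sizes at which every
stage's statistical behavior is already visible while a full run stays in
the seconds-to-minutes range. The defaults in `SimulationConfig` and
`RunConfig` remain the full study conditions.

## Known limitations

* The absolute-change threshold is exposed but fixed per run; no
  barcode-gap estimation or dynamic thresholding is attempted.
* `compare_runs` between two separate pipeline runs differences per-group
  MOTU counts and Chao estimates; MOTU labels are run-local, so a
  subset-exact comparison across runs is only available when both surveys
  are clustered jointly (as `run_pipeline` does internally for the
  systematic-vs-qualitative increase report).
* Chao SE formulas are one published variant of several; see above.
* The χ² homogeneity test is asymptotic; with expected cells < 1 it is
  reported with a warning rather than replaced by an exact test.
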