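# Methods

## Scope and model

The package computes distance-based statistics over a *given* curated,
aligned CO1 barcode library. It takes morphological curation as input (the
annotation table: confidence groups, distribution ranges) and never infers
it; tree building and threshold-search algorithms (neighbour joining,
Bayesian inference, ABGD/ASAP partition search) are out of scope, though
externally produced partitions can be scored.

## p-distance with pairwise deletion

`distances.p_distance` counts differing sites over comparable sites, where a
site is excluded for a pair if either sequence carries `-`, `N` or any IUPAC
ambiguity code. Ambiguity codes are treated as missing rather than as
fractional matches: partial-match weighting would make distances depend on
an arbitrary resolution model, while exclusion is conservative and
order-independent. Consequences worth knowing:

- Comparable-site sets differ per pair, so the triangle inequality can fail;
  nothing downstream assumes a metric.
- A pair can have zero comparable sites; the matrix stores NaN there and
  single-linkage partitioning refuses to run until such pairs are resolved
  (connectivity through an undefined edge is undecidable).
- The matrix is built from one-hot indicator products (`V·Vᵀ` for comparable
  counts, `Σ_b A_b·A_bᵀ` for matches), which keeps a ~3600-sequence library
  in the minutes range on one CPU.

Reported tables render distances as percent, rounded **half-up** to one
decimal (0.0225 → 2.3); concordance percentages round half-up to whole
percent. Decimal arithmetic is used so float representation cannot flip a
boundary case.

## Closest-congener statistics

Reference species = confidence group 1; congener pool = groups 1–2; group 3
excluded. The species-to-species distance is the **minimum** over cross-pair
specimen distances (not a centroid): the statistic exists to answer "how
close can two good species get", so the closest observed pair is the
relevant summary, and it matches how closest-congener pairs are reported in
practice. Ties for closest congener are all retained; the lexicographically
first is displayed. Congener scope is the annotated genus; an optional alias
map can merge genera that curators treat as one complex (e.g.
Mogulones/Datonychus).

Distribution groups: ISL if the island flag is set (regardless of range),
else C1 for range ≤ 50 km, C2 up to the subfamily cutoff, C3 above it. The
cutoff is 500 km for Cryptorhynchinae and 2000 km for Apioninae and
Ceutorhynchinae. Boundaries are closed on the left class (C1 = (0, 50],
C2 = (50, U]): "up to 50 km" naturally includes 50.

Leave-one-out recomputes the whole table with one species' records removed.
Since removal only shrinks each remaining species' candidate set and
distances among remaining records are unchanged, no remaining minimum can
decrease — asserted as a property test and reported by the acceptance
script.

## MOTU concordance

Single-linkage partition at threshold t = connected components of the graph
with edges d ≤ t, via `scipy.sparse.csgraph`. A morphospecies is correct iff
its record set equals one MOTU exactly. Sequence-level error counting has
two defensible conventions, both implemented:

- `affected_taxa` (default): all sequences of each non-concordant species —
  the species-centric reading of "sequences of wrongly assigned taxa";
- `misplaced`: only sequences outside their species' plurality MOTU — the
  repair-cost reading (a pure lump costs 0 moved sequences).

The default is the weaker claim and the one consistent with reporting both a
taxon count and a sequence count per threshold.

## QC screening

Stops under the invertebrate mitochondrial code are TAA and TAG only (TGA is
tryptophan, AGA/AGG serine). A codon containing ambiguity codes is called a
stop only if *every* resolution is a stop (TAR yes, TAN no): screening flags
must not depend on how an ambiguity would resolve. Incomplete terminal
codons are ignored. The reading frame is a property of how the barcodes were
primer-trimmed and therefore a caller-supplied parameter (default frame 0).
QC flags and counts; exclusion is a curatorial decision — libraries
legitimately retain flagged or sub-minimum-length records.

## Synthetic data

The generator emulates a genus-structured barcode library; it is the test
bed for every stage.

**Sequence model.** Per genus an i.i.d.-uniform 658 nt ancestor; species
founders derive from it by independent per-site substitution with
probability `inter_divergence` (uniform over the three other bases);
specimens derive from founders likewise with `intra_divergence`. Each step
acts on the base distribution as `(1−u)I + u(J−I)/3`, so the expected
p-distance between sequences joined by steps u₁…u_k is
`¾·(1 − Π(1 − 4uᵢ/3))` (`simulate.expected_p_distance`) — oracle tests are
closed-form. Defaults: intra 0.005 (≈ 1% expected conspecific distance),
inter 0.055 (≈ 10.6% expected congener distance, the middle of typical
weevil genus averages). No indels or rate heterogeneity are simulated, and
frame-0 stop codons are repaired by default so planted pseudogene signals
are the only QC flags; passing tests therefore demonstrate correctness of
the statistics, not robustness to alignment error or rate variation in real
data.

**Sampling model.** Species per genus: zero-truncated Poisson (mean 5), or
pinned via `species_per_genus_fixed` for controlled experiments. Specimens
per species: a three-part mixture — singleton with probability 0.43;
otherwise deep (6 + Poisson(2.3)) with probability 0.30, else shallow
(2 + Geometric(0.77) − 1). These values were chosen so that, at scale, ~16%
of *sequences* are singletons and the median sequence belongs to a species
with ~6 specimens while the mean stays near 2.8 sequences/species — the
composition of a densely collected release. (A single heavy-tailed family
cannot satisfy both targets; the species-level median of such a library is
2, so the "median 6" target is sequence-weighted.) Annotations draw
confidence groups (0.6/0.25/0.15), an island flag (0.35) and a lognormal
continental range (median ≈ 150 km, σ_log 1.8) spanning all distribution
groups.

**Determinism.** One `numpy` generator seeded from `SimConfig.seed`; draw
order is fixed (per genus: species count; per species: specimen count,
annotation fields, founder, specimens), so a seed fully determines the
FASTA bytes.

**Planted gap.** `make_gap_scenario` simulates with intra 0.002 / inter 0.08
and rejection-samples (advancing the seed) until a direct scan confirms
every within-species distance ≤ g_lo and every between-species distance
≥ g_hi; the guarantee is verified, not assumed.

## Problem sizes

The test suite and acceptance script run libraries of ~90–1600 sequences:
large enough for the composition statistics to stabilise and for the
divergence-recovery check (25 two-species genera → 50 reference species,
binomial SE ≈ 0.22 percentage points) while keeping a full run in seconds.
The distance matrix scales as O(n²L) and handles release-scale libraries
(~3600 sequences) in minutes.

## Known limitations

- Statistics require the annotation table; confidence and distribution
  assignments are curator input, and errors there propagate untouched.
- Pairwise deletion can overweight short overlaps between fragmentary
  records; comparable-site counts are exposed (`DistanceMatrix.m`) so users
  can filter.
- The default label grammar is one convention; other releases need a custom
  `LabelScheme` pattern.
- The generator's star-shaped within-genus topology (all founders equidistant
  from one ancestor) has no nested species structure, so it cannot emulate
  paraphyly or introgression.
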