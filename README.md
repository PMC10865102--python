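# congener-gap

Distance statistics for curated DNA-barcode libraries: per-genus
closest-congener p-distances stratified by geographic distribution,
single-threshold MOTU delimitation scored against morphospecies, and
pseudogene (NUMT) screening — plus a synthetic-data generator with known
ground truth, so every stage is testable without downloading reference data.

## The problem

A universal genetic distance threshold for species delimitation does not
exist: interspecific CO1 divergence varies strongly between genera and with
geographic setting. A practical alternative is to calibrate expectations
morphologically: take only "good" (taxonomically uncontroversial) reference
species, measure each one's distance to its closest congener, and summarise
those distances per genus and distribution class. A new specimen whose
distance to its nearest congener falls below that genus's known minimum is a
likely synonym; one far above it is a candidate new species. This package
implements that workflow for aligned CO1 barcode libraries such as the
Molecular Weevil Identification (MWI) release (Zenodo DOI
10.5281/zenodo.7430106).

## The statistics

For aligned sequences *x*, *y* the **uncorrected p-distance** is

    d(x, y) = (# differing sites) / (# comparable sites),

where a site is comparable unless either sequence has a gap, `N` or an IUPAC
ambiguity code there (pairwise deletion). The **species-to-species distance**
is the minimum of d over all cross-specimen pairs. Each reference species
(confidence group 1) contributes the distance to its **closest congener**
(argmin over same-genus species of groups 1–2; group 3 — species complexes,
candidate species — is excluded). Per genus × distribution group
(ISL / C1 ≤ 50 km / C2 / C3, with a subfamily-specific C2–C3 cutoff at 500 or
2000 km) the table reports the minimum and mean of these per-species minima,
in percent to one decimal.

**MOTU evaluation:** records are clustered by single linkage at a p-distance
threshold; a morphospecies is correctly assigned iff its record set equals
exactly one MOTU (no split, no lump). Reports count wrongly assigned taxa and
their sequences.

**QC:** each record's reading frame is scanned for stop codons under the
invertebrate mitochondrial code (TAA/TAG; AGA/AGG are serine) — in-frame
stops indicate nuclear pseudogene copies (NUMTs). Records are flagged, never
dropped; length accounting tracks the full 658 nt barcode and the 500 nt
minimum.

## Worked example

```sh
$ congener-gap simulate --seed 42 --out demo
wrote 239 sequences, 90 species to demo

$ congener-gap summarize --alignment demo/alignment.fasta
sequences       239
species 90
qualified_sequences     0
singleton_species       38
median_specimens_per_species    2.0

$ congener-gap stats --alignment demo/alignment.fasta --annotations demo/annotations.tsv
genus   ISL_min ISL_avg C1_min  C1_avg  C2_min  C2_avg  C3_min  C3_avg
GenAaa  10.0    10.0    10.9    10.9    10.8    10.8
GenAab  11.1    11.1    11.4    11.4    11.9    11.9    11.1    11.1
GenAac                                  12.6    12.6
...
```

Each cell pair is the minimum and mean percent p-distance from a genus's
reference species to their closest congeners in that distribution group;
blank cells have no reference species. Here the generator's founder
divergence (0.055 per site, ≈ 10.6% expected pairwise) is visible in every
cell. A specimen of `GenAaa` on an island, 4% from its nearest congener,
would fall far below that genus's ISL minimum of 10.0% — a synonym warning.

```sh
$ congener-gap sweep --alignment demo/alignment.fasta --thresholds 0.02,0.05,0.10
threshold  n_motus  n_morphospecies  n_wrong_taxa  n_wrong_seqs  pct_wrong_seqs
0.02       90       90               0             0             0
0.05       90       90               0             0             0
0.1        72       90               25            66            28
```

This library has a clean barcoding gap (intraspecific ≈ 1%, interspecific
≈ 10%): thresholds inside the gap delimit all 90 species perfectly, while
10% lumps 25 species into mixed MOTUs (28% of sequences affected).

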