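# Methods

## Scope and coordinate conventions

splicescape consumes post-alignment evidence: a GFF3 gene annotation,
per-individual splice-junction tables (tab-delimited or TopHat-style
BED12), per-base coverage in bedGraph, and per-gene fragment counts.
Spliced alignment itself is out of scope; overhang and duplicate-position
metadata are taken from the evidence files, never recomputed from reads.

All internal coordinates are 0-based half-open. GFF3 (1-based closed)
is converted at the I/O boundary only; bedGraph and BED12 are already
half-open. Junction identity across individuals is the tuple
(chrom, strand, intron_start, intron_end) — the interval removed by
splicing. Chromosome names are opaque identifiers, so unplaced scaffolds
need no special handling.

## Junction support filter

A junction passes when `read_count >= 2`, `distinct_positions >= 2` and
`min_overhang >= 4` bp. "Non-repetitive match position" is
operationalised as at least two distinct supporting-read alignment start
coordinates, which guards against PCR/mapping duplicate stacks; the
threshold is configurable. The overhang requirement is applied to the
per-junction maximal left/right anchors (the best read per side), not to
every read individually — with per-read anchors unavailable in the
evidence formats, this is the weakest reading consistent with the data,
and it is configurable. Filtering is monotone: tightening any threshold
can only shrink the passing set (property-tested).

## Event detection and classification

Candidate introns for retention are the annotated introns *plus* every
interval implied by a filtered junction, so retention of novel introns is
detectable. An IR event requires, in the same individual, (a) depth ≥ 1
at every base of the intron and (b) the exactly matching spliced junction
in the filtered set. Requiring both in the same individual is the
conservative choice; it makes IR calls independent across individuals.

A3SS/A5SS detection groups filtered junctions by shared donor
(respectively acceptor), resolving donor = 5′ end of the intron in
transcription direction, so the same coordinate pattern classifies as
A3SS on '+' and A5SS on '−'. Events are counted **pairwise**: a donor with
k acceptors yields k(k−1)/2 events. This convention keeps every event a
two-isoform object with a well-defined long-isoform frequency and a
well-defined 2×2 Fisher table; the cost is that nested alternatives are
counted more than once, which is documented rather than hidden.

ES requires a filtered exclusion junction whose removed interval contains
at least one complete internal exon of a same-strand transcript, plus
both flanking inclusion junctions in the filtered set; one event per
(exclusion junction, skipped exon). A structural consequence of the
pairwise convention: an ES exclusion junction shares a splice site with
each inclusion junction, so the generic pair scan also reports an
A3SS/A5SS event at every ES locus. The catalog keeps both, because the
catalog is defined as the exhaustive union of the three detectors
(verified against unoptimized brute-force re-scans); consumers that want
ES precedence can drop alt-SS events whose junction pair coincides with
an ES event's junctions.

Events are assigned to the gene whose collapsed exonic span contains the
event's anchor span (smallest span wins, ties by gene id); unassigned
events are kept but excluded from "AS gene" counts.

## Isoform quantification

Inclusion/exclusion counting per type:

| type | inclusion (L) | exclusion (S) |
|------|---------------|----------------|
| A3SS/A5SS | reads of the shorter-intron junction | reads of the longer-intron junction |
| ES | floor(mean of the two inclusion junctions) | exclusion-junction reads |
| IR | floor(mean depth at the two intron boundary bases) | spliced-junction reads |

IR inclusion uses boundary-base depth rather than intron-body FPKM so the
two counts are commensurate junction-like read counts directly usable in
a 2×2 contingency table; intron-body integrals grow with intron length
and would bias the test. Floor (not round) keeps averaged counts integer
and deterministic. Quantification reads the *unfiltered* evidence map, so
an event detected in one individual can be quantified in another whose
support is sub-threshold; a 0/0 event has an undefined frequency that is
propagated as missing, never imputed as 0.

## Expression

FPKM = count / (collapsed exonic length / 10³) / (library size / 10⁶).
Counts are fragments (read pairs once). The library size is an explicit
per-individual input rather than the sum of per-gene counts, because the
genome-wide mapped total normally exceeds the annotated-gene subset being
tabulated; when absent, column sums are used. Expression categories:
zero (= 0), low (0, 5), medium [5, 40], high (> 40) — the boundary value
5 counts as medium, with both cut-points configurable. Feature densities
assign each base one class with precedence exon > intron > intergenic and
report coverage integrals and FPKM-style densities per class.

## Population variation

Only events of genes with FPKM ≥ 5 in **every** analyzed individual enter
the variation analysis (controls for coverage differences between
libraries). Spearman correlations are computed per pair on the events
with defined frequencies in both individuals, ranking within the shared
subset (whole-column ranking, as some table libraries do, is incorrect
under pairwise-complete deletion). Individuals are clustered by average
linkage on 1 − ρ; the dendrogram is written as an ultrametric Newick tree
(leaf at half its merge height).

Each (event, pair) 2×2 table [[incl_A, excl_A], [incl_B, excl_B]] gets a
two-sided Fisher exact p (sidedness: isoform shifts have no privileged
direction). Degenerate tables (a zero margin) are assigned p = 1 and
flagged rather than dropped, keeping denominators stable. BH adjustment
is applied, by default, to the pooled family of all (event, pair) tests
within a population group — the most conservative defensible reading of a
single per-group FDR cutoff — with a per-pair family available as an
option. The variable-event fraction (events flagged in ≥ 1 pair) is
reported over both candidate denominators, events tested and events
detected, since the choice is a convention.

## Synthetic-data generator

The generator emulates the statistical structure of a multi-individual
junction study, not reads: each AS gene (default 60% of genes, one event
per gene, one transcript per gene) hosts one event with type drawn from a
mixture defaulting to 0.40 IR / 0.32 A3SS / 0.20 A5SS / 0.08 ES — the
genome-wide type shares observed in poplar developing xylem. Base
long-isoform frequencies are Beta(2, 2); a `shift_fraction` (default
0.10, matching the observed 7–13% of variable events) of events carries a
frequency shift of `shift_dp` (default 0.30) in a single individual
(default scope — within-group pairwise tests only see individual-scoped
variation; a whole-group scope is available for population
differentiation).

Per individual and event, the informative depth is Poisson with mean 84:
junction surveys of this kind observe ≈ 42 reads per junction, and an
event spreads its informative reads over two junction classes.
Constitutive annotated introns get Poisson(42) junction reads. Inclusion
counts are Binomial(n, p) — exactly the sampling model assumed by the
Fisher test, so null simulations are calibrated by construction — with an
optional beta-binomial overdispersion knob (`beta_binomial_rho`) for
robustness studies. Coverage is emitted sparsely, only over retained
introns (at the drawn inclusion depth), which keeps fixtures tiny;
non-retained introns are simply uncovered. A `below_support_fraction`
(default 0.05) of events is emitted with a 1-read distinguishing junction
to exercise the support filter. Fragment counts are
Poisson(FPKM · L/10³ · library/10⁶) with true gene FPKM drawn log-normal
(median 20, σ = 1), so some genes straddle the FPKM ≥ 5 filter.

What the generator does **not** model: sequencing error, mapping bias,
positional coverage non-uniformity, multiple transcripts per gene,
overlapping genes, correlated events within a gene, and exonic coverage
outside retained introns. Tests passing on synthetic data therefore
establish the correctness of the event algebra and the calibration of the
statistics under the stated sampling model — not robustness to alignment
artefacts in real libraries.

## Numerical and reproducibility choices

- Every stochastic step flows from one integer seed through
  `numpy.random.default_rng`; per-individual streams are derived as
  `default_rng([seed, 1000 + index])` so emission order is irrelevant.
- Report files are written with fixed float formatting (`%.6g`) and fully
  sorted keys, so identical inputs give byte-identical bundles; the run
  manifest records a SHA-256 hash of the config.
- Fisher tests use the exact hypergeometric distribution (verified against
  exhaustive enumeration over all tables with grand total ≤ 30); BH uses
  the standard step-up with monotonicity enforcement (verified against the
  direct max-k definition).
- Degenerate inputs: empty junction files, events with no evidence
  (undefined frequency), coverage gaps (depth 0), and all-equal distance
  matrices (tie-broken deterministically by input order) are handled
  explicitly and covered by tests.
- Default problem sizes in tests (40–60 genes, 20 individuals, 2000
  events in calibration studies) were chosen to give Monte-Carlo standard
  errors a few times smaller than the margins being asserted while
  keeping the full suite interactive.

## Known limitations

- The pairwise A3SS/A5SS convention over-counts k-ary alternative sites
  and double-classifies ES loci (see above).
- IR inclusion from two boundary bases is noisier than an intron-body
  average; it is the price of an unbiased 2×2 table.
- The per-group pooled BH family is conservative when groups are large;
  power-sensitive analyses may prefer the per-pair family option.
- Known/novel junction labelling requires strand agreement; unstranded
  aligner output should be strand-assigned upstream.
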