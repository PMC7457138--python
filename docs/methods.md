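# Methods

This note documents the models, conventions and design choices behind
`asorf`, in the order the pipeline applies them.

## Coordinates, formats, genetic code

All interfaces use 1-based inclusive, stranded coordinates (the GFF3
convention); the only 0-based arithmetic lives behind one conversion pair
in `seqio`. Genomes are FASTA (A/C/G/T/N; any other IUPAC code is
rejected, because downstream codon logic needs unambiguous bases — codons
containing N translate to X, which keeps frames intact without guessing).
Annotations come from GFF3 or NCBI assembly feature tables; feature types
outside CDS/rRNA/tRNA are retained as `other`. Translation uses NCBI
table 11 throughout; internal stops render as `*` and are *kept*, never
truncated, so that alignment lengths stay comparable (relevant for
antisense-frame proteins, which routinely contain stops). CDS spans not
divisible by 3 are flagged and skipped for translation but do not abort a
genome-wide run — annotation glitches are data, not exceptions.

## Embedded antisense ORF discovery

For each annotated CDS the reverse complement of the host span is scanned
in all three frames for start→stop ORFs. Scanning only within the span
makes "fully embedded" true by construction: an ORF crossing the host
boundary is never reported, and never truncated to fit. Defaults: start
codons {ATG, GTG, TTG} (the table-11 initiators with appreciable usage in
enterobacteria), minimum 20 codons (start included, stop excluded), and
longest-ORF-per-stop reporting so nested sub-ORFs sharing a stop are not
counted as distinct candidates. All three knobs are parameters and are
recorded in output headers, since reasonable tools differ on them. ORFs
contained in several overlapping hosts are reported once per genomic span
with every host listed. Correctness is checked against an independent
six-frame enumeration + containment oracle on hundreds of random genomes.

## Alignment and percent similarity

Global protein alignment follows the EMBOSS needle conventions: affine gap
cost `gap_open + L*gap_extend` with defaults 10.0/0.5 (a one-residue gap
costs 10.5), end gaps free by default. The DP is Biopython's
`PairwiseAligner` (exact, C-implemented); this module owns the scoring
conventions and statistics. Percent identity = identical columns /
alignment length (gap columns included); percent similarity = columns with
substitution score strictly > 0, so identities with non-positive
self-score (e.g. X:X) count as identical but not similar, matching the
EMBOSS convention. `*` is scored via the matrix's own `*` row. Sequences
are aligned in a canonical argument order so that co-optimal tracebacks
resolve identically for (a,b) and (b,a) and the percentages, not just the
score, are symmetric; among co-optimal alignments the reported one is a
deterministic but otherwise arbitrary representative, and this determinism
is documented rather than assumed by any downstream statistic. Scores are
verified against exhaustive enumeration of every global alignment on short
pairs, and against a recomputation of the traceback's score on long ones.

## Neutral mutation-accumulation model

The null model asks: if a coding sequence accumulates random point
mutations with *no* selection, what similarity accompanies a given loss of
identity? Conditions (package defaults): 50 sequences of 333 codons drawn
i.i.d. from *E. coli* K-12 codon usage (the standard codon-usage-table
frequencies, shipped as a constant; stop codons removed from the sampling
distribution so sense frames stay open), then 70 rounds of 10 point
substitutions. A substitution hits a uniformly random position and always
changes the base; duplicate positions within a round are allowed and
collide (both choices the original mutagenesis tools leave unstated are
exposed as flags). Point mutation means substitution only — indels would
frameshift the fixed-frame translations and destroy the curve's meaning.
After each round the mutant is translated in the sense frame, or — for the
antisense control — in frame 0 of the direct reverse complement with no
further frame shift, and aligned against its unmutated ancestor.
Observations are binned by `round(100 − identity%)` and summarized by
per-bin medians; bin 0 is the self-comparison (100, 100). Mutation-created
internal stops translate as `*` and are aligned as such. Per-sequence
random streams are spawned from one master seed (`numpy.random.SeedSequence`),
so runs are bitwise reproducible and the sense and antisense curves are
computed from identical mutated nucleotide streams.

## Conservation statistics and classification

A single-copy ortholog family holds exactly one protein per genome; its
conservation is the median over all n(n−1)/2 pairwise alignments of
percent identity and similarity (median of an even count = mean of the
central two). Families can come from three routes, recorded in the run
manifest: an external clustering tool's orthogroups TSV (the route for
real, full-scale data), a built-in reciprocal-best-hit fallback over
all-vs-all alignment scores (quadratic; intended for desk-scale inputs),
or shared gene labels (positional orthology, exact for synthetic clades).
The conservation threshold is the 0.25 quantile (linear interpolation
between order statistics — the mainstream numerical default, recorded in
metadata since the convention is not universal) of median similarity over
a seeded random sample of up to 1000 annotated families; analyses with
fewer families use them all, logged. "Exceeds" is strict inequality.
Similarity excess compares a family's median similarity with the antisense
null curve at the family's identity bin (nearest bin at the edges);
positive excess means the family fixes more similar replacements than
neutral mutation predicts.

## Synthetic clade generator

The generator emulates the evolutionary structure the conservation
analysis assumes: a clade of genomes descending star-like from a common
ancestor, annotated genes generated from codon usage, a known subset of
genes hosting embedded antisense ORFs, per-gene divergence comparable to
ortholog families within a bacterial family. Defaults: 13 genomes, 200
genes of 333 codons, 30% of genes hosting one 25-codon antisense ORF, 40
substitutions per gene per branch — chosen to put annotated-gene pairwise
identity near 90%, the divergence regime the conservation statistics
operate in.

ORFs are planted constructively in the codon-aligned antisense frame: the
sense codon CAT yields the antisense ATG start, a sense codon from
{TTA, CTA, TCA} yields the antisense stop, interior sense codons are drawn
from usage excluding those three (keeping the antisense frame open), and
an extra antisense stop is placed immediately upstream so the planted span
is exactly the maximal ORF the scanner reports. Genes alternate strands;
intergenic spacers are random.

Selection is modeled as probabilistic rejection of dissimilar amino-acid
replacements: a proposed substitution whose sense replacement scores ≤ 0
in BLOSUM62 is rejected with probability `rejection_prob` (default 0.9) in
sense-purifying host genes; within antisense-selected ORF spans the same
rule additionally applies to the antisense-frame replacement. Rejected
proposals are redrawn, so every branch carries its exact per-gene
substitution count — selection relocates mutations rather than reducing
them, which is what makes selected ORF spans measurably more conserved
under an identical mutational load. This is deliberately simpler than a
full codon model: it produces the similarity-biased signal the analysis
is designed to detect, with interpretable knobs, and nothing more.

What the generator does *not* emulate: recombination, gene gain/loss,
indels, rate heterogeneity across sites and branches, non-star topologies'
shared internal branches (arbitrary per-branch substitution counts are
accepted, but the default is a star), and compositional differences
between genomes. Passing end-to-end tests therefore demonstrates that the
pipeline recovers a known selection signal under clean conditions — not
that real ortholog families are free of the confounders above. In
particular, on real data host-gene constraint alone lifts antisense ORF
conservation (the generator reproduces this: neutral ORFs inside purifying
hosts show small positive excess), so the discriminating quantity is the
*comparison* of excess between ORF sets, not its absolute value.

## RIBO-seq coverage

Primary mapped alignments are read from SAM; reads overlapping any rRNA or
tRNA feature by ≥ 1 nt on either strand are removed (contamination is
strand-agnostic). Each retained read increments depth over every site of
its aligned blocks, on its mapping strand — full-read coverage, not 5′-end
or P-site assignment. RPM = depth / denominator × 10⁶ with the denominator
the *post-exclusion* retained read count by default (rRNA reads dominate
ribosome-profiling libraries, so normalizing before exclusion would make
tracks depend mostly on contamination levels); a pre-exclusion option
exists. A zero denominator yields all-zero tracks with a warning rather
than an error. No MAPQ filter is applied by default. Output is bedGraph
per strand; smoothing is left to plotting consumers.

## Problem sizes and numerical choices

The test-suite and the acceptance script run everything at the scale the
analysis defines: the null model at its full 50 × 333 × 70 × 10 geometry,
and clade parameter recovery at 13 genomes × 200 genes, with smaller
geometries in unit tests where the property under test does not depend on
scale (per-round median monotonicity, for instance, is asserted on the
full 50-sequence ensemble because medians of small ensembles are noisy).
Alignment percentages are exact rational multiples of 100 and compared
exactly where the inputs are discrete; statistical assertions (parameter
recovery, chi-square calibration of the codon sampler) use fixed seeds and
conventional significance levels (0.01). Quantiles interpolate linearly;
tie-breaks in nearest-bin lookup prefer the lower bin index. All master
seeds are plain integers; derived streams come from `SeedSequence.spawn`,
never from arithmetic on the seed itself.

## Known limitations

* The RBH fallback is quadratic in proteome size and meant for synthetic
  or reduced inputs; full-scale ortholog inference should come from a
  dedicated clustering tool via the orthogroups adapter.
* Percent similarity inherits BLOSUM62's conventions; matrices without a
  `*` row cannot score antisense-frame proteins containing stops.
* The ORF scanner reports ORFs relative to annotated host CDS only; it is
  not a general-purpose gene caller and ignores same-strand overlaps.
* Codon usage is genome-wide; expression-stratified usage (highly vs
  weakly expressed genes) is not modeled, though it is known to matter for
  real codon statistics.
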