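# Methods

`pacscope` analyzes where transcripts end. In 3'-end sequencing (poly(A)
click sequencing and related protocols), each read terminates at a poly(A)
tail, so the 3'-most aligned base of a read marks a cleavage-and-
polyadenylation position. The package quantifies how the usage of such
positions redistributes between an annotated 3' UTR and the genomic space
around it — coding exons, introns, and the intergenic region up to 10 kb
past the gene — when a condition changes (the motivating case is knockdown
of a core cleavage/polyadenylation factor in cancer cell lines), and
propagates those shifts into expression-level consequences: quadrant
classifications against RNA-seq fold changes, derived gene sets, cohort
signature scores, and mRNA half-life estimates.

## Genome partitioning

Internally all coordinates are 0-based half-open (BED convention); GTF
input (1-based inclusive, Ensembl attribute dialect) is converted on load.
Only protein-coding genes are considered by default and transcripts tagged
`retained_intron` are dropped, because a retained-intron model would
blur the CDS/intron boundary the partition depends on.

Per gene, four stranded interval classes are built:

* **utr3** — union over the gene's transcripts of annotated 3' UTR
  features, each extended 300 nt in the direction of transcription
  (cleavage sites typically sit at, or a short distance past, the
  annotated UTR end). The extension is clipped at chromosome bounds.
* **cds** — merged coding-sequence features.
* **intron** — gene span minus the gene's merged CDS minus its *extended*
  3' UTR. 5' UTR exonic bases deliberately remain in this class; the
  partition targets poly(A)-site accounting, not exon bookkeeping.
* **downstream10k** — a 10-kb window appended at the gene's strand-aware
  3' end, minus all same-strand exons and all extended 3' UTRs of any
  gene. Opposite-strand features are kept: a stranded 3'-end library
  cannot confuse them with sense polyadenylation.

Subtracting the *extended* UTR (not the raw annotated one) when building
the intron and downstream classes guarantees utr3/intron and
utr3/downstream disjointness by construction. The window length of 10 kb
trades off capturing distal intergenic cleavage against running into
neighboring genes. Both the 300-nt extension and the window are
configurable.

A brute-force check (reimplementing the above rules base by base over the
chromosome) is part of the test suite and must agree exactly with the
interval algebra on randomized annotations; the four classes must be
pairwise disjoint per gene.

## 3'-end read processing

1. **Tail detection.** The poly(A) tail is the longest suffix of the raw
   read containing at most 2 non-A bases (sequencing-error tolerance;
   configurable), trimmed so it starts with an A. Reads with fewer than
   25 tail A's are discarded — a hard floor below which a terminal A-run
   cannot be distinguished from genomic A-richness. When the insert's own
   3' end is A-rich the suffix rule absorbs those bases into the tail;
   the 24-versus-25 boundary is therefore exact only for inserts that do
   not end in A, which is how the tests probe it.
2. **Site calling.** The 3'-most *aligned* base defines the site
   (`end - 1` on `+`, `start` on `-`); soft-clipped bases are ignored.
3. **Internal-priming filter.** Oligo(dT) priming on genomic A-tracts
   mimics a poly(A) tail. A site is removed when the 20 genomic
   nucleotides immediately 3' of it (on the transcript sense strand; for
   `-` strand sites this means reference T's scanned toward decreasing
   coordinates) contain more than 12 A. Exactly 12 is kept. The scan uses
   the sense strand only.
4. **Clustering.** Single-linkage with a 25-nt gap absorbs cleavage
   heterogeneity (a few nt of jitter around a true site). The
   representative position is the highest-support member; ties break
   toward the most distal position in transcription direction. 25 nt is a
   typical cleavage-heterogeneity scale; the value is configurable and
   recorded in provenance.
5. **Counting.** Sites/clusters are assigned to a gene and region class
   when the representative position falls inside an interval with
   matching strand. Each region class is counted independently (they
   originate from separate BED quantifications); within one class a
   position covered by more than one gene is discarded as ambiguous
   rather than fractionally split, keeping counts integral. Ambiguous and
   unassigned tallies are reported.

## Differential testing

Counts are normalized to counts per million (plain library-size cpm; no
trimmed-mean normalization, since the downstream PAC-score subtracts two
fold changes from the same libraries and composition effects cancel).
Units must exceed 2 cpm (condition mean) in *every* condition and 5 reads
total in at least one condition. "Condition mean" (rather than every
sample) was chosen because the filter's purpose is to exclude
unquantifiable units, not to penalize one noisy replicate; both scopes
are configurable.

The test itself is a deliberately simple stand-in for a quasi-likelihood
negative-binomial GLM: per unit, a pooled two-group method-of-moments NB
dispersion (floored at 0, the Poisson limit), a delta-method variance for
the difference of log group means, and a Wald statistic referred to a
t distribution with `n1 + n2 - 2` degrees of freedom as a small-sample
correction. log2 fold changes use condition-mean cpm with a 0.5-cpm
pseudo-count for stability at low counts. The test is validated by
calibration (type-I error 0.05 ± 0.02 under its own NB null at n = 3 vs 3)
and power (≥ 90 % at a 4-fold change, mean 200, dispersion 0.1), not by
matching another implementation's numbers. p-values are adjusted by
Benjamini–Hochberg step-up (independent-hypothesis-weighting variants are
out of scope: they require a covariate model this package does not fix;
the padj < 0.1 threshold semantics are unchanged).

A gene-level alternative-polyadenylation call requires at least two
poly(A)-site clusters, one of which is differential (padj < 0.1) with an
absolute usage-fraction change ≥ 10 %. Direction follows the most distal
qualifying cluster: gaining usage = lengthening, losing = shortening.
Keying direction to the most distal significant cluster is one of several
defensible rules; a usage-weighted mean-shift alternative would differ
only for genes with ≥ 3 shifting clusters.

## Integration: PAC-score, quadrants, gene sets

For a gene and region class *r* ∈ {intron, cds, downstream10k}:

    PAC-score(r) = log2FC(PAC counts in r) − log2FC(PAC counts in utr3)

Positive scores mean usage shifted toward the region upon treatment. Any
transcription/expression component common to both regions cancels in the
subtraction — an invariant the tests verify by superimposing a pure
expression fold change and requiring the score to be unchanged. (The sign
convention follows the "higher score = more distal usage" semantics; read
literally, one could define the subtraction the other way. The convention
is fixed here, not a flag — negate the column if the opposite forensic
convention is needed.)

Genes quantifiable by all three metrics (region log2FC, utr3 log2FC,
expression log2FC) are placed in quadrants by sign: QI = expression down,
score up; QII = up/up; QIII = up/down; QIV = down/down; exact zeros stay
unclassified. The headline gene set — lengthened-and-downregulated (QI) —
requires PAC-score > 0.5 and expression log2FC < −0.25 (strict) in at
least 2 of the ≥ 2 contrasts supplied. Extreme-significance gene sets
take the cross-table intersection of genes with sign(log2FC)·(−log10
padj) beyond ±4, padj floored at 1e−300 to keep the log finite. Ranked
lists for external enrichment tools use sign(log2FC)·(−log10 p) on
unadjusted p, sorted descending with lexicographic tie-breaks for
determinism.

## Signatures and kinetics

Cohort matrices are standardized per gene across samples (sample sd,
n−1); constant genes are dropped with a warning. A signature score is the
unweighted mean Z over the set's genes present in the matrix (missing
genes are counted in provenance, never imputed). Score–driver association
reports the Pearson r as the headline value with the p-value from a
two-sided Spearman rank test; group comparisons use Welch's unpaired
two-sided t-test by default (pooled-variance available). Whether the
cohort matrix is log-scaled is the caller's responsibility; Z-scoring is
applied to the matrix as given.

qPCR fold changes use the comparative Ct method, 2^−ΔΔCt, against a
reference gene and calibrator sample. Transcription-shutoff decay courses
are converted from Ct to percent-remaining through a standard curve
(OLS of Ct on log10 dilution; a slope of −1/log10(2) ≈ −3.32 corresponds
to perfect doubling), then fitted to one-phase decay
N(t) = N0·exp(−K·(t − t0)) with the plateau fixed at 0 (percent-remaining
is referenced to vehicle, so complete decay is the correct asymptote; a
free plateau is available by flag). N0 is fitted rather than pinned to
100 to absorb normalization error, t0 defaults to 6 h (the first time
point at which decay is underway; earlier points are excluded), K ≥ 0 is
enforced, and t½ = ln 2/K. Fitted K below 1e−6 /h is reported as "no
decay" with a non-finite half-life.

## The synthetic world

The generator emulates the structure of a 3-cell-line knockdown study:
per contrast, 3 replicates each of one control and two knockdown shRNAs
(differential tests compare 3 control vs the 6 pooled knockdown
samples). Each synthetic gene (default 120 per study) has a two-exon
structure with an annotated 3' UTR site and an intergenic site 2 kb past
the gene end; 25 % of genes also get an intronic site at 10 % constant
usage. Genes sit in non-overlapping slots wide enough that 10-kb
downstream windows never touch a neighbor. A canonical AATAAA hexamer is
planted ~21 nt upstream of every true site.

Defaults of the stated world: 30 % of genes are "intended QI" — upon
knockdown their usage shifts utr3:downstream from 0.8:0.2 to 0.2:0.8
(expected PAC-score = log2(0.8/0.2) − log2(0.2/0.8) = 4) and their
expression drops 2-fold (log2FC −1); all other genes are null. 3'-end
depth is 1000 reads/gene/sample with NB dispersion 0.05; cleavage
positions get Gaussian jitter (sd 3 nt, truncated at ±10, within one
cluster at the default 25-nt gap). RNA-seq means are 500 counts/gene with
NB dispersion 0.04 — a biological coefficient of variation of 0.2, the
standard figure for genetically identical cell-line replicates, which is
what the emulated design consists of (an earlier provisional 0.1 was
revised to this field-standard value; tissue-scale dispersion would be
unrepresentative of the design being emulated).

Two constructions make filter tests exact rather than statistical. Every
20-nt window of the background sequence, on both strands, is forced to
contain at most 12 A and at most 12 T (random patching outside planted
feature masks), so no true site — even after jitter — can trip the
internal-priming filter. Decoy internal-priming positions are planted
with 14 A in their downstream 20-mer, and decoy reads carry genuine
≥25-A tails, so the genomic filter is the *only* mechanism that can
remove them: the filter's effect is isolated from tail filtering.

All randomness derives from one master seed through labeled substreams
(`rng_for(seed, label)`), so regenerating one artifact never perturbs
another and every output is byte-reproducible from (config, seed).

What a green end-to-end test establishes: the interval algebra, counting,
filtering, testing and thresholding machinery recovers planted truth at
realistic depths and effect sizes (≥ 95 % QI recovery, ≤ 1 % false
inclusion at the default world). What it does not establish: robustness
to mappability artifacts, overlapping genes, fragment/GC bias,
sequencing-error tail degradation, or isoform-level annotation ambiguity
— none of which the generator models.

## Numerical choices and degenerate inputs

* Touching intervals merge; subtraction requires merged operands and
  treats zero-length input as invalid at construction.
* Windows truncated by chromosome ends are scanned/clipped as-is and
  logged.
* p and padj are floored at 1e-300 before logs; BH propagates NaN
  p-values (untestable units) without letting them enter the correction.
* Genes with a zero 3'-end total in any condition have undefined usage
  fractions and are skipped (logged) by the APA caller.
* Cluster-representative ties break distally; ranked-list ties break
  lexicographically; both for determinism.
* The decay fit initializes K from a log-linear slope and N0 at 100,
  with bounds K ≥ 0, N0 ≥ 0.

## Known limitations

* The differential test is a calibrated approximation, not a
  reimplementation of a quasi-likelihood GLM; exact p-values differ from
  edgeR-class software even though decisions at the stated thresholds
  agree in simulation.
* Ambiguous assignments are discarded, so closely spaced same-strand
  genes lose signal in shared downstream windows.
* No UMI handling, no paired-end support, no alignment: aligned reads (or
  3'-end BED) are the entry point.
* Signature scoring assumes the cohort matrix is already on a sensible
  scale; no cross-cohort batch handling.
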