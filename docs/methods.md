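# Methods

This note documents the models, statistics, and design choices behind
`m6akit`, and what its synthetic-data tests do and do not establish about
real m\*A-seq data. ("m6A" below is N6-methyladenosine.)

## Problem setting

m6A-seq (MeRIP-seq) fragments mRNA into ~100-nt pieces, immunoprecipitates
m6A-containing fragments with an anti-m6A antibody, and sequences the IP
alongside a non-IP input library. Regions where the IP is enriched over
input mark methylated windows. The package works entirely in transcript
space: per-nucleotide fragment counts on each mRNA, with 0-based
half-open coordinates throughout and GFF/GTF converted at the boundary.
The coding region (`cds_start_t`, `cds_end_t`) includes the stop codon,
and the "stop codon" anchor used for windows is the first base of the
stop triplet — the annotation itself does not fix this anchor, so it is
pinned here for determinism.

## Peak calling

Sliding windows (width 50 nt, stride 25 nt — about half the fragment
length) tile each transcript; a final truncated window covers any tail.
Each window's IP/input fragment counts form a 2x2 table against the
library sizes, tested with a one-sided Fisher's exact test
(hypergeometric upper tail, alternative: IP-enriched). Enrichment is the
library-normalized pseudocounted ratio
`((ip + 0.5)/N_IP) / ((input + 0.5)/N_in)`; the pseudocount 0.5 is used
everywhere a count ratio is formed. Benjamini-Hochberg runs over **all
windows of all transcripts jointly**, reading the FDR < 0.05 threshold
transcriptome-wide. Significant windows with gaps <= 25 nt merge into
peaks; the peak p-value is the minimum window p, and the summit is the
argmax of the 25-nt-smoothed per-nucleotide normalized IP/input ratio
(ties break 5'-most). A count-table exact test is the simplest defensible
IP-vs-input statistic at transcript scale; no attempt is made to emulate
a genome-space caller's local background model.

High-confidence peaks are replicate-consensus peaks: maximal intervals
covered by peaks from all replicates, which (for non-overlapping peaks
within each replicate) are exactly the non-empty intersections of one
peak per replicate. The consensus summit comes from the supporting
replicate peak with the smallest p-value.

## Transcript topology

Coding transcripts are partitioned into five disjoint segments covering
`[0, length)`: TSS (first `min(100, 5'UTR length)` nt), 5'UTR, CDS, stop
codon (100-nt window centered on the first stop-triplet base, taking
precedence over the segments it straddles), and 3'UTR. The TSS width is
not defined by the annotation conventions this follows; 100 nt was chosen
to mirror the stop-codon window. Summit fractions per segment are
normalized by each segment's share of transcriptome nucleotides to give
relative enrichment (ratio 1 = no positional preference). The metagene
profile rescales each summit to its fractional position within 5'UTR,
CDS, or 3'UTR (TSS counts with the 5'UTR; the stop window is split at the
stop base), with 30/100/30 bins by default, proportional to typical
segment lengths.

Summit-based assignment is implemented; whole-peak-overlap assignment is
a defensible alternative reading and would shift fractions slightly for
peaks spanning segment boundaries.

## Motif enrichment

Targets are the peak subsequences; the background is the exonic sequence
with peak intervals excised, chopped into fragments matched to the median
peak length to neutralize length bias. Counting is sequence-level
(zero-or-one occurrence per sequence), tested per k-mer with a
hypergeometric upper tail over the pooled sequence population and BH
across all 4^k k-mers (k = 6 by default). Sequence-level counting keeps
the exchangeable unit simple and avoids within-sequence occurrence
dependence; it approximates, but does not replicate, ZOOPS-style motif
scoring. The plant consensus UGUAYY is matched with the IUPAC reading
Y = C/U.

## Differential analysis

Expression is FPKM from the input libraries. Differential expression uses
a two-sided Welch t-test on log2(FPKM + 1) across replicates with BH
adjustment; a gene is called at p < 0.05 and fold change >= 1.5 (the
boundary counts; fold change is the pseudocounted mean ratio, and
magnitude max(FC, 1/FC) is compared so both directions are symmetric).
This is a deliberately minimal replicate-aware stand-in for a full count
model.

Differential m6A per peak compares replicate-summed IP/input count tables
between conditions: per-condition enrichment as above, fold change
B over A, and a two-sided Fisher's exact test on
`[[IP_A, in_A], [IP_B, in_B]]`, with the same p < 0.05 and FC >= 1.5
rule. Replicate-summing matches count-table differential testing; a
replicate-aware extension would model between-replicate dispersion.

The quadrant table cross-tabulates transcript-level m6A direction
(most significant peak per transcript; ties broken by |log2 FC|) against
expression strata {up, down, unchanged}, where "unchanged" means failing
either expression criterion. The negative m6A-expression association is
tested with a one-sided sign test on concordant-negative vs discordant
pairs (transcripts with unchanged expression are uninformative).

## Bench-assay arithmetic

* **m6A-IP-qPCR**: technical-replicate C_T values are averaged before
  exponentiation (standard ddCT practice); the target is normalized
  against ACTIN within IP and input fractions and IP is then normalized
  by input: `2^-(dCT_IP) / 2^-(dCT_input)`. The ddCT structure makes the
  result invariant to constant C_T shifts.
* **LC-MS/MS**: standard curves are ordinary least squares of peak area
  on concentration with a free intercept (forcing through the origin is
  a plausible alternative; the free intercept is strictly more general
  and exact on collinear points). Sample areas are inverted through the
  curve; the m6A/A ratio is reported in percent.
* **Bisulfite 5mC**: clones must be pre-aligned and gap-free (alignment
  is out of scope so the computation stays exactly testable). Each
  reference C's level is n_C/(n_C + n_T) over clones; other bases count
  as mismatches and are excluded; zero-call sites are dropped with a
  warning. Context is CpG/CHG/CHH from the reference with H = A/C/T;
  missing bases at the sequence end are treated as non-G. No
  conversion-efficiency correction is applied.

## Synthetic data generator

The generator emulates the study conditions every test runs under:

* **Transcriptome**: 500 transcripts by default; 5'UTR ~ U[50, 300] nt,
  CDS ~ U[300, 1800] nt rounded to codons, 3'UTR ~ U[100, 500] nt; one
  to three exons with 50-500 nt introns, random strand, start/stop
  codons written into the sequence.
* **Sites**: 10% of transcripts carry one m6A site, placed by segment
  weights concentrated on the stop-codon window (0.55) and 3'UTR (0.30),
  with stoichiometry 0.8. UGUAYY (Y drawn from {C, U}) is embedded
  centered on the site for 60% of sites.
* **Counts**: input coverage per nucleotide is negative binomial with
  mean `30 x abundance` (abundance lognormal, sigma 0.5) and dispersion
  0.02; IP means are the input means times
  `1 + (enrichment - 1) x stoichiometry` (enrichment 8) in a 100-nt
  window around each site, renormalized to the input depth. The small
  dispersion reflects libraries pooled from many fruits per replicate,
  where window-scale noise is dominated by counting rather than
  biological variation; it is also the regime in which a count-table
  exact test is approximately calibrated. Larger dispersions make the
  Fisher windows anticonservative — a real limitation of count-table
  testing that the differential modules inherit.
* **Conditions**: half of the methylated transcripts are differentially
  methylated in condition B (80% hypermethylated), planted as a 3x fold
  change on the IP enrichment boost so the planted effect is directly
  the quantity the differential test estimates; the depleted-condition
  stoichiometry is back-solved and validated to stay in (0, 1].
  Hypermethylated transcripts have 2x lower abundance in B (negative
  coupling; the sign is configurable).
* **Reproducibility**: one global seed; every (condition, replicate)
  count stream is an independent child stream, so any subset of the
  design regenerates identically.

What passing tests on this generator do **not** show: robustness to
alignment artifacts, isoform mixtures, GC or length biases, antibody
off-target binding, or biological replicate dispersion beyond the small
default — none of which the generator models.

## Problem sizes and numerical choices

The test suite and the acceptance script run at desk scale: 500
transcripts (~0.4 Mnt of transcript space) for calibration and recovery,
250-500 transcripts per run for the 10-20 seeded motif and
quadrant-association repeats. Uniform-summit checks of the normalization
identity use systematically spaced summits so the check is exact rather
than a sampling coin flip. Ties are broken deterministically everywhere
(5'-most summit, lexicographic k-mer order); degenerate inputs (empty
peak sets, zero-variance expression rows, zero-call bisulfite sites)
return defined values or named errors rather than propagating NaNs.

## Known limitations

* Fisher-based window testing assumes near-binomial counts; it is
  anticonservative under strong overdispersion (see above).
* Consensus intervals with `min_replicates` below the replicate count
  report maximal supported intervals, which can be wider than any single
  pairwise intersection.
* Peak boundaries are window-quantized (25 nt); summit localization is
  limited by the smoothing radius.
* Quantities that depend on a real sequencing dataset (absolute peak
  counts, exact segment percentages) are out of scope; the pipeline
  reports their simulation analogues only.
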