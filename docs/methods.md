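# Methods

This note documents the models, parameter choices and numerical
conventions behind `phageadapt`, and what the synthetic benchmarks do and
do not demonstrate.

## Tetranucleotide signature profiling

**Model.** Oligonucleotide usage is a replicon-wide signature: 4-mer
frequency vectors of fragments drawn from one genome correlate strongly
with the whole-genome vector, while recently acquired DNA retains the
donor's signature. The profile computes, per fragment, the Pearson
correlation between the fragment's z-scored 4-mer frequency vector and
the whole-genome (and optionally whole-host-genome) vector.

**Counting.** 4-mers are counted on the forward strand with a width-4
window sliding by 1; windows containing an N are skipped and excluded
from the normalizing window count, so N-containing fragments remain
comparable after frequency normalization. Counts are converted to
frequencies before z-scoring. Strand-symmetric signatures (forward plus
reverse-complement counts) are available via `strand="both"`; the default
is forward-only, since strand pooling roughly symmetrizes the vector and
slightly blurs strand-specific adaptation signals.

**Fragmentation.** Window 10,000 bp, step 1,000 bp by default. Fragment
*i* is centered on the midpoint of the *i*-th step tile and padded by
wrap-around at the sequence ends, so every tile — including terminal
ones — is represented by one full-width fragment and a genome of length
*L* yields ⌈*L*/step⌉ fragments. Wrap-around padding was chosen over
mirroring or random padding because it preserves genome-wide composition
exactly; for a linear genome it does splice the two termini into
end-spanning fragments, which is accepted as the price of unbiased
fragment widths. With window = genome length every fragment is a rotation
of the genome, whose signature differs from the unrotated genome's only
in the three 4-mers spanning the junction.

**Z-scoring.** Population standard deviation (divisor 256), applied
per-vector across the 256 components; a constant vector raises a
degenerate-signature error rather than returning NaNs. Outputs are
validated to mean 0 / sd 1 within 1e−9.

**Anomaly localization.** The headline call is the global minimum of
*r*<sub>self</sub> (first occurrence on ties, i.e. lowest fragment
index). The dip span is the maximal contiguous run of fragments
containing the minimum with *r*<sub>self</sub> < median − *k*·MAD
(*k* = 2 by default). The median/MAD threshold is robust to the dip
itself inflating the spread; on a monotone track with no robust outlier
the span is reported empty.

## GC-skew origin calling

Per-window skew is (G−C)/(G+C) with N counting toward neither base and a
zero denominator guarded to skew 0. Windows abut by default (window =
step = 100 bp), a trailing partial window is discarded, and the
cumulative sum is taken in position order. The origin is reported as the
midpoint of the window attaining the global cumulative minimum, the
terminus the maximum, both 1-based with first-occurrence tie-breaks.
100 bp windows resolve origin calls to one window on phage-sized
(tens-of-kb) genomes; both parameters are configurable for larger
replicons.

## Synteny blocks

A gene is syntenic when it survives homology pairing: hits filtered to
alignment length ≥ 10 bp and e-value ≤ 1e−5, then one best subject per
query gene (max bitscore, ties by min e-value, then lexicographically
smallest subject id). Blocks are maximal chains, in the query genome's
gene order, of at least 5 syntenic genes with at most 4 consecutive
non-syntenic genes between syntenic neighbours. The gap rule is evaluated
on the query order only and B-side gene-order conservation is *not*
required by default — the recognition rule speaks of shared genes in the
same genomic area, not of colinearity, and this tolerates inversions
within a cassette. A `colinear=True` mode additionally breaks chains
whenever the partner index in genome B fails to increase. Reported ranges
span first to last syntenic gene; flanking non-syntenic genes are never
included. Because the gap rule induces a unique partition of the syntenic
gene list into maximal chains, the single left-to-right scan is exact;
the test suite checks it against a brute-force enumeration of maximal
valid chains on 1,000 random instances.

## Read recruitment

The reciprocal-best-hit filter retains (read, ORF) pairs where the ORF is
the read's best reverse hit and also the best forward query among hits
whose subject is that read. "Best" is max bitscore, then min e-value,
then lexicographically smallest id — a deterministic total order, so each
read lands in at most one pair. Reads present only in the forward table
are discarded: their reciprocity cannot be verified.

Per-ORF abundance = recruited reads / (total virome reads × ORF
amino-acid length). The virome-level pooled abundance divides total
recruited reads by total virome reads and the summed amino-acid length of
*recruited* ORFs (those with ≥ 1 read); pooling over recruited ORFs keeps
the statistic interpretable as a weighted mean of the per-ORF values.
Per-ORF abundances are the primary contract; the pooled denominator is a
package convention, as aggregate "reads per amino-acid pair" statistics
are reported in the literature without a stated denominator. ORF coverage
is the fraction of ORFs with at least one recruited read.

## Synthetic-data generators

All generators take an explicit integer seed, are bit-reproducible, and
emit the planted truth with the data. They emulate the *statistical
structure* each analysis assumes, not real sequencing: no read-level
errors, quality scores, chimeras, or alignment score distributions — hit
tables are simulated at the alignment-summary level with fixed scores.
Passing recovery benchmarks therefore demonstrates that each method reads
the signal it is designed for at realistic signal strengths, not that it
is robust to every artifact of real libraries.

* **Mosaic genomes** (anomaly target): background and donor are
  independent 3rd-order Markov chains (order 3 controls 4-mer usage
  directly). Both transition matrices are Dirichlet draws at
  concentration 3 — equal peakedness, so neither signature dominates the
  pooled whole-genome vector, while the empirical mean absolute 4-mer
  frequency divergence between the two chains is ≈ 0.002–0.003
  (measured by `signature_divergence` on sampled sequence), comparable to
  genomes from different genera. Defaults: 34,000 bp background
  (phage-sized) with a 10,000 bp insert (one full analysis window)
  replacing a background segment.
* **Replichore genomes** (skew target): i.i.d. bases with
  P(G)−P(C) = −bias before the planted origin and +bias after, A and T
  fixed at 0.25; default bias 0.1, a moderate, realistic strand
  asymmetry. The model is linear (no wrap), matching linear phage
  chromosomes; with bias 0 the cumulative curve is a driftless random
  walk and the origin call is noise (excluded from recovery statistics).
* **Synteny pairs**: gene lengths and spacings are drawn randomly, but
  homology is planted exactly — syntenic pairs get fixed strong hits
  (bitscore 50, e-value 1e−20, 30 bp alignment) and non-syntenic genes
  get none — so called blocks must equal the plan.
* **Recruitment tables**: per-ORF read counts are Poisson at planted
  rates (default 10 per ORF, 20 ORFs, 10⁶-read virome); decoys appear
  only in the forward table, and reciprocity noise reassigns a read's
  reverse best hit to a different ORF. Truth reports the full planted
  counts, so noise and decoys measurably degrade recovery.

## Benchmark problem sizes

The recovery statistics run at the generators' default scale: 20 seeded
mosaic genomes (34 kb, insert position uniform), 100 seeded replichore
genomes (origin uniform in [2,000, 32,000]), 1,000 random synteny
instances of ≤ 30 genes plus 50 planted-block trials, and 10 simulated
viromes. These sizes give the pass thresholds (≥ 90% localization within
±2 fragments, ≥ 95% origin recovery within ±2 windows, 100% oracle
agreement and exact recoveries) comfortable statistical margins: the
measured replichore recovery rate is ≈ 98–99%, so at n = 100 the ≥ 95%
threshold is met with high probability under seed variation.

## Known limitations

* The signature profile reports correlation dips; it does not classify
  their cause (host adaptation, prophage remnant, amelioration state) or
  test significance beyond the median−*k*·MAD heuristic.
* Origin calling assumes a single origin/terminus pair and clear
  replichore structure; genomes replicating by other mechanisms (e.g.
  rolling circle with weak strand bias) may yield extrema without
  biological meaning.
* The synteny caller consumes precomputed homology tables; it neither
  runs alignments nor validates that hit coordinates are consistent with
  gene models beyond id resolution.
* Reference checks that require the deposited phage genome and its
  annotation need those files supplied locally; the package does not
  fetch accessions over the network.
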