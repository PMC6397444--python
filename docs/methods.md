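# Methods

## Problem and model

Transcription factors (TFs) bind short, degenerate DNA motifs. Genome-wide
binding assays routinely find sites far from promoters, often inside genes.
`motifmc` quantifies how many such sites are expected to occur *by chance* —
that is, under a null model in which no selection acts on the binding site
itself, but the genome's other compositional biases (GC content, gene-scale
heterogeneity, strand asymmetry, codon usage, dinucleotide stacking) are
retained.

### Motif scoring

A training set of n aligned sites of length L gives a count matrix
N_{a,i}. With pseudocount c the probability matrix is

    p_{a,i} = (N_{a,i} + c) / (n + 4c)

and the position-specific score matrix is the log-odds against a
strand-symmetric background q derived from the scanned genome's GC content
(q_A = q_T = (1−GC)/2, q_C = q_G = GC/2):

    s_{a,i} = log2(p_{a,i} / q_a),    S(w) = Σ_i s_{w_i, i}.

S is in bits; S = 0 means a window is equally likely under the motif and
the background, which anchors the calibration diagnostics at cutoff 0. The
identity Σ_x P_bg(x)·2^{S(x)} = 1 holds exactly and is verified by brute
force for L ≤ 6. Motif information content is Σ_i (2 − H_i) bits, computed
from raw frequencies (pseudocount 0), the sequence-logo convention; scores
use pseudocount 0.5 per cell by default. Both the pseudocount and the log
base are configurable because neither is dictated by the scoring model;
bits are the default so scores and information content share a unit. With
pseudocount 0, zero probabilities map to a −∞ sentinel: a window containing
one can never pass a finite cutoff.

### Region sets

The chromosome is partitioned into gene, intergenic and *unmodeled*
segments. A CDS becomes a gene segment when it is single-interval, its
length is divisible by 3, and it does not overlap an earlier-accepted gene
(earlier start wins whole). Compound (join) locations, frameshifted CDS and
overlapped remainders are unmodeled: the codon alphabet is undefined for
them, so the randomizer treats them like intergenic DNA, but they are still
masked out of "intergenic" scans. Four region sets are scanned: the whole
genome (both strands), intergenic segments (both strands), and the coding
and template strands of genes (one designated strand each). Windows never
straddle segment boundaries in region-restricted scans, and windows
containing N are skipped and excluded from the window total.

Two comparators are deliberate and kept distinct: cumulative counts use
S ≥ cutoff, while the excess statistic ΔN uses strictly greater.
Floating-point comparisons snap toward inclusion at 1e-9 so analytically
zero scores count at cutoff 0.

### Null models

* `b` — one genome-wide Bernoulli model (letter frequencies only).
* `bb` — an independent Bernoulli model per segment, genes fitted on the
  sense strand, so gene-scale heterogeneity and coding/template asymmetry
  survive randomization.
* `m1c1` — intergenic (and unmodeled) segments as first-order nucleotide
  Markov chains; each gene as a first-order chain over the 64-codon
  alphabet where the next codon is conditioned on the last base of the
  previous codon. This also reproduces dinucleotide frequencies, codon
  usage, and dinucleotides spanning codon junctions. Higher orders are
  deliberately not offered (overfitting risk outweighs the gain).

All models are generative, not permutation shuffles: composition is matched
in expectation, and all fidelity tests use sampling tolerances. Fitting
adds small transition pseudocounts (α_nuc = 0.1 per nucleotide transition,
α_codon = 0.01 per codon transition, both configurable) to avoid absorbing
states in short segments. The first codon of a sampled gene is drawn from
the gene's codon marginal (the start codon is not pinned) and the first
intergenic letter from the segment's composition; stop codons get no
special protection, so the terminal stop is reproduced at its empirical
frequency and internal stops can occur by sampling. Length-1 segments are
copied verbatim. Sampled genomes preserve length, segment frame, strands
and the feature table exactly.

Seeding: a master seed plus the replicate index feed a `SeedSequence`
spawn, giving independent, reproducible streams per replicate.

### Monte Carlo statistics

For each of N replicates (1000 by default, matching common practice for
stable 1st/99th percentiles) the same region sets are extracted and
scanned with the same grid. Per cutoff, replicate counts yield percentile
envelopes at {1, 5, 25, 50, 75, 95, 99}. Percentiles use nearest rank
(ceil(p·n/100)-th order statistic), except the median, which averages the
two central order statistics for even n; envelope differences between
interpolation conventions are sub-integer on counts. Per region set,

    ΔN = #{observed windows with S > median of replicate maxima}

computed from exact window scores, so grid resolution never affects ΔN.
ΔN for each region uses the replicate maxima of that same region
(ΔN_ig from intergenic maxima, and so on). Replicates are streamed: peak
memory is independent of the replicate count, while per-replicate counts
and maxima can be persisted to TSV.

A caveat worth stating explicitly: in a region where the observed genome
really is null-like, the observed maximum exceeds the median of replicate
maxima with probability near 1/2, so ΔN values of 1–3 in such regions are
expected behaviour of the statistic, not evidence of selection.

## Synthetic study genomes

The generator emulates exactly the structure the null models assume:
alternating intergenic segments (first-order dinucleotide chain or i.i.d.
letters at a target GC) and genes (ATG + interior codons from a codon
usage table, stops excluded from interiors, + stop codon), strands assigned
at random, emitted with a consistent CDS feature table. Planted sites are
substitutions, never insertions, so all coordinates stay stable and every
planted site is exact ground truth.

Defaults mirror a miniature *E. coli*: 200 genes of 100–500 codons,
intergenic gaps of 20–220 nt, GC 0.51. The bundled experiments use a
smaller instance (60 genes of 100–300 codons, ≈43 kb) chosen so the whole
experiment battery runs in minutes; the properties they probe (envelope
coverage, recovery of planted sites, model ordering, chain fidelity) are
size-invariant. What the generator does *not* emulate: operon structure,
promoter grammar, replichore GC skew, repeats and mobile elements. Passing
tests therefore demonstrate correctness of the machinery and calibration
against the stated generative structure, not fidelity to every bias of a
real chromosome.

The planted motif used in the experiments is a 16-bp, 16-bit synthetic
motif with the palindromic AT-rich consensus `ATTTAAATATTTAAAT` (dimeric
TFs commonly bind palindromes; AT-rich sites contrast with GC-neutral and
GC-rich backgrounds). Its columns share one consensus probability solved
numerically so each contributes IC/L bits.

## Numerical and design choices

* Coordinates are 0-based half-open internally; GenBank 1-based inclusive
  conversion happens only at the parser boundary (Biopython).
* Circular chromosomes are scanned and randomized as linear; the loss is
  at most L−1 windows at the origin.
* Reduced training sets ("top n sites") rank sites by their score under
  the full-set model with a uniform background — i.e. by motif-model
  likelihood, independent of any genome — with ties broken by input order.
* Region scans concatenate a region's sequences with L−1 Ns between them,
  so a single vectorized pass scores every window while boundary windows
  are impossible by construction.
* The median of replicate maxima and ΔN's strict inequality use a 1e-9
  tie snap; score ties on the lattice of achievable sums therefore do not
  inflate ΔN.
* RegulonDB-style matrix blocks may hold counts or normalised frequencies;
  columns are accepted either way since the pseudocount normalisation only
  needs the common column total.

## Known limitations

* Single-chromosome GenBank records only (first record wins, with a
  warning); RNA genes are not modeled.
* The PSSM is an additive model: no cooperative binding, DNA shape or
  supercoiling effects.
* ΔN is descriptive, not an inferential test; no multiple-testing
  correction is applied or appropriate.
* Cross-species scans recompute the background from the target genome but
  keep the source-species matrix; interpretation then rests on the user.
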