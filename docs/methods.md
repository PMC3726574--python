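# Methods

`ltrsurvey` re-implements, as a tested pipeline, a genome-wide survey of
full-length and solo LTR retrotransposons and of the host genes these
elements capture. Real surveys of this kind run on complete plant genomes
(rice, sorghum); here every stage is exercised end-to-end on synthetic
genomes carrying planted elements with exact ground truth, so each
component's recovery behaviour can be measured rather than assumed.

## Synthetic genomes

The simulator plants, into an i.i.d. background of configurable GC
content (default 0.44, rice-like), full-length elements built from the
features a structural detector relies on:

* a long terminal repeat (LTR) of 250–1200 bp, duplicated and then
  diverged; both copies begin `TG` and end `CA`;
* a 4–6 bp target-site duplication (TSD) copied from the insertion site
  onto both flanks;
* a primer-binding site (PBS): the 18-nt reverse complement of one of
  three built-in tRNA 3'-end sequences, placed 2 bp inside the 5'-LTR
  (real elements prime minus-strand synthesis on host tRNAs; the precise
  primer set is a free choice and is not meant to be biologically exact);
* a polypurine tract (PPT): 12 nt of A/G placed 2 bp upstream of the
  3'-LTR;
* optionally a captured single-exon gene: `ATG` + 100–300 sense codons +
  stop, written into the internal region and into the truth annotation as
  a `gene`/`mRNA`/`CDS` hierarchy.

**Divergence model.** The 3'-LTR derives from the 5'-LTR by per-site
Bernoulli substitutions at rate *d*, with every hit site guaranteed to
change base and the terminal dinucleotides protected. Only one copy is
mutated, which makes the expected LTR–LTR identity exactly 1 − *d*;
mutating both copies at *d*/2 would give 1 − *d* only to first order.
There are no indels by default, so identity stays analytically
predictable. No insertion-age model is imposed: divergence is a free
parameter, not a molecular clock.

**Lineages.** A configurable fraction of gene-carrying elements are
diverged copies of another element (default copy divergence 0.08,
matching the ~92% LTR homology of well-described expansion pairs); the
PBS is inherited unchanged, and a configurable fraction of copied genes
are pseudogenized with exactly one frameshift (1–2 bp indel) or one
premature stop, never touching the first or last codon. Stops are placed
in the first 85% of the CDS so that they are unambiguously premature.
Solo LTRs are single-LTR recombination products; the simulator keeps the
5'-LTR of the source element (an arbitrary but fixed choice) at a default
10% extra divergence.

**What the simulator does not model:** nested or fragmented insertions,
transposition into other elements, realistic codon usage, introns,
sequencing gaps. Passing recovery tests on these genomes therefore shows
the machinery is correct under clean conditions, not that it matches the
published counts on real genomes — those depend on the true insertion-age
and fragmentation spectrum.

## Structural detection

Detection mirrors the classic feature set: direct-repeat pair + TSD +
`TG…CA` termini + PBS + PPT + internal ORF, under the standard limits of
at most 20 kb between the LTR pair, LTR length 100–3500 bp, and minimum
LTR–LTR identity 0.80.

1. **Seed pairs.** Exact 20-mers are indexed (2-bit packed); same-strand
   position pairs with gap ≤ 20 kb are chained on a shared diagonal
   (band ±30 bp, anchor gap ≤ 400 bp). Chains refine to repeat extents by
   Smith–Waterman on padded windows; if the alignment pins to a window
   edge the pad doubles (40 → 640 bp).
2. **Refinement scoring.** The refinement alignment uses match +1,
   mismatch −2, gap open −4, extend −1. The expected local-alignment
   score of random DNA must be negative here: with the milder identity
   scoring (mismatch −1, extend −0.5), gap extension is so cheap that
   random flanks align profitably and extents drift tens of bp into the
   flanks. The traceback is additionally trimmed to its maximum-scoring
   core segment, because co-optimal Smith–Waterman paths can carry
   zero-net-score tails.
3. **Identity.** The two repeat copies are re-aligned globally with the
   documented parameter set (match +1, mismatch −1, open −2, extend
   −0.5); identity is matched columns over all alignment columns.
4. **Termini.** The element start must begin `TG` and the element end
   must end `CA`. Candidate shifts within ±20 bp are enumerated and the
   start/end shift pair supported by an exact flanking TSD (longest of
   6, 5, 4 bp) wins; ties prefer the smallest shift. Inner boundaries
   (5'-LTR end, 3'-LTR start) snap to the nearest `CA`/`TG`
   independently. The TSD-supported joint search replaced a simple ±3 bp
   per-boundary snap: alignment extents are only accurate to roughly
   ±10 bp, and the TSD pins the true insertion boundary precisely.
5. **Score.** Additive: +2 LTR identity ≥ 0.80, +1.5 TSD, +1 `TG…CA` on
   both LTRs, +1 PBS (≥14/18 complementarity to a library primer within
   20 bp of the 5'-LTR), +1 PPT (≥10 nt, ≥80% purine within 30 bp of the
   3'-LTR), +1 internal ORF ≥ 300 bp (any frame, either strand).
   Elements keep score ≥ 6.0, so a fully featured element (7.5, or 6.5
   without cargo ORF) passes while an LTR-pair-only candidate (3.0)
   fails. This additive score is a documented stand-in for the opaque
   internal score of the original annotator; it is calibrated only by
   the requirement above, not against any tool's output. Overlapping
   survivors resolve by higher score, then smaller span, then leftmost.

Detection is forward-strand only; the feature set is strand-symmetric at
this level. Candidates with more than 10% `N` are dropped; all-`N` input
yields an empty result, not an error.

On the default study conditions (2 Mb, 20 elements, 5% LTR divergence,
all features) the detector's measured recall is ≥ 0.90 with mean
boundary error well under 1 bp, and 10 × 1 Mb feature-free genomes yield
zero calls (see `scripts/acceptance.py`).

## Solo LTRs

LTRs harvested from detected elements are clustered greedily (length-
descending, join at ≥ 80% global identity to the representative with a
length ratio ≥ 0.8). Each cluster becomes a position-weight log-odds
matrix: a star alignment to the representative gives per-column base
counts (pseudocount 0.5; columns > 50% gaps dropped), scored against the
genome's base composition. A full profile HMM with insert/delete states
is deliberately not used: the downstream filters (E-value cutoff,
≥ 70% identity) never exercise HMM-specific behaviour.

Scanning scores every window start on both strands via FFT
cross-correlation of the four base-indicator tracks (the genome's
forward FFTs are shared across profiles). Significance is calibrated
per profile on a dinucleotide-shuffled copy of the genome: the shuffled
score track is cut into 1000 blocks and a right Gumbel is fitted to the
block maxima; per-window exceedance is the fitted survival divided by
the block size, and E = exceedance × number of windows. Fitting maxima
rather than the bulk of the null scores is essential: a Gumbel fitted to
near-Gaussian bulk scores has so fat a tail that even a perfect match to
a short (~400 bp) profile cannot reach E ≤ 1e-9, while the extreme-value
fit recovers the tail the E-value actually depends on. The cutoff
E ≤ 1e-9 and the ≥ 70% identity floor (realigned to the representative,
gaps as mismatches) are the thresholds used for solo calling in plant
genome surveys. Hits overlapping any full-length element by ≥ 1 bp are
removed before identity filtering; TSD presence at the solo flanks is
recorded but not required, since the thresholds above nowhere condition
on it.

## Captured genes and pseudogenes

A captured gene lies strictly within an element span ("located within");
boundary-straddling genes are excluded, and a gene inside two
overlapping elements maps to the higher-scoring one. Genes whose
description matches a TE keyword (retrotransposon, transposon, gag,
pol, polyprotein, reverse transcriptase, integrase, RNase H — list
configurable) are removed, as those are the element's own coding
capacity. Annotation is read from GFF3 via `gffutils`, keeping the
splice form with the longest CDS.

Pseudogene classification aligns the child genomic CDS region to the
parent protein in all three frames: frame translations are split at stop
codons, segments ≥ 8 aa are locally aligned (BLOSUM62, open −11, extend
−1), and blocks with score ≥ 40 are chained by dynamic programming
(collinear on parent and child; junction overlaps up to 30 aa / 90 nt
tolerated because local alignments overrun disablement junctions). A
frameshift is any frame change along the chain — the chain's initial
frame is the annotated frame 0, so a disablement upstream of the first
alignable block still registers. A premature stop is a stop codon
interrupting a same-frame chain before the final 5% of the parent; stops
in the last 5% are treated as natural stop-position wobble. The call is
pseudogene iff parent coverage ≥ 0.70 (union of chained parent spans)
and at least one disablement. Measured on 100 synthetic parent/child
pairs (half disabled), sensitivity and specificity are ≥ 0.95; the
residual misses are frameshifts within the last few codons, which are
genuinely indistinguishable from alignment end noise at this block size.

## Ka/Ks (NG86)

Expansion pairs are element pairs with both LTR identities ≥ 0.80
(ranked by mean identity; PBS/PPT flagged as matching at ≥ 0.90
identity). Their captured genes pair by best reciprocal global protein
identity (BLOSUM62, gap open −10, extend −0.5) at ≥ 0.50. Codon
alignments back-translate the protein alignment; gap columns and codons
containing `N` are dropped, internal stops are rejected.

The estimator is Nei–Gojobori (1986) with Jukes–Cantor correction —
chosen over codon-model methods because it is fully specified and
oracle-testable; the synonymous fraction of each codon position counts
changes to stop codons as nonsynonymous, differences average over all
minimal pathways with equal weights, pathways through stops are
excluded, and a codon pair whose every pathway hits a stop contributes
its differences as nonsynonymous (a documented fallback; such pairs are
vanishingly rare in practice). S + N = 3 × codons exactly, the estimate
is symmetric in its arguments, and the implementation matches an
independent brute-force enumeration oracle to < 1e-9 on 1000 random
codon pairs. No transition/transversion weighting is applied, so the
estimator is consistent for data evolved under uniform substitution —
which is exactly what the codon simulator produces (synonymous
proposals always accepted, nonsynonymous with probability ω, stops
never): simulation at ω = 0.5 (100 pairs × 300 codons) recovers a mean
ratio within ±0.1, and neutral simulation recovers 1.0 within ±0.15.
The universal genetic code is assumed throughout.

## Enrichment, expression, smRNA

* GO-style term enrichment is a one-sided hypergeometric
  over-representation test with Benjamini–Hochberg FDR, significant at
  p < 0.05 and FDR < 0.25. This operationalizes "gene-set enrichment"
  as practiced in annotation surveys that compare term frequencies
  between a gene set and the genome, rather than a ranked-list
  enrichment score; no GO DAG propagation is performed (flat term sets).
  Under random foregrounds ≤ 7% of terms are nominally significant at
  α = 0.05 (the test is conservative because hypergeometric p-values are
  discrete).
* Domain (Pfam-style) frequency comparisons use a two-sided 2×2
  chi-square without continuity correction, significant at p < 0.01;
  Fisher's exact test substitutes automatically when any expected cell
  is < 5. Direction is the sign of the foreground-minus-background
  proportion difference.
* A gene is called expressed if any evidence source fires: a cDNA/EST
  hit at ≥ 95% identity covering ≥ 90% of length; MPSS normalized
  abundance ≥ 5 in **both** the 17-bp and 20-bp signature sets; a
  microarray presence flag; an RNA-seq presence flag. Platform-level
  calling (array normalization, RNA-seq quantification) is out of scope;
  those flags arrive precomputed. The call is monotone: more evidence
  can only turn a gene on.
* Expression divergence between paralogs is status discordance, or a
  ≥ 2-fold abundance difference on a shared quantitative source when
  both are expressed. The published figures do not record which of the
  two senses was used, so both are exposed (`fold_threshold` is a
  parameter; discordance alone is obtained with `fold_threshold=inf`).
* smRNA mapping requires exact full-length matches (18–30 nt, both
  strands) inside gene sequences, and keeps only smRNAs with exactly
  one occurrence in the whole genome.
* Chromosomal density is the fraction of all elements whose midpoint
  falls in each fixed window (fractions sum to 1 per genome), and
  centromere enrichment is a one-sided permutation test
  (p = (1 + #resamples ≥ observed)/(n + 1)) under uniform repositioning.

## Pipeline and reproducibility

`ltrsurvey all --config cfg.yaml` runs simulate → detect → solo →
capture → evolve → profile; every stage reads and writes standard
formats (FASTA, GFF3, BED6, TSV, BEDGRAPH), so stages also run singly on
external inputs. The global seed propagates as seed + stage index. A
manifest stores the config hash and per-stage input/output SHA-256
checksums; reruns with unchanged config and intact files skip stages.
Deterministic stages are byte-identical across runs at a fixed seed.
Report percentages are printed to one decimal (e.g. 73 Mb of a 373 Mb
genome → 19.6%).

## Problem sizes

The shipped benchmarks use a 2 Mb chromosome with 20 elements and 10
solos for recovery, ten 1 Mb genomes for the false-positive control,
1000 random codon pairs for oracle agreement, 100 pairs × 300 codons for
Ka/Ks recovery, 100 parent/child pairs for the pseudogene benchmark, and
20 random-foreground replicates over 30 terms for enrichment
calibration. These sizes give stable estimates (binomial noise on a
recall of 0.9 at n = 20 is ±0.07) while keeping a full run in tens of
seconds on one core.

## Known limitations

* Nested and fragmented elements, the dominant complication in real
  plant genomes, are neither simulated nor untangled.
* No Gypsy/Copia classification and no RT/IN/RH domain HMM scan; the
  internal-ORF term is a proxy for coding capacity.
* The NG86 estimator ignores transition/transversion bias and codon
  frequencies; on real data it is biased relative to maximum-likelihood
  codon models, especially at high divergence.
* The "extension cutoff" knob of the original detector has no published
  semantics; the chaining parameters here are not equivalent to it.
* E-value calibration is per-genome and empirical; E-values are
  comparable within a run, not across genomes of different composition.
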