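# Methods

## The diversity statistic for tandem zinc-finger arrays

PRDM9's DNA-binding specificity comes from a tandem array of C2H2 zinc
fingers, each a 28-residue unit `X2-CXXC-X12-HXXXH-X5` whose two cysteines
(positions 3 and 6) and two histidines (19 and 23) coordinate the zinc ion.
In lineages where PRDM9 positions recombination hotspots, the array turns
over rapidly by paralogous gene conversion and duplication, and positive
selection acts on the base-contacting residues (array positions 11, 12, 15
and 18).  Because gene conversion leaves no single tree relating the
fingers, site-model dN/dS tests are mis-specified; the package instead uses
a tree-free statistic.  For position `k` across the fingers of one array,

    x_k = 1 - sum_i f_i^2

where `f_i` is the frequency of the i-th distinct residue at that position
(the per-site heterozygosity of the finger "alignment" that the exact
28-aa repeat structure provides for free).  The summary statistic

    P = sum_{k in {11,12,15,18}} x_k / sum_k x_k

is the share of total amino-acid diversity carried by the DNA-binding
residues.  Significance is empirical: P for the focal gene is ranked
against P for every other C2H2 ZF gene of the same species, and the gene is
called rapidly evolving when its competition rank falls in the top 5%.

Decisions taken where the procedure was open:

* **Finger parsing** is greedy, left-to-right and non-overlapping: a match
  consumes its 28 residues.  Tandem repeats are exact 28-aa units, so this
  is deterministic and recovers them one by one.  `X` (unknown residue) is
  accepted anywhere except the four anchors; records containing `X` are
  flagged in output rather than dropped.
* **Array grouping**: consecutive fingers starting exactly 28 + g apart
  (0 ≤ g ≤ `gap_tolerance`, default 0) form one run; runs shorter than
  `min_fingers` (default 4) are discarded; the first surviving run is the
  gene's array.  The default tolerance of 0 treats the motif's trailing X5
  as the inter-finger linker, so genuinely tandem fingers abut exactly.
  A pooled "all fingers" mode is provided for genes whose fingers split
  into several short arrays; both modes agree exactly on single-array
  proteins and the package tests assert that.
* **NA propagation**: a monomorphic array (every `x_k = 0`) has undefined
  P and is excluded from both the ranking and its denominator, rather than
  being assigned the bottom rank.
* **Ties** get competition (minimum) ranks, which is conservative for the
  top-5% call.
* Unweighted residue frequencies over the fingers of the selected array;
  duplicating every finger leaves all `f_i`, hence x and P, unchanged
  (property-tested).

## Catalytic-residue screening

Given any amino-acid alignment containing a designated reference sequence,
the SET-domain check maps ungapped reference positions (for PRDM9, the
three catalytic tyrosines at human positions 276, 341 and 357) to alignment
columns and reports, per query sequence, the observed residue and a
substituted/unalignable call.  A gap in the mapped column yields
`alignable = False` with substitution status undefined.

## Crossover landscapes

Crossovers are observed as ancestry-switch intervals (BED, 0-based
half-open).  The pipeline:

1. drops events lying within 10 kb of a contig edge;
2. tiles contigs with fixed 10-kb windows from coordinate 0, dropping
   trailing partial windows and windows within 10 kb of a contig edge;
3. assigns each event to exactly one retained window it overlaps,
   uniformly at random for multi-window events (seeded; events overlapping
   no retained window are dropped and counted);
4. defines the window's rate as its share of all assigned events — a
   relative rate, not per meiosis; rates sum to 1;
5. measures each window's distance to the nearest feature of each class,
   either interval-to-interval (0 on overlap) or from the window midpoint;
6. averages rate in 10-kb distance bins up to 100 kb, smooths with a
   Gaussian-kernel local-linear fit, and scales the curve by its value at
   the last grid point (a fold change relative to the far-from-feature
   background, exactly 1 there by construction);
7. bootstraps windows with replacement (default B = 500) for percentile
   CIs and SEs per bin;
8. reports Spearman's rho between rate and distance, and a partial
   variant — all variables rank-transformed, controls residualised out of
   both vectors by least squares, Pearson correlation of residuals — for
   questions like "does the peak-distance association survive controlling
   for TSS and CpG-island distance?".

Numerical choices: quantiles use numpy's default linear interpolation
(stated in output metadata; the even-count median is the midpoint of the
two central order statistics).  The loess bandwidth is `span` times the
distance range, default span 0.3, exposed in the API and CLI; local-linear
weighted least squares reproduces an exactly linear trend exactly,
whatever the bandwidth, which the tests exploit as an oracle.  Degenerate
inputs (constant distance, < 5 points, a zero at the scaling point) raise.

## Motif scanning and the shuffled-motif null

PWMs are probability matrices over ACGT (MEME minimal format).  Scores are
log2 odds against a background (default uniform), with pseudocount 0.01
added to each probability and the column renormalised; `N` scores 0.  Both
strands are scanned — the minus strand by reverse-complementing the matrix
— and every window at or above the threshold (default 5 bits) is a hit, in
forward coordinates, overlaps allowed.

The permutation null shuffles whole motif positions (columns) without
replacement, preserving the column multiset, per-position base usage and
total information content exactly.  (Shuffling the four base entries
within each position is available behind a flag as the alternative reading
of a "shuffled matrix".)  The overlap statistic is the number of peaks
overlapping at least one hit; the empirical p-value is
`(1 + #{null >= real}) / (n_null + 1)` (default 500 nulls), so it is never
zero.  Tissue-specific peak sets (peaks of one set overlapping no peak of
the other) feed a 2x2 Pearson chi-squared (Yates correction optional,
off by default; a warning is attached when an expected cell is below 1).

## What the synthetic generators emulate

`gen_zf_family` builds each gene as a tandem repeat of an independently
drawn ancestral finger, mutated per finger and position at rate
`sub_rate` (default 0.08), times `binding_multiplier` at positions
11/12/15/18, never at the anchors; mutations replace the residue with a
different standard amino acid chosen uniformly.  Multiplier 1 gives a
neutral background family: by exchangeability of the 24 mutable positions,
E[P] = 4/24 ≈ 0.167, which the tests verify.  Multiplier 10 with 10
fingers gives a PRDM9-like gene.  An optional conversion step overwrites
fingers with copies of random paralogous fingers, emulating the
homogenising effect of concerted evolution.  The generator does not model
codon structure, indels, linked sites, or phylogenetic correlation between
genes — so passing recovery tests demonstrates the statistic's behaviour
under independent-sites diversity, not robustness to alignment error or
shared ancestry.

`gen_landscape` emits contig sizes, uniformly placed TSS/CGI features,
peak sets (uniform, or jittered onto TSSs), and crossover intervals.
Event midpoints are drawn by rejection sampling so the realised intensity
is exactly `1 + A·exp(-d/lambda)` around the target feature class
(defaults A = 5, lambda = 20 kb; `uniform` sets the intensity flat).
Event lengths are log-normal with median 13 kb and 75th percentile 35 kb —
the parameters are solved from those two quantiles — mimicking the
resolution profile of ancestry-switch intervals inferred from low-coverage
hybrid sequencing.  The generator does not model ancestry-inference error,
power variation along the genome, or chromatin-driven peak placement.

## Problem sizes used in the checks

The calibration and recovery checks run at: 100 seeds of a 200-gene
neutral family plus one selected gene (top-5% recovery); 100 replicates of
5,000 windows / 1,000 events with B = 200 for the flat-profile check; 100
replicates of 20,000 windows / 2,000 events for enrichment detection; one
20,000-window / 5,000-event dataset for the mediation (partial-rho) check;
100 random 10-kb sequences for scanner-vs-brute-force equality; 200
replicate datasets for the empirical-p uniformity check and 20 for power
at n_null = 500.

Two design points in the empirical-p uniformity check matter.  First, the
"real" motif is drawn afresh in every replicate: with iid random columns,
the real column order and its shuffles are exchangeable permutations of
the same multiset, so uniformity of the empirical p is exact up to ties —
with a single fixed motif the p-value need not be uniform for that
particular motif even when peaks are random.  Second, the add-one
empirical p is discrete and ties make it conservative, so the fixture uses
enough peaks (400 over 100 kb) and a moderate-information motif to spread
the overlap counts; what is being verified is the test's calibration under
its own null, not a property of any particular dataset size.

## Known limitations

* Window rates are shares of observed events; comparisons across datasets
  with different event totals need external normalisation.
* The partial correlation is the standard rank-residual construction; it
  is not an effect-size decomposition and inherits the usual caveats of
  residualised correlations under non-monotone confounding.
* The Gaussian-kernel loess uses a single global bandwidth; heavily
  non-uniform distance designs may warrant an adaptive smoother.
* The catalytic-residue check trusts the supplied alignment; it does not
  realign or detect misalignment.
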