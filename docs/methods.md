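# Methods

## Scope and data flow

The package implements a five-stage gene-family survey over one genome:

1. **census** — member/pseudogene calls from protein FASTA + a
   conserved-domain table (CD-search-style), plus molecular weight and
   isoelectric point;
2. **phylogeny** — p-distance neighbor-joining tree with bootstrap
   supports and exemplar-based group assignment;
3. **duplication** — tandem clusters from gene order, NG86 Ka/Ks,
   WGD segment-pair identification with phylogeny + collinearity
   validation, molecular-clock dating and selection classification;
4. **gene structure** — exon/intron/UTR summaries and per-group statistics;
5. **expression** — geNorm reference stability, efficiency-corrected
   relative expression, temporal pattern classification, RNS candidate
   selection and the heatmap transform.

All genomic coordinates are GFF3-style 1-based inclusive throughout; the
representative isoform of a gene is its longest (spliced) mRNA.  Every
stochastic step draws from a generator seeded in configuration, so a rerun
with the same configuration is byte-identical.

## Census rules

A locus is a putative pseudogene when any of three criteria fire: peptide
length < 150 residues (exactly 150 is a member); no catalytic papain-type
domain hit at all (peptidase_C1 or the cathepsin-B variant — the
propeptide_C1 + cathepsin-B architecture is a legitimate member pattern, so
the cathepsin-B domain satisfies the requirement); or the best catalytic
hit covers < 60% of the full-length domain model
(`truncation_coverage_min`, configurable).  The 60% operationalizes "large
fragment deletion", for which no published cutoff exists.

Molecular weight is the sum of average-isotopic residue masses plus one
water (18.01524 Da).  The isoelectric point solves net charge = 0 by
bisection on pH ∈ [0, 14] to 1e-3, with Henderson–Hasselbalch terms over
the termini and D, E, C, Y, H, K, R using the Bjellqvist pKa set (the
ExPASy ProtParam convention); the net charge is monotone decreasing in pH,
so the root is unique.

## NG86 conventions

Site counting treats a mutation to a stop codon as nonsynonymous, so
S + N = 3 × codons exactly.  Difference counting averages over all
orderings of the observed per-codon changes with equal weight, excluding
orderings that pass through a stop codon; in the degenerate case where
every ordering is blocked, all orderings are used.  The Jukes–Cantor
correction is undefined at pS or pN ≥ 3/4 and raises a saturation error.
No transition/transversion or codon-frequency weighting is applied (this
is NG86, not YN00 — a deliberate, self-contained and oracle-checkable
choice; the printed divergence table shipped as a fixture is consumed as
*input* for dating and ω, so the method difference does not affect those
numbers).

## Segment-pair identification

Per-gene-pair Ks feeds a three-step procedure: cross-chromosome family
pairs with Ks inside the WGD window (default [0.06, 0.45], bracketing the
recent legume WGD cohort at 0.10–0.34 with margin) are matched one-to-one
by ascending Ks, then chained into segments when consecutive matches sit
within the collinearity window on both chromosomes.  Validation criterion 1
asks that, for every member pair, the smallest leaf set over all edges of
the unrooted NJ tree containing both genes stays inside the two segments
(the unrooted formulation matters: a sister pair placed at the NJ root
trifurcation has no small *rooted* clade).  Criterion 2 computes the
longest chain of homolog anchors strictly increasing in both segments
(orientation-aware, restricted to ±`collinearity_window` genes around the
focal pair) and requires ≥ `collinearity_min_anchors`.

`collinearity_min_anchors` defaults to 18.  This is a calibration against
the anchor density the package's own genome emulation produces (one family
locus per four genes, all genes carrying WGD paralogy): an ordered segment
yields ≥ 26 anchors in a ±25-gene window, while a randomly shuffled window
of m anchors has an expected longest increasing subsequence of ~2√m ≈ 7–13.
A small threshold (e.g. 3) cannot distinguish the two — random gene order
would validate — so the default sits in the measured gap with ~6σ margin on
both sides.  Sparser real anchor sets need a lower threshold, set in
configuration.

The representative Ks of a multi-gene segment pair is the minimum over
member pairs (configurable to the mean); ω uses the Ka of that
representative pair.  Dating is T = Ks/(2λ) × 10⁻⁶ Mya, λ defaulting to
6.1 × 10⁻⁹/site/year, reported to 2 decimals.

## Phylogeny

p-distance excludes columns with a gap in either sequence, pairwise.
Neighbor joining is the standard Saitou–Nei agglomeration: Q-matrix
minimization with lexicographic tie-breaking (internal nodes keyed by their
smallest descendant leaf), the usual branch-length formulas, negative
lengths clamped to zero with the deficit moved to the sibling edge, and a
trifurcating root representing the unrooted tree.  On additive matrices
this reconstructs the generating topology and branch lengths exactly.
Bootstrap resamples alignment columns with replacement; supports are the
fraction of replicate trees containing each internal bipartition of the
tree built from the original alignment.

The built-in aligner is intentionally minimal: equal-length inputs are
treated as already aligned (the generator evolves sequences without
indels), ragged inputs go through a star-progressive alignment (pairwise
global alignments to the first sequence, match 1/mismatch −1/gap −2,
merged by "once a gap always a gap").  A single-center star alignment
misplaces gaps between two sequences that are both distant from the
center, so for real, indel-rich families a precomputed MSA
(`alignment.fasta` in the bundle) should be supplied; the pipeline accepts
it everywhere.

Group assignment propagates labels from exemplar leaves: each leaf takes
the group of the smallest rooted clade containing it and ≥ 1 exemplar, or
"unassigned" when that clade's exemplars disagree.  On synthetic data group
*labels* are arbitrary; only co-membership is meaningful.

## Temporal pattern classification

A significant move between consecutive timepoints is a fold-change ratio
≥ `fc_threshold` (default 2.0) or its reciprocal.  Classes are tried in
priority order: senescence_up (≥1 rise, no fall, maximum at the last
point), development_down (≥1 fall, no rise), mid_peak (global maximum at an
*early* interior timepoint — the first half of the course, the 30/42dN
analogs — with a significant fall after it), down_then_up (first
significant move a fall, later a rise), up_then_down (first a rise, later a
fall, maximum not last), bimodal (a rise and a fall present, ≥2 local
maxima each within the threshold of the global maximum), flat (no
significant move).  Two refinements were needed to make every class
reachable and noise-stable: restricting mid_peak to early-interior maxima
(otherwise any rise-then-fall profile would be absorbed by it, leaving
up_then_down unreachable under the priority order), and requiring
significant moves for bimodal (otherwise noisy flat profiles, whose trivial
local maxima are all within threshold of each other, classify as bimodal).
Classification is invariant to rescaling all fold changes by a constant.

## Expression quantification

Replicate Ct values are averaged per (gene, sample) before quantities
Q = E^(Ct_min − Ct).  geNorm M_j is the mean over other candidates k of the
sample standard deviation (ddof = 1) of log2(Q_j/Q_k); it is invariant to
per-sample additive Ct shifts.  Fold changes divide the
reference-normalized target quantity by its baseline-sample value;
replicate scatter propagates to a fold-change SD by first-order error
propagation in log space (reference contributions damped by 1/k² for k
references).  RNS candidates are genes strictly above the per-sample
`high_quantile` (default 0.75) quantile in ≥1 symbiosis-related tissue AND
≥1 nodule-stage sample.  The heatmap transform is log2(x + 1) followed by
per-gene centering.

## The synthetic genome

The generator emulates the history the survey infers on real legume
genomes, with these study conditions as defaults: 20 ancestral genes of
300 codons on 2 proto-chromosomes; tandem expansion of two loci into
arrays of 3 and 2 copies *before* the WGD (so arrays appear on both derived
chromosomes — the configuration seen in the most complex real segment
pairs — and adjacent copies, at target Ks 0.3, are more diverged than WGD
partners); a WGD copying every proto-chromosome with pairwise synonymous
divergence targeted at Ks 0.2 and nonsynonymous at 0.2 × that (purifying
selection); 10% of non-array family genes pseudogenized, alternating the
two trigger paths (truncation to 120 codons; in-frame deletion of 45% of
the catalytic domain, leaving hit coverage 55% < 60%); three background
genes between family loci (the WGD copied them too, which is what makes
collinearity anchors dense); and per-gene exon counts of 1–4 with fixed
UTR and intron sizes.

Divergence is applied at expectation level, not with a full codon-model
simulator: for each codon, at most one single-nucleotide change across the
two copies (synonymous with probability pS·s_c, nonsynonymous with
pN·n_c, where pS/pN invert the Jukes–Cantor correction at the target),
and the changed codon sets of the two copies are disjoint.  Downstream
pathway counting is therefore exact within a pair, and the Ks estimator is
unbiased up to the (small, positive) Jensen term of the correction — the
50-pair cohort's mean estimate lands within 3 standard errors of the
target.  Recorded `true_ks` values are the NG86 values of the emitted
sequences.  What this generator does *not* emulate: indel evolution in
retained genes, rate variation among sites or genes, realistic intron
lengths, base composition bias, and alignment uncertainty.  Passing
recovery tests therefore demonstrates the pipeline's correctness on
clean, substitution-only histories, not robustness to alignment error or
rate heterogeneity in real genomes.

The expression layer adds five symbiosis-tissue columns and the five
nodule timepoints (12/30/42/64/84 days post inoculation).  The tissue
matrix has a designed high/low split — the number of high genes per column
is chosen so the 0.75 quantile falls between the clusters, making the RNS
ground-truth set exactly recoverable — with decoys high in only one tissue
class.  The qPCR table generates Ct = base − log_E(profile) + N(0, sd)
with three replicates, E = 2.0 and noise sd 0.2 cycles; class-defining
profile moves are ≥3-fold so the 2-fold classification threshold keeps a
noise margin.  Two reference genes are flat by design; two more drift by
±3 log2 units across samples, giving the stability ranking a real contrast.

## Problem sizes and numerical choices

Recovery suites run on the default 46-gene genome; the duplication cohort
uses 47 ancestral genes (50 WGD pairs) and the expression recovery 50 genes
per temporal class.  NG86 codon-pair results are memoized (4096 possible
codon pairs), making the ~5,000-pair all-vs-all Ks computation on the
cohort take seconds.  Exhaustive oracles in the tests are limited to sizes
where enumeration is feasible: pathway permutations per codon (≤ 3! = 6),
subset enumeration for collinear chains (≤ 10 anchors), and least-squares
topology search (≤ 7 taxa, 945 topologies).  Bisection tolerance for pI is
1e-3 pH; divergence times and ω are rounded to 2 decimals in tables, ω to
3 decimals in the printed-table check.
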