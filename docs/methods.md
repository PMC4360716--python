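# Methods

This note documents the models, algorithmic choices, and defaults behind
viroclade, and what the synthetic-data experiments do and do not
demonstrate.

## Similarity search and score statistics

All protein and nucleotide similarity steps run through one engine: an
exact affine-gap Smith–Waterman (gap of length L costs `gap_open +
L*gap_extend`; protein defaults BLOSUM62 with 11/1, nucleotide +2/−3 with
5/2). Determinism is pinned down explicitly: the alignment ends at the
highest-scoring cell with the smallest `(q_end, s_end)`, and the traceback
prefers diagonal, then up, then left. Adjacent insertion–deletion pairs are
excluded from the state machine; under these penalties they are never
optimal. For long subjects, a shared-k-mer prefilter (k = 4 for proteins,
k = 11 for nucleotides) restricts the dynamic program to diagonal windows
around seeds; within a window the alignment is still exact. In translated
recruitment, windows additionally require two seeds on nearby diagonals,
because a single shared 4-mer between a ~60-aa read frame and a multi-kb
frame translation occurs by chance almost always.

Raw scores convert to bit scores and e-values by the Karlin–Altschul
formulas with fixed gapped constants (λ = 0.267, K = 0.041 for BLOSUM62;
0.625/0.41 for the nucleotide scheme). The e-value search space is m×n per
compared pair, not database-wide; all comparisons here are pairwise, and
the qualification thresholds (bit > 50, E < 0.001) are fixed cutoffs, not
calibrated statistics. No finite-size edge correction is applied.

Nucleotide synteny blocks are found by seed-and-extend without gaps: shared
11-mers define diagonals, and the maximal-scoring ungapped segment per
diagonal (Kadane's algorithm on the +2/−3 score profile) is reported when
it clears the bit threshold; overlapping candidates resolve best-score
first. Ungapped extension can run a few chance-matching bases past a true
homology boundary — block edges are approximate by one or two words.

## Multiple alignment

Progressive alignment with a k-mer-distance guide tree. The guide tree uses
average-linkage (UPGMA) agglomeration rather than NJ because progressive
merging needs a rooted merge order; this matches the first-iteration guide
tree of the commonly used progressive aligners. Profiles merge by global
affine-gap alignment on expected column scores; with two sequences this
reduces exactly to pairwise global alignment. Fragment placement onto a
reference profile (for capsid domain checks) uses free end gaps.

## Marker screening and domain rule

Each gene takes at most one marker label: the best qualifying hit by bit
score across the reference sets, ties broken toward the alphabetically
first reference id. The capsid domain coordinates (columns 122–162 and
735–766) refer to columns of the reference g23 alignment, not residue
positions of any one sequence; a domain counts as present when at least 80%
of its columns receive a candidate residue after placement onto the
reference consensus. The 80% coverage fraction is a package default — the
domain rule itself gives coordinates but no explicit coverage threshold —
and it is configurable. The contig length floor is 10 kb.

## Trees, supports, clades, concordance

Distance trees are Saitou–Nei neighbor joining on p-distances (mismatches
over shared non-gap columns; disjoint-coverage pairs get distance 1 and a
flag). Ties in the Q matrix break toward the smallest active pair in
row-major order; negative branch estimates clamp to zero. On noiseless
additive inputs NJ reproduces the generating tree and its branch lengths to
floating-point accuracy, which the test suite checks against simulated
additive trees.

Supports come from a nonparametric bootstrap (columns resampled with
replacement; support = percentage of replicates containing the same
unrooted bipartition). Edges below 50% support are contracted into
polytomies; an edge at exactly the threshold is kept. Rooting requires a
monophyletic outgroup and places the root at the midpoint of the
outgroup–ingroup edge; because node confidences label the edge above the
node, supports are remapped during path inversion (and the two root
children share the root edge's support).

Clade delineation takes a rooted, support-annotated tree and reports the
maximal subtrees with support ≥ 80% whose leaves (at least two) are all
query sequences; remaining query leaves are unassigned. Because the rule is
"maximal", meaningful delineation requires reference leaves interspersed
among the queries — otherwise the entire query set can form one supported
clade. The synthetic communities therefore include per-clade reference
sequences that attach at each clade stem (see below).

Robinson–Foulds distance counts non-trivial unrooted bipartitions present
in exactly one tree, after restricting both trees to their common leaves.
The concordance test permutes the leaf labels of the second tree uniformly
(1000 draws by default) and reports three p-values: the conservative
empirical p `(1 + #{null ≤ obs})/(n_perm + 1)`; a lower-tail
normal-approximation p from the null mean and SD (needed to express
significance beyond the 1/(n_perm+1) floor, as when the observed deficit is
tens of SDs below the mean); and a tie-randomized p. The RF null is heavily
discrete — for random topologies most label permutations sit at or near the
maximum distance — so the conservative p has large point masses and cannot
be uniform under the null; the tie-randomized p (`(#{null < obs} +
U·(1 + #{null = obs}))/(n_perm + 1)`, U ~ Uniform(0,1)) is the standard
construction that is exactly uniform given exchangeability, and it is the
quantity whose calibration the test suite verifies by KS test.

## Gene content

Shared-gene counting qualifies each gene of the smaller gene set by its
best hit in the other contig (bit > 50, E < 0.001); the proportion divides
by the smaller gene complement, so a fragment nested in a larger genome
scores 1. "Shortest contig" is read as fewest genes — dividing a gene count
by base pairs would not be a proportion — with the alternative available
behind a flag. Clustering is complete linkage on 1 − proportion; contig ids
are sorted first so linkage ties resolve toward the smallest id pair, which
also makes the dendrogram invariant to input order. Novelty classification
is precedence-ordered (reference hit, then group-only, then unique), and
self-contig hits never count toward group membership.

## Read recruitment and environments

Translated mode aligns the best of the 6×6 read/contig frame pairs in
protein space (an approximation of tblastx: stop codons simply score −4);
nucleotide mode aligns both read strands. One best hit per read per contig
is kept; presence requires ≥ 100 distinct recruited reads, counted before
the 60% amino-acid identity filter, which applies only to recruitment
plots. Coverage windows tile the contig exactly: window i of a length-L
contig is `[floor(iL/30), floor((i+1)L/30))`, and reads are assigned by
alignment start; stored counts are raw, with log10(count+1) applied only at
plot time. Normalized coverage is total aligned bp divided by L. The
freshwater-vs-seawater style comparison is a Welch two-sample t-test, with
explicit conventions for degenerate inputs (both groups constant and equal:
p = 1; constant and unequal: p = 0 with an infinite statistic).

## Host prediction

Tetranucleotide profiles count overlapping 4-mers on the given strand only
(a canonical strand-symmetric mode exists behind a flag); windows
containing any non-ACGT base are excluded and frequencies renormalize over
the remaining windows. Host calls take the nearest host genome in Euclidean
distance; the tier thresholds follow a published calibration treated as
fixed constants (below 4×10⁻⁴: stated 95% accuracy; below 1×10⁻³: 84%) with
strict "below" at both boundaries. Spacer matching aligns both strands,
scores coverage as aligned spacer positions over spacer length and identity
over alignment columns, and flags exact (full-length, 100%) matches
separately, since only exact matches are really trustworthy at spacer
lengths.

## dN/dS (NG86)

Synonymous site counts per codon are the fraction of the three possible
changes per position that preserve the amino acid; changes that create a
stop codon stay in the denominator (counted as nonsynonymous). Observed
differences average over all orderings of the changed positions with equal
weight, excluding orderings that pass through a stop (with a fallback to
all orderings in the degenerate case where every path is blocked).
Proportions are Jukes–Cantor corrected. ω = dN/dS is undefined when dS = 0
or the correction saturates — except that ω = 0 is still reported when no
nonsynonymous difference was observed at all. The group summary is the mean
pairwise ω within each partition, excluding and counting undefined pairs.
This is a descriptive counting estimator; maximum-likelihood codon models,
site classes, and likelihood-ratio tests are intentionally out of scope.

## Synthetic communities

The generator emulates the statistical structure of a clade-structured
uncultivated phage group:

* **Hosts** — one random order-3 Markov chain per host (Dirichlet(0.5)
  transition rows), giving well-separated tetranucleotide signatures.
  Default length 200 kb.
* **Genomes** — a root genome of ordered gene modules: 6 core genes (the
  first four are the labelled markers g23 at 790 aa — long enough that the
  reference alignment spans the C-terminal domain columns — g20 at 420,
  g17 at 410, phoH at 230 aa) and 10 clade-specific flexible genes of
  150 aa (core virion genes are the long ones in T4-like genomes; flexible
  genes are shorter and more numerous). Intergenic spacers fill to the
  20 kb default genome length.
* **Clade structure** — each clade ancestor derives from the root at
  between_clade_div (default 0.5 substitutions/site), with the stem split
  just below the crown so each clade also gets a sister reference sequence
  (emulating previously published members of the group; these references
  are what make "maximal pure-query" clade delineation well-posed). Within
  a clade, genomes descend along a random ultrametric genealogy whose
  root-to-leaf paths carry within_clade_div (default 0.05); flexible-gene
  turnover accrues on the same edges at rate 8 per substitution/site, so
  sequence divergence and gene-content differences share one genealogy, as
  they do in real phage clades. At zero within-clade divergence all clade
  members are byte-identical, which also exercises the duplicate-contig
  exclusion rule.
* **Composition** — flexible genes and intergenic spacers draw each base
  from the assigned host's Markov chain with probability amelioration_w
  (default 0.7) and from a uniform background otherwise; core genes are
  host-agnostic. Substitutions use a uniform Jukes–Cantor kernel, applied
  codon-aware inside genes (changes creating stops are discarded; start and
  stop codons are immutable), so translations remain valid and ω ≈ 1 —
  the generator is selectively neutral by construction.
* **Reads and spacers** — reads of 150 bp (default 2000) drawn
  proportionally to abundance × length, uniform starts, random strand,
  per-base substitution errors at 0.005; spacers of 32 nt (2 per genome)
  with per-base mutation rate 0.03; ids encode the true origin.

All randomness flows from one seed through SHA-256-labelled child seeds, so
identical configurations produce byte-identical output files.

What the synthetic experiments do **not** show: the generator has no
indels inside genes, no recombination, no assembly artifacts or chimeras,
no realistic read-error profiles (no quality ramps or homopolymer indels),
and hosts are far better separated in composition space than real microbial
taxa. Passing recovery tests therefore demonstrates correctness of the
pipeline's logic under its stated model, not expected field performance on
real viromes.

## Problem sizes in tests and the acceptance script

The recovery studies use 20 simulation seeds at the default community size
(3 clades × 4 genomes of 20 kb) with 100 bootstrap replicates and 1000
permutations; host genomes are shortened to 50 kb in the clade-recovery
sweep (host composition plays no role in the marker tree), while host
recovery runs at the full 200 kb with 5 hosts; permutation-test calibration
uses 200 independent 16-leaf tree pairs; oracle checks use exhaustive
6-leaf topology enumeration plus several hundred random trees up to 12
leaves, 200 random additive trees for NJ, and 200 random protein pairs for
Smith–Waterman; the neutral dN/dS study uses 100 pairs of 200 codons. These
sizes were chosen to make the whole suite rerunnable on a laptop in a few
minutes.

## Known limitations

* The Smith–Waterman engine is exact but quadratic; it is intended for
  desk-scale analyses (tens of contigs), not database-wide searches.
* The e-value convention is per-pair; fixed λ/K constants are not
  recalculated for alternative scoring schemes.
* Bootstrap supports on p-distance NJ trees understate uncertainty under
  saturation; the clade-delineation threshold (80%) inherits that caveat.
* The NG86 group comparison is a descriptive substitute for branch-model
  likelihood ratio tests and should be read as such.
* CRISPR array detection and taxonomy resolution are out of scope; spacers
  and host genomes are caller-supplied inputs.
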