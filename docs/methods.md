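# Methods

This note documents the models and procedures implemented in `mitojack`,
the defaults they use, and what the synthetic-data experiments do and do
not demonstrate.

## Genome model and annotation conventions

A `CircularGenome` stores the deposited strand, taken to be the majority
(J) strand, with 0-based half-open coordinates internally and the 1-based
inclusive convention at every file boundary (GenBank, feature-table TSV).
Origin-spanning features are stored with `end < start` and resolved by
modular arithmetic. Junction spacers are signed: the representative nearest
zero is chosen, so a 7-nt overlap reports −7 and the wrap-around junction
reports the gap across the origin. The text convention "7 bp at the
nad4/nad4L junction" refers to the magnitude of that −7 overlap; the API
always reports the signed value. The A+T-rich control region is taken from
an explicit annotation when present, otherwise as the largest junction
spacer (conventionally rrnS → trnI).

Start codons are classified canonical (`ATN`) versus noncanonical (e.g.
`TTA`, `TTG`, `GTG`, all observed in diplurans); stops are the complete
`TAA`/`TAG` or the incomplete `T-`/`TA-` completed by polyadenylation. The
classifier works from the terminal remainder after whole codons, raising
on anything else — an error here means the annotation, not the sequence,
is suspect. Ambiguity code N is allowed in sequences, excluded from all
composition statistics, and rejected inside start/stop codons.

The packaged pancrustacean reference table (37 genes with per-species
codons, sizes and spacers for the seven dipluran genomes) has 23 genes on
the J strand (9 PCGs + 14 tRNAs) and 14 on the N strand (4 PCGs + 8 tRNAs
+ both rRNAs), matching the standard fly-like arrangement. Two spacer
columns of the source comparison (after trnS-uga and after nad1) are
stored as best-effort values; no analysis depends on them.

## Composition statistics

AT skew = (A−T)/(A+T) and GC skew = (G−C)/(G+C), with AT% =
100·(A+T)/(A+C+G+T). Statistics are computed on the J strand for the whole
genome and on the coding sense for J- and N-oriented protein-coding genes,
overall and per codon position; N-gene codon positions are defined on the
coding sense (the reverse complement of the deposited strand). Pooling is
by counts, not by averaging per-gene skews. Report tables round to two
decimals; raw values are kept internally. Zero denominators yield missing
values rather than zeros.

## tRNA cloverleaf fold

`fold_cloverleaf` is a purpose-built structural classifier, not a tRNA
finder: gene boundaries are taken as given and only the arm decomposition
is searched, exhaustively, under these constraints: acceptor stem exactly
7 pairs with ≥5 valid (Watson-Crick or G-U wobble) pairs; anticodon stem
4–5 pairs with at most one mismatch and a 7-nt loop centred on the
anticodon; D stem 2–4 perfect pairs with a 3–10-nt loop, or the arm
declared absent with an unpaired remnant (0–16 nt); T stem 2–5 perfect
pairs or absent; variable loop 3–24 nt; connector lengths 1–2 and 0–2 nt.
The score is total pairs minus stem mismatches; ties prefer more pairs,
then a present D arm, then a smaller variable loop, and the enumeration
order prefers canonical connector lengths, making the result
deterministic. D-arm "absent" means no D stem of ≥2 pairs formed — the
threshold that separates a lost arm from a merely shortened one — and the
stem bounds are configurable (`FoldConstraints`). Mitochondrial tRNAs are
degenerate, so real molecules may fold with boundaries ±1 nt relative to
manually curated structures; the classifier's claim is the presence call,
not nucleotide-exact boundaries.

Arm-loss characters (0 = arm present, 1 = lost, `?` = unknown) map onto a
rooted tree by Fitch parsimony. Ambiguous down-pass states resolve toward
the parent and the root toward state 0, because the full cloverleaf is the
ancestral condition in the group; with no outgroup in the matrix a
character lost in every taxon therefore reconstructs as ancestrally lost
(zero changes) — the stem event appears as soon as arm-bearing outgroups
are included.

## Alignment preparation

Retro-alignment expands an amino-acid alignment back to codons using each
taxon's CDS under the invertebrate mitochondrial code (translation
table 5), after removing complete or incomplete terminal stops; any
translation mismatch is an error naming the taxon and position. Trimming
is a codon-aware conserved-block filter in the Gblocks spirit: columns are
conserved when the majority state reaches t1 (default just over half the
taxa) and flanking columns need t2 = 0.85; runs shorter than `min_block`
(default 10 codons) and columns over the gap threshold (default: no gaps)
are dropped, in whole codon triples when codon labels are present. The
exact thresholds of the published trims are not recoverable, so trimmed
totals are treated as descriptive, not as targets. Concatenation takes the
union of taxa, fills absent rows with `?` (missing data, distinct from the
alignment gap `-`, though both are missing to the likelihood), and keeps
one data block per source gene, refinable to per-codon-position blocks.
RY recoding maps A,G→R and C,T→Y at selected codon positions (nt3 = third
only, nt13 = first and third); ambiguity codes that cross the purine/
pyrimidine split become missing, rRNA columns are never recoded, and
recoding is idempotent and shape-preserving.

## Likelihood machinery

Felsenstein pruning with 4-category discrete gamma (mean-per-quantile
category rates), GTR for nucleotides and a 2-state model with free state
frequencies for RY data. Partitions share branch lengths through
per-group rate multipliers ("proportional" linking). Missing states
contribute partial likelihood 1. Numerics: per-node global rescaling with
accumulated log factors; branch lengths clamped to [1e-8, 10]; eigenvalue
decomposition via similarity to a symmetric matrix.

Branch lengths are optimized edge-by-edge with Brent's method against
cached inside ("down") and outside ("context") partials, sweeping until
the joint likelihood stops improving; a sweep that degrades the joint
likelihood (possible because partials go stale within a sweep) is
reverted. Topology search is NNI hill climbing: both interchanges around
every internal edge are scored from the same caches with a batched grid
over the central branch length, all improving non-conflicting moves are
applied simultaneously (falling back to the single best move, or to no
move, whenever the joint likelihood disagrees), and branch-length sweeps
are interleaved until no move improves. Starting trees are neighbor
joining on LogDet (paralinear) distances — the classic correction that
keeps compositionally biased taxa from being drawn together before the
likelihood search even starts; uncorrected p-distance starts were observed
to strand the search in poor local optima on exactly the data this
package targets. Model parameters (exchangeabilities, frequencies, gamma
shape, rate multipliers) are fitted by L-BFGS-B on the starting tree and
held fixed during the topology search.

The bootstrap resamples site-pattern weights within each partition group
(exactly equivalent to resampling columns), restarts each replicate from
the full-data tree with the full-data model parameters (rapid-bootstrap
style), re-optimizes branch lengths coarsely and reruns the NNI loop.
Support is the percentage of replicates containing each bipartition; a
clade absent from the best tree still reports its replicate frequency,
flagged as not recovered. NNI-only search is adequate at the ≤30-taxon
scale this package targets and is a documented scale limit, not a claim
of parity with production tree searchers.

## Partition-scheme selection

Greedy BIC search in the PartitionFinder style: all blocks start
separate; every pairwise merge is fitted (with caching) on a fixed guide
tree and the merge with the largest BIC reduction is applied until no
merge helps, with lexicographic tie-breaking so block order cannot change
the result. Each group fit optimizes its substitution model and one rate
multiplier on the shared, fixed branch lengths. Parameter counts: GTR+Γ =
5 relative exchangeabilities + 3 frequencies + shape + multiplier = 10;
BIN+Γ = 1 + 1 + 1 = 3; shared branch lengths are counted once per scheme,
and n in BIC is the site count. Parameter accounting conventions differ
between implementations, so absolute BIC values are never compared across
programs — only schemes within one run. Constant-data groups are fitted
but flagged (`boundary_alpha`).

## Synthetic data: what it emulates, and what it does not

`simulate_genome` produces the 37-gene arrangement with per-gene lengths
and spacers from the packaged reference table (the Octostigma column by
default), target AT content and strand skews (N-strand genes are sampled
with negated skews on the coding sense so the deposited-strand targets
hold), valid start/stop codons with incomplete stops at probability 0.3
(roughly their frequency among the seven diplurans) and noncanonical
starts at 0.1, tRNAs built from cloverleaf templates honoring per-gene
D-arm flags, and an A+T-rich region at 85% AT sharing the strand skews.
The conserved nad4/nad4L (−7), atp8/atp6 (−7) and nad6/cob (−1) overlaps
are laid out exactly as in the real genomes (terminal codons take
priority in the shared bases; a 1-nt overlap forces the compatible
TAA/ATN pairing); overlaps that would corrupt a tRNA are clipped to zero.
Synthetic tRNA stems are perfect Watson-Crick pairs and loops avoid
self-pairing alphabets, so the intended fold is the unique optimum —
which is why the classifier is exactly right on clean molecules; real
tRNAs have mismatched stems and the accuracy curve under random mutation
(reported by the acceptance script) is the honest statement of
robustness. The generator does not simulate sequencing artifacts,
assembly gaps, codon-level selection, or realistic intergenic turnover.

`simulate_alignment` evolves partitioned nucleotide matrices along a tree
under GTR+Γ, with per-site gamma categories fixed across the tree and
per-lineage overrides that rescale branch lengths and/or redirect the
composition via a nonstationary rate matrix (same exchangeabilities, new
frequencies). Codon labels are assigned cyclically within protein
partitions; no codon model is used, which matches the nucleotide/RY level
of the downstream analyses.

## The taxon-jackknife preset

The 16-taxon preset holds a true 7-tip ingroup of three subclades — three
fast "camp" tips, one intermediate "proj" tip sister to them, three
"japy" tips — among nine outgroups including a fast 3-tip clade. The camp
and fast stems carry rate ×8 and AT-content 0.80 overrides (stem-only:
the classic naked-long-branch geometry). Branch lengths were calibrated
once, during development, so that the artifact robustly wins exactly when
proj is unsampled: the ingroup stem is short (0.06 substitutions/site),
proj sits close to camp (0.06) and the rabdura stem is long (0.14). The
default experiment is the single-partition GTR+Γ variant (the cheapest
column of the support-table design, which already exhibits the recovery
pattern); recoded (nt3/nt13 RY) and partitioned variants are available
through `JackknifeCase`. Six cases drop nested taxon subsets (A: none; B:
proj; C: all but two camp and one japy; D: C plus proj restored; E: all
camp; F: all japy); support above 60% counts as significant. At 3,000
sites and 50 bootstrap replicates the expected contingency — the clade
recovered in A, D, E, F and lost in B, C — held in 10 of 10 validation
seeds. Passing this experiment shows the inference machinery reproduces
the qualitative taxon-sampling effect under controlled misspecification;
it says nothing about the numeric support values of any real data set,
which depend on genomes and search heuristics outside desk scale.

## Problem sizes and determinism

All tests and the acceptance script run on synthetic data generated at
run time: genomes ≈15 kb, alignments ≤3,000 sites, trees ≤16 taxa, 50
bootstrap replicates, 10 experiment seeds — sizes chosen so the whole
suite completes in minutes while every qualitative claim is exercised.
Every stochastic step takes an explicit seed and is bit-for-bit
reproducible; the acceptance script derives all randomness from its
`--seed` argument. Statistics for the deposited GenBank records
(JN990598–JN990601) are recomputed only when the flatfiles are supplied
locally, since they are not redistributable inside the package.
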