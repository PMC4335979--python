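# Methods

## Scope and model of the analysis

The package reconstructs, end to end, the comparative-genomics chain used
to delimit a transporter gene family across yeast proteomes and interpret
its evolutionary history: reciprocal-best-hit screening defines
membership, progressive alignment plus block filtering prepares the data
for distance phylogenetics (NJ/BioNJ with bootstrap), and duplication–loss
parsimony reconciliation against a species tree turns the gene tree into
an event narrative. Two further components capture the family's
functional side: a degenerate-motif scanner for the TM7 transporter
signature and least-squares estimation of substrate consumption rates
from concentration time series. Maximum-likelihood tree inference,
TM-topology and ubiquitination predictors, synteny detection, and all
wet-lab procedures are deliberately out of scope.

## Sequence search and statistics

Local and global alignments use affine gap costs, `open + (L−1)·extend`
for a gap of length L, with BLOSUM62 and open 11 / extend 1 as defaults —
the standard protein-search configuration. The dynamic program is
delegated to Bio.Align.PairwiseAligner (whose gap convention matches this
definition exactly); the package's own test oracles re-derive scores by
exhaustive enumeration at small lengths, keeping the check independent of
the engine. Hit significance is the Karlin–Altschul expectation
`E = K·m·n·e^(−λS)` with the gapped BLOSUM62-11/1 parameters λ = 0.267,
K = 0.041 and n equal to the subject proteome's total residue count; the
default admission cutoff is E ≤ 1e-10. Heuristic seeding (word hits),
composition-based statistics and low-complexity masking are not
implemented: decoys in the synthetic data are uniform random, so the
exact scan is both feasible and unbiased.

In the reciprocal screen, "top hit" means the best (E-value, score) with
ties broken by subject id for determinism — except that subjects *exactly*
tied at the best score are all carried forward (and a reciprocal top tie
counts if any tied partner is a seed). With real, diverged sequences exact
ties essentially never occur, so this behaves as a single-top-hit screen;
on degenerate inputs (identical paralogs) it avoids the arbitrary loss of
tied copies.

## Multiple alignment and block filtering

Progressive alignment builds an NJ guide tree on pairwise
global-alignment distances (1 − identity/100) and merges profiles
bottom-up with profile–profile Needleman–Wunsch; the column score is the
arithmetic mean of substitution scores over all residue–residue pairs,
with the same affine penalties for gap states, and end gaps are
penalized. Tie-breaking prefers column–column steps. This is a
deliberately plain progressive scheme: consistency objectives and
iterative refinement (MAFFT-style) are non-goals, and the simulator
introduces no indels, so alignment difficulty in the tested regime comes
from substitution noise only — results on indel-rich real data will be
rougher than the tests suggest.

Block filtering keeps maximal runs (≥ `min_block_length`, default 3) of
columns whose gap fraction is ≤ 0.5 and whose most frequent residue
(gaps excluded) reaches ≥ 0.5 of the residues. The filter is idempotent.
These defaults are mild and exposed in configuration; they mimic the
spirit, not the exact flank/anchor semantics, of classic conserved-block
editors.

## Distance phylogenetics

p-distances use pairwise deletion; columns where either row has a gap or
an unknown residue ('X') are excluded for that pair (unknowns never count
as matches or mismatches). Corrections: Poisson `−ln(1−p)` and gamma
`α((1−p)^(−1/α)−1)` with user-supplied α (default 1.0); since
maximum-likelihood optimisation of α is out of scope, no particular α is
claimed as "the" right one. p > 0.99 is treated as saturated — an error
by default, or capped (default cap 10 substitutions/site) when requested.

NJ follows Saitou–Nei with Q-minimisation ties broken by the
lexicographically smallest representative label pair, and negative branch
lengths clamped to zero with the deficit moved to the sibling edge
(PHYLIP convention). BioNJ uses the same selection criterion but the
variance-weighted reduction, with the weight λ clamped to [0, 1] and the
distance matrix itself as the default variance matrix. Both are
consistent on additive inputs; the suite verifies exact topology and
total-length recovery there, and BioNJ's average non-inferiority under
±2% multiplicative noise. Bootstrap resamples columns with replacement to
the original length; replicates whose distances saturate are skipped,
warned about and counted. Supports of trivial bipartitions are 100 by
convention. Outgroup rooting places the root at the midpoint of the edge
separating a (unrooted-sense) monophyletic outgroup, carrying supports
over the inverted edges.

## Duplication–loss reconciliation

Gene trees must be rooted and binary; polytomies are rejected rather than
silently resolved, because resolution changes event counts. The LCA
mapping is computed bottom-up; a node is a duplication iff its image
equals a child's image; losses on edge (v, c) number `path − 1` edges for
a speciation and `path` for a duplication, each placed on the species
branch skipped by the child mapping. These counts are the
duplication–loss parsimony minimum (verified against exhaustive search
over all ancestrally-valid mappings for random instances). The
per-branch scenario report derives gene-copy flow from explicit lineage
segments, so the identity `copies_out = copies_in + duplications −
losses` is an emergent consistency check. User-asserted ortholog pairs
(e.g. from synteny evidence) can be validated post hoc — a pair whose
gene-tree LCA is a duplication is flagged — but no synteny inference is
attempted.

## Synthetic data: what it does and does not emulate

The species-tree generator draws a Yule topology with exponential branch
lengths of mean 0.1 substitutions/site (a free choice — real species-tree
branch lengths are data-derived — exposed as `branch_length_mean`). Gene
families evolve forward along the species tree as a linear birth–death
process: exponential waiting times with competing duplication
(default 0.3 per unit branch length) and loss (default 0.1) risks;
duplications split a lineage in place, losses terminate it, and the full
event list is retained as ground truth alongside the pruned surviving
gene tree. Sequences evolve under the 20-state equal-rates model — chosen
because its closed forms (e.g. expected p-distance
`0.95(1 − e^{−(20/19)rt})` and the 1/20 saturation identity) make exact
oracle tests possible — with 500-residue family proteins (a typical
transporter length) embedded among 20 uniform-random decoys per proteome
of length 200–800. Consumption curves are piecewise-linear decays clipped
at zero with Gaussian noise (default panel: c0 = 10 g/L, 12 samples over
40 h, noise 0.05 g/L).

Passing the recovery tests therefore demonstrates correctness of the
algorithms under these idealized conditions; it does not bound
performance on real proteomes, where indels, rate heterogeneity,
compositional bias and paralog-specific selection all degrade signal.

A point worth documenting for reuse: exact parsimony/truth equality in
the recovery tests is asserted only on replicates whose history is
*fully observable* — every duplication kept extant descendants on both
sides and remains anchored at its true branch (the species LCA of its
survivors is the branch it occurred on), every extinct speciation side is
a bare loss that died childless in its birth branch, and the founding
speciation kept both sides. Outside that set parsimony provably
under-counts (events above the surviving root or collapsed under a
displaced duplication are invisible), and only the ≤ inequality is
asserted. The predicate was validated against exhaustive simulation.

## Rate fitting

Consumption rates are negated OLS slopes of concentration on time; R² is
the squared Pearson correlation, matching the convention of printed
rate/R² tables. The default window stops before the first observation at
or ≤ 0 g/L, because post-depletion zeros bias slopes toward zero.
Constant or increasing series yield rate 0 with a warning rather than an
error. Segmented fits split at a user-supplied breakpoint (default 22 h,
the growth transition of the published panel) with the boundary sample in
both windows; automatic changepoint detection is a non-goal. Ratios are
computed in decimal arithmetic on the stated rates and rounded
half-away-from-zero at the displayed precision, with the unrounded value
always retained — published tables of this kind contain ratios that are
not the quotient of their printed rates at any standard rounding, and the
package records rather than reconciles such discrepancies.

## Numerical and interface conventions

All sequence coordinates shown to users are 1-based inclusive (residue
numbering like N379); internal indices are 0-based. Residue alphabet: the
20 canonical amino acids plus 'X'; '*' and gaps are rejected in proteome
input. The Newick dialect parses numeric internal labels in [0, 100] as
bootstrap supports and others as node names; quoted labels are
unsupported. Every stochastic component takes an explicit seed, and the
pipeline derives per-stage seeds from one master seed by hashing the
stage name, so a single integer reproduces every artifact byte-for-byte.
Problem sizes in the shipped checks (50 end-to-end replicates, 300
reconciliation instances, 200 NJ matrices, 500 rate series, 1000 scanned
sequences) were chosen as the smallest panels at which the Monte-Carlo
margins are comfortably resolved.

## Known limitations

No maximum-likelihood or Bayesian tree inference; no empirical
substitution matrices in the simulator; no indel simulation; no
duplication–transfer–loss models; no heuristic search acceleration (the
exact scan is quadratic per pair and intended for family-scale, not
genome-scale, inputs); bootstrap uncertainty is not propagated into the
reconciliation.
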