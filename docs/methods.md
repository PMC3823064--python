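# Methods

This note documents the models, statistics and design choices behind
`specswap`, in the spirit of a methods appendix: what each component
assumes, which knobs matter, and what the synthetic-data tests do and do
not demonstrate.

## Scope and conventions

The package covers the *analysis* chain for substrate-specificity evolution
in subfamily Iα aminotransferases: structure-anchored position selection,
divergence scoring and grouping, conservation statistics, two-substrate
kinetic fitting with specificity classification, and binary-trait parsimony.
It deliberately excludes upstream tool-chain steps (multiple-alignment
construction, tree inference, structural alignment, database searches) and
probabilistic function-prediction models; alignments, structures, trees and
rate tables enter as files in standard formats.

Residue numbers are 1-based as printed in PDB coordinate files; alignment
columns are 1-based; all intervals are closed unless stated. Alignments are
aligned FASTA only (one canonical dialect keeps round-trips byte-exact);
trees are Newick, forced-rooted on parsing, with unifurcations collapsed;
rate tables are comma- or tab-delimited with headers
`enzyme,substrate,conc_aa_mM,conc_cosub_mM,conc_e,rate`, and unparseable
rows are skipped with a logged warning rather than aborting (lab exports are
messy; silent loss is avoided by logging). PDB parsing is delegated to
Bio.PDB (first model only; altLoc other than blank/'A' skipped for a
deterministic atom set).

## Active-site shells

For each polymer residue the distance to the target group is the minimum
Euclidean distance over all (residue heavy atom, target heavy atom) pairs.
Hydrogens are excluded by default — the crystal structures this targets do
not resolve them. When both a cofactor (PLP) and a ligand (e.g. maleate)
are selected, the minimum is taken over the union of their atoms.

Shells are assigned by ascending radii with closed boundaries: shell *i* is
the smallest *i* with distance ≤ r_i; beyond the last radius a residue is
unshelled. Defaults are 3.40 Å (first shell — direct contact range),
then 11.3, 16.3, 22.0 Å, i.e. roughly 5 Å per shell; the second-shell
boundary is not independently anchored and is set by linear interpolation
between the stated anchors. All radii are configurable. The 15 Å cutoff
used for D&V position selection measures to the cofactor only by default
(the selection criterion names the cofactor alone); measuring to
cofactor+ligand is a config switch (`distance_target`).

## Conservation statistics

**Column profiles.** Per column: counts over the 20 amino acids plus gap,
the modal residue, its fraction *over non-gap residues*, and the gap
fraction. The gap-free denominator matches the intent of "the same amino
acid in X% of sequences" being about residues; gap handling is explicit and
separate. All-gap columns have modal fraction 0 by convention.

**q-scores.** The per-column quality score is on a 0–100 scale: 100 iff the
column holds a single residue type with no gaps, 0 for all-gap columns. The
default scorer projects each residue onto substitution-matrix profile space
(its BLOSUM62 row over the 20 amino acids), takes the column consensus as
the mean profile vector of non-gap residues, and scores each sequence
`1 − d/D` (d = Euclidean distance to consensus, D = largest inter-residue
profile distance); gaps score 0; the column score is 100 × the mean. This
follows the documented ClustalX construction, but the exact historical
ClustalX parameterization is not recoverable, so the scorer sits behind a
registry (`scorer="profile" | "simple"`, the latter being
100 × modal fraction × (1 − gap fraction)); any published q-score sums are
treated as regression anchors, not targets.

**Permutation test.** Is the q-score sum of k designated columns (the first
shell) high relative to k columns drawn at random? The null resamples k
columns without replacement from the eligible set (by convention, columns
ungapped in the structure's reference sequence), `n_perm` times (default
100,000). The p-value uses the add-one estimator
p = (1 + #{null ≥ observed}) / (1 + n_perm), which is never zero and is the
natural summary when no null draw reaches the observed sum. Observed
positions are required to be eligible (overridable, logged). Draws are
vectorised in blocks; results are bit-reproducible given the seed.
Calibration is tested: when the "observed" set is itself drawn from the
null, p-values are uniform (KS test at α = 0.01, 500 replicates at
n_perm = 2000).

**Conserved sets and Venn partition.** A column is conserved in a sequence
subset at level L (default 0.75) when one residue (gaps excluded) occurs in
≥ ceil(L·n) of the subset's sequences — the ceiling rule reproduces the
conventional "at least 15 of 19 / 9 of 12 / 6 of 7" count thresholds. The
Venn partition of two specificity classes A and B reports: columns
conserved in the pooled A∪B set (intersection), and the per-class conserved
sets minus the other class's (A-only, B-only). Membership ignores *which*
residue is conserved, so a column conserved as Ala in A and Ser in B lands
in both per-class sets and in neither "only" set; the two "only" sets are
disjoint by construction.

**Percent identity** is 100 × identical columns / columns where both
sequences are non-gap.

## D&V selection

Selected positions satisfy distance < d_max (strict; default 15 Å) and
f_low ≤ modal fraction < f_high (default [0.25, 0.75) — "at least 25% but
fewer than 75%"). Columns are joined to structure residues through the
reference sequence's non-gap columns (k-th non-gap column ↔ k-th polymer
residue; an explicit offset is required on length mismatch).

A candidate's D&V score adds 1 for each selected position where its symbol
differs from the symbol of *every* reference-panel sequence; the
contributing columns are recorded. Gap handling: gap vs residue counts as
different, gap vs gap as identical (gap as 21st symbol — the least
surprising rule; configurable in principle via preprocessing). The score is
monotone non-increasing in panel size.

The pairwise score s(i→j) counts mismatches between i and j over *i's*
contributing columns, and is therefore generally asymmetric. Candidates
with a score strictly above the shortlist threshold (default 10) advance.
Grouping draws an undirected edge between i and j when s(i→j) < cutoff AND
s(j→i) < cutoff (default 9) and takes connected components — the pair rule
defines edges, and chaining to components is the closure that makes groups
disjoint. Representative choice is pluggable: `lex` (deterministic default;
the historical criterion, gene availability, is not computable),
`max-score`, or `manual`.

## Kinetics

The ping-pong bi-bi initial-rate law without substrate inhibition is

    v = [E] kcat A B / (Km_A B + Km_B A + A B),   A = [amino acid], B = [co-substrate]

with the first-order limit v = [E] (kcat/Km_A) A when A ≪ Km_A and B is
held saturating. Concentrations are in mM, [E] in M, rates in the same
units as [E]·s⁻¹; specificity constants are reported in M⁻¹s⁻¹.

Fitting is unweighted nonlinear least squares (relative 1/v² weighting is
available; published fits do not state a weighting) on the turnover scale
v/[E], so convergence tolerances are meaningful regardless of enzyme
concentration. Initialisation uses a Hanes linearisation (A/v vs A) at the
highest co-substrate levels; bounds keep all parameters positive; standard
errors come from the local curvature (covariance of the fit). The reduced
model is exact closed-form least squares through the origin on
(A, v/[E]).

**No-saturation (NS) rule.** In `auto` mode the full model is fitted first
and the assay is declared unsaturated when the fitted Km_A exceeds the
highest tested concentration (capped at the 40 mM bound that is routinely
attainable) or its standard error is unbounded (≥ the estimate); the data
are then refitted with the reduced model and only kcat/Km is reported —
mirroring how "NS" rows are tabulated.

**Classification.** The specificity ratio is
(kcat/Km)_Asp / (kcat/Km)_aromatic, rounded to two significant figures
(round-half-even, matching tabulated precision): > 1 ⇒ AATase, < 1 ⇒
TATase, exactly 1 at the reported precision ⇒ ambiguous. Re-dividing
*published rounded* constants reproduces the published ratio column for
eAAT, AtmAT, GicAT, PfcAT, PaAT, TbmAT and VcAT; the remaining rows (e.g.
CtAT 470, SccAT 3,600, CecAT 80,000) were evidently computed from unrounded
fits and do not round-trip — this is a property of the published table, not
of the classifier, and those rows are not used as checks.

## Parsimony

Binary-trait small parsimony (states AAT/TAT) on a rooted tree with
partial leaf annotations, by Sankoff dynamic programming with unit change
cost (equivalent to Fitch on two states but supporting root constraints and
missing leaf states directly). Unannotated leaves are free variables
optimised over, not pruned — matching how one reasons about a large tree
with few characterized leaves. The root-constrained variant fixes the root
symbol; the minimum over root constraints equals the unconstrained minimum.

Co-optimal structure is summarised two ways: the number of optimal
labelings (a product-sum DP, cheap at any size), and the switch edges. Full
enumeration of optimal labelings is exponential in the number of free
nodes, so `enumerate_switch_edges` enumerates only below a configurable
limit; the *union* of candidate switch branches is always available exactly
via a per-edge constrained DP (force the edge to switch, re-optimise along
its ancestor chain, accept if the optimum is unchanged).

The leave-one-out predictor masks one annotated leaf and returns the set of
states it takes across all minimum-change labelings; a singleton is a
confident call, both states is undecided (scored as incorrect by default —
conservative; half credit is a flag).

## Synthetic data

The generators define the test conditions:

* **Alignments** (default 92 sequences × 400 columns, gap probability 0.05,
  matching the scale of the real subfamily alignment): per column, the
  modal residue is assigned to round(target × n_nongap) sequences and the
  rest draw uniformly from the other 19 amino acids, so realized modal
  fractions match targets up to rounding; the reference row is kept
  gap-free so it maps 1:1 onto a structure. Not emulated: phylogenetic
  correlation between sequences, indel structure, residue covariation — so
  conservation tests here validate counting and calibration, not robustness
  to tree-structured correlation.
* **Structures**: one CA atom per residue placed at the planted distance in
  a random direction from a single-atom pseudo-cofactor at the origin.
  Exact distance control, no sterics or secondary structure; suitable for
  verifying geometry code, not for any physical claim.
* **Kinetics** (default: 8 amino-acid levels 0.25–40 mM × 3 co-substrate
  levels 0.5–10 mM, [E] = 10 nM, 1% multiplicative Gaussian noise —
  constant CV, the way initial-rate assay error scales; negative draws are
  resampled): rates exactly on the ping-pong law times (1 + ε).
* **Trees**: a spine of k+1 blocks in which each of k blocks pairs a
  root-state clade with a flipped clade. Each block is a disjoint subtree
  containing both states, which lower-bounds the parsimony minimum at k,
  and switching exactly the k flipped stems achieves it — so the planted
  switch count is provably the parsimony minimum (feasible for
  n_leaves ≥ 2k+1). The `fig3_like_tree` preset is a deterministic ~92-leaf
  tree with 12 AAT + 7 TAT annotations, the TAT leaves in three separate
  clades nested such that an AAT-constrained root yields 3 switches and a
  TAT-constrained root 5. It is a consistency preset reproducing the
  published annotation pattern and switch counts, *not* a reconstruction of
  the published topology, which is not machine-readable.

## Problem sizes in the test suite

The suite and the acceptance script use sizes chosen to exercise every code
path at interactive speed: 20×50 alignments over 100 seeds for the D&V
oracle comparisons, 200 replicates of n = 30-point kinetic fits at 1%
noise, exhaustive-enumeration parsimony oracles on 200 random trees of ≤ 8
leaves (where 2^(free nodes) enumeration is exact and fast), permutation
calibration at n_perm = 2000 × 500 replicates, and the 92-leaf preset for
the root-constraint comparison. Published alignment-scale quantities that
require the original UniProt sequences and PDB entries 1ASN/1ASM (q-score
sum 1446/1600, permutation maximum 1107, 76 D&V positions, the Table of
percent identities, Venn counts 71/39/21) are accepted as inputs when those
files are supplied locally but are not recomputed offline; the pipeline's
contract on externally-shaped inputs is exercised with synthetic stand-ins.

## Known limitations

* The q-score is a faithful implementation of the documented construction,
  not a bit-for-bit ClustalX clone; absolute q-sums should be compared only
  within a scorer.
* The ping-pong law omits substrate inhibition; strongly inhibited assays
  would need an extended model.
* NS detection is a heuristic threshold rule; near-boundary Km estimates
  (Km within a factor ~2 of the maximum tested concentration) can flip
  between full and reduced reports, which is why the bound is configurable.
* Parsimony treats switch costs as symmetric and unit; no branch-length or
  likelihood information is used.
* The leave-one-out predictor is a deliberately simple phylogeny-only
  baseline; it is not a reimplementation of posterior-probability methods.
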