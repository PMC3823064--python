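# specswap

Tools for studying how substrate specificity evolves in subfamily Iα
aminotransferases — the PLP-dependent enzymes that interconvert amino and
keto acids and split into narrow-specificity aspartate aminotransferases
(AATases) and broad-specificity aromatic aminotransferases (TATases).
Sequence identity is a poor predictor of which is which: two enzymes can be
>40% identical and prefer different substrates. `specswap` implements the
computational chain used to pick divergent enzymes for characterization and
to interpret the results:

* **Active-site shells** — per-residue minimum heavy-atom distances to the
  PLP cofactor (and optionally a bound ligand) from a PDB structure, with
  radial shells (first shell ≤ 3.40 Å, then ~5 Å spacing).
* **Conservation statistics** — ClustalX-style per-column quality scores
  (q-scores, 0–100), a permutation test of whether active-site columns are
  more conserved than random columns, ≥75% conserved-column (Venn) sets per
  specificity class, and pairwise percent identity.
* **D&V selection** — the distance-and-variability score: positions < 15 Å
  from the cofactor with moderate variability (modal residue in 25–75% of
  sequences) are selected; a candidate scores +1 per position where it
  differs from *every* member of a characterized reference panel. Asymmetric
  pairwise scores over each candidate's contributing positions, thresholded
  at < 9 in both directions, chain candidates into groups from which
  representatives are picked.
* **Ping-pong bi-bi kinetics** — nonlinear fitting of

  $$v = \frac{[E]\,k_{cat}\,[AA]\,[\alpha KG]}{K_m^{AA}[\alpha KG] + K_m^{\alpha KG}[AA] + [AA][\alpha KG]}$$

  with a first-order fallback $v = [E]\,(k_{cat}/K_m)\,[AA]$ when the amino
  acid cannot be saturated (fitted $K_m$ above the highest tested
  concentration, default 40 mM). The specificity call is the ratio
  $(k_{cat}/K_m)_{Asp} / (k_{cat}/K_m)_{aromatic}$: > 1 ⇒ AATase, < 1 ⇒
  TATase (reported at two significant figures).
* **Parsimony on the phylogeny** — binary-trait small parsimony (Sankoff DP
  with unit costs) over a rooted tree with partial AATase/TATase leaf
  annotations: minimum switch counts with free or fixed root state,
  candidate switch branches, and a leave-one-out parsimony predictor.
* **Synthetic data** — seeded generators for every input (alignments with
  planted column conservation, structures with planted cofactor distances,
  rates from the ping-pong law plus noise, trees with planted specificity
  switches), so the whole pipeline is testable offline.

## Worked example

Fit simulated rate data (1% noise) and classify (`examples/02_kinetic_fitting.py`):

```
saturating enzyme (truth: kcat=100 /s, Km_AA=2.0 mM, Km_cosub=0.5 mM)
  model: full
  kcat      =  100.02 +/- 0.30 /s
  Km_AA     =   1.997 +/- 0.018 mM
  Km_cosub  =   0.498 +/- 0.006 mM
  kcat/Km   = 50,095 /M/s

non-saturating enzyme (truth Km_AA = 400 mM, max tested 40 mM)
  model: reduced (saturation not reached -> NS-style report)
  kcat/Km   = 112 /M/s (only this is identifiable)
```

The full model recovers all three parameters within one standard error;
when saturation is unreachable the fit honestly degrades to the first-order
slope, i.e. only the specificity constant is reported.

Count specificity switches on the preset 92-leaf annotation pattern
(`examples/05_parsimony_switches.py`):

```
preset: 92 leaves, 19 annotated
unconstrained minimum switches: 3 (optimal root state: ['AAT'])
  root fixed to AAT: 3 switches
  root fixed to TAT: 5 switches
```

With the 7 TATase annotations split over three clades, an AATase root
explains the data with 3 independent switches while a TATase root needs 5 —
parsimony support for an aspartate-preferring ancestor.

The other scripts in `examples/` walk through specificity-ratio
classification from published constants, active-site shell assignment plus
the conservation permutation test, D&V scoring and grouping, and the full
pipeline run from one YAML config.

## Command line

Each stage is also exposed as a thin CLI over the library:

```bash
specswap simulate structure --seed 3 --out sim.pdb
specswap shells --structure sim.pdb --cofactor PLP --radii 3.4,11.3,16.3,22.0
specswap permtest --aln aln.fasta --positions 5,12,40 --eligible-ref AAT_ECOLI --n-perm 100000 --seed 1
specswap parsimony --tree tree.nwk --states states.tsv --root TAT
specswap run --config config.yaml --out report/
```

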