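# Methods

## Scope and model

`tmic7` implements a tertiary-structure screening procedure for detecting
remote homologs of seven-transmembrane-domain ion channels (7TMICs) — the
superfamily containing insect odorant and gustatory receptors — together
with the sequence-side analyses used to curate candidate families and
reason about their relationships when multiple alignment is impossible.
The premise is that tertiary structure is conserved far beyond primary
sequence in this superfamily (members can share under 10% amino-acid
identity), so candidates are found by structural similarity to an
experimentally determined insect Or co-receptor subunit and then vetted by
membrane-topology criteria and fold features.

All structural computation is C-alpha-only.  The scores used in the screen
(TM-score, distance-matrix elastic score) are defined on C-alpha traces,
so full-atom detail would add nothing to any quantity the package reports.

## Structural alignment (superpose)

`tm_align` is an implementation of the TM-align search strategy, not a
bit-exact clone of the released binary:

- **Pair score**: `1/(1 + d_ij^2/d0^2)` with
  `d0 = 1.24 (L_norm - 15)^(1/3) - 1.8`, floored at 0.5 Å so tiny chains
  (L ≤ 21) keep a positive scale.
- **Initial alignments**: best two gapless threadings, one
  secondary-structure-string alignment (helix/strand/coil assigned from
  C-alpha distance patterns), and the two best-RMSD fragment
  superpositions (fragment length 20, coarse grid).
- **Refinement**: iterate superposition (on the current pair subset,
  distance-trimmed) and global dynamic programming with gap-open −0.6 (the
  classic TM-align value; no extension penalty) until the path is stable or
  30 iterations.  Ties between candidate paths break toward the
  lexicographically smaller path, making the search deterministic.
- **TM-score** of the final path is maximized over superpositions of
  aligned subsets by the standard iterative-extension heuristic (full set
  plus half-length fragment seeds, distance cut starting at max(d0, 3 Å)).
  Both normalizations (query and target length) are always computed; the
  single reported value defaults to query normalization, since in the
  screening use-case the query is constant across a table of comparisons
  and per-row query normalization is the only self-consistent choice.

The inner DP is compiled with numba; on ~250-residue chains one pairwise
alignment takes ~0.3 s on one CPU.

## Elastic (distance-matrix) score and Z calibration (distscore)

The elastic score over an alignment path sums, over ordered pairs of
aligned positions,

```
(0.20 - |dA_ik - dB_jl| / d*) * exp(-(d*/20 Å)^2),   d* = (dA_ik + dB_jl)/2
```

with diagonal terms contributing 0.20.  This is the Dali functional form;
however the published Dali server's size normalization is internal to the
server, so this package's Z-score is an openly documented empirical
approximation and **no attempt is made to reproduce printed Dali Z
values** — only rank order and band behavior are meaningful.

Two consequences of approximating Dali this way deserve explanation:

- **Path trimming.** Dali optimizes its alignment against the elastic
  score itself; this package derives the path from the TM-score search
  instead (no Monte-Carlo optimizer, keeping the screen deterministic and
  fast).  A TM-score-optimal path retains pairs that are geometrically
  inconsistent under the distance-matrix criterion; scored raw, unrelated
  pairs then produce strongly negative scores with enormous variance,
  which destroys the Z scale the screen operates on.  The scoring channel
  therefore first applies a deterministic greedy trim
  (`optimize_path_subset`): repeatedly drop the aligned pair with the most
  negative marginal contribution until all remaining pairs contribute
  non-negatively.  This plays the role of Dali's optimizer restricted to
  subsets of the structural alignment path.  `elastic_score` itself is the
  untrimmed formula and is tested exactly against a brute-force double
  sum.
- **Empirical background.** `calibrate_background` aligns a seeded random
  sample of decoy pairs (all pairs would cost hours at ≥100 decoys and add
  nothing; the fit is stable from a few hundred pairs), then fits the
  background mean and standard deviation of the trimmed elastic score as
  smooth functions of effective pair size `sqrt(L_A · L_B)`.  The shipped
  table (`src/tmic7/data/calibration.tsv`, plain text, versioned) was
  fitted on 120 synthetic decoys spanning lengths 100–600.
  `z_score = (raw - mean(L)) / sd(L)`; requests outside the calibrated
  size range are flagged as extrapolation.

Homology bands follow the conventional Dali reading: Z > 20 definite,
8–20 probable, 2–8 gray, < 2 none; boundary values go to the higher band
(the choice is arbitrary but deterministic; real screens never hinge on an
exact boundary value).  The screen threshold defaults to Z > 10.

## Topology and fold features (topology)

External predictor output is ingested as a 3-column table (id, segment
label, 1-based inclusive range); segments must tile the sequence and
membrane segments must alternate sides.  A built-in stand-in predictor
(Kyte–Doolittle window 19, cutoff 1.6, membrane runs ≥ 15, orientation by
the positive-inside rule over 15-residue flanks) lets the pipeline run
with no external tool; it is a hydropathy heuristic, not a reimplementation
of a neural predictor, and is only relied on for synthetic sequences whose
composition makes the assignment unambiguous.

Candidate criteria: (i) exactly seven membrane segments; (ii) intracellular
N-terminus; (iii) summed intracellular loop length greater than summed
extracellular loop length, terminal tails excluded.  Criterion (iii) is
qualitative in origin; the summed-length reading is robust to a single
short loop, which matters because intracellular loop lengths vary
enormously across the superfamily.

Fold features are computed from the structure plus its topology: the
membrane slab is the 30 Å layer (standard hydrophobic bilayer thickness)
along the mean TM-helix axis that maximizes membrane-residue occupancy,
with plateau ties broken toward the median membrane projection; the
TM7a/7b split requires a helix break (≥ 2-residue non-helical gap or
≥ 20° axis kink) inside the seventh membrane segment with one sub-helix
beyond the cytosolic slab face and the other inside the slab; the anchor
projection requires helices 4–6 each to extend ≥ 10 Å beyond the cytosolic
face.  All quantities are projections onto the estimated membrane normal,
so the features are invariant under rigid motion.  Fold features are
reported but deliberately not used as hard gates in the screen — they
automate what is fundamentally a visual judgement.

## The screen (screen)

`run_pipeline` composes: forward screen (every library member aligned to
the query; elastic Z; keep Z > threshold, rank descending with id
tie-break), reverse validation (candidate used as query against a
reference structural proteome; passes iff the top-1 hit is in the target
family — the strictest defensible reading of "most similar proteins
reversed"; the top-k family fraction is reported), topology criteria, fold
features, and control bands ("clearly superior to negative controls"
operationalized as candidate z > max negative z AND TM > max negative TM).
`final_call` is `candidate` only if threshold ∧ reverse ∧ topology ∧
above-negative all hold; hits without topology are `ambiguous`.

## Sequence side (seqkit)

- **Curation**: drop records flagged partial/low-quality/ambiguous,
  collapse 100%-identical duplicates (first-seen id kept), drop records
  with fewer than 4 predicted TMs (a permissive count chosen to tolerate
  predictor sensitivity differences); idempotent, with per-filter counts.
- **Clustering**: greedy longest-first at 70–90% identity, identity =
  matches / global alignment length including gaps (edit-distance global
  alignment via edlib); the longest sequence represents each cluster.
- **Network**: all-to-all Smith–Waterman (BLOSUM62, gap 11/1, Biopython's
  aligner) with Karlin–Altschul E-values using ungapped BLOSUM62
  parameters on gapped scores — a documented approximation; the reference
  workflow used a different engine, so only relative structure (clusters,
  the weak-edge tag at E > 1) is meaningful, never specific E-values.
  Edges kept at E ≤ 10; self-comparisons excluded.
- **Graph splitting**: recursive spectral bipartition with edge weights
  `-log10(E)` floored at 0, normalized Laplacian, Fiedler-vector sign;
  disconnected parts split by component.  Topology-only trees (branch
  lengths are not estimated — these trees are used for grouping, not
  rates).
- **Supports**: edge perturbation — each replicate multiplies every edge
  weight by an independent log-normal factor (σ = 0.5 by default; the
  reference method does not specify its perturbation distribution, so
  supports are comparative, not absolute), trees rebuilt per replicate,
  and per-branch transfer bootstrap expectation
  `100·(1 − mean transfer distance/(p−1))` reported.
- **Motifs**: patterns like `TYhhhhhQF` with h = {A,V,L,I,M,F,W,Y,C}
  (configurable) and explicit alternative sets `(H/N)`; best window per
  degapped region with per-position conformity.
- **Introns**: phase = cumulative CDS length at the junction mod 3;
  affected residue = floor(cumulative/3), mapped through the gapped
  alignment row to a column, so homologous introns land in the same
  column.

## Synthetic data (synthetic_data)

The generator produces every input class with planted ground truth:

- **Bundles**: idealized α-helices (1.5 Å rise, 100°/residue, C-alpha
  radius 2.3 Å) packed on a circle (~9.4 Å spacing), intracellular
  N-terminal tail, intracellular loops (14 aa) longer than extracellular
  ones (8 aa), membrane-spanning helices of 25 aa — a 7-helix bundle
  passes all three candidate criteria by construction.  Optional planted
  TM7a (tilted sub-helix below the slab + 2-residue non-helical connector)
  and anchor extensions of helices 4–6.  Sequences are composed to make
  hydropathy topology recovery unambiguous (hydrophobic TM cores,
  K/R-rich intracellular loops, acidic extracellular loops).
- **Homolog series**: per-axis Gaussian C-alpha noise (σ in Å); used for
  score-decay and calibration operating points (σ = 2 Å plays the "true
  remote homolog", σ = 5 Å is near the random-similarity regime).
- **Decoys**: non-7TM helical bundles (3–12 helices, never 7; randomized
  packing radius, helix tilt up to 25°, lengths, loops) and extended
  zigzag chains, plus 0.8 Å jitter and a random rigid motion; lengths
  drawn from the requested range (100–600 for the shipped calibration).
- **Families**: point-substitution evolution from family ancestors with
  exact mutation counts, solving the per-site rate so realized pairwise
  identities match the within-family (0.92) and between-family (0.40)
  targets; no indels by default so identity targets stay exact.  The
  first member of each family carries a 5-residue extension so
  "longest representative" is well-defined.  Optional injected partial/
  ambiguous/low-quality/duplicate records for curation tests.
- **Gene models**: two-exon CDS with the intron planted at a requested
  residue and phase.

What this emulates — and does not.  Idealized geometry tests score
monotonicity, calibration, and feature detectors, not biophysics: there is
no loop realism, no cryo-EM noise or model-confidence emulation, no indel
evolution unless enabled.  Passing tests therefore demonstrate that the
procedures are correct and well-calibrated on structures whose ground
truth is known, not that real predicted proteomes will show the same
error rates.

## Problem sizes and numerical choices

The test suite and acceptance script run at desk scale: screens of 5
planted homologs vs 50 decoys, calibration checks on dozens of held-out
decoy pairs, 12-node networks, ≤ 30-residue chains for exhaustive oracle
comparisons.  These sizes were chosen so the full suite completes in
minutes on one CPU while keeping every statistical check adequately
powered.  Degenerate inputs are errors, not silent results: empty
alignment paths, empty structures, all-masked chains, non-tiling
topologies, sd ≤ 0 backgrounds.

## Known limitations

- The Z-score is calibrated against synthetic decoys; absolute values are
  not comparable to published Dali Z values (rank order within a screen
  is).
- The TM-align search is heuristic; scores can differ from the reference
  binary by a few hundredths, and symmetry between orderings is only
  guaranteed to ~0.02.
- The hydropathy topology stand-in is deliberately simple and will
  misassign real sequences with charged TM residues or re-entrant loops;
  real predictor tables should be used where available.
- E-values use ungapped Karlin–Altschul constants on gapped scores and are
  comparable only within one network.
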