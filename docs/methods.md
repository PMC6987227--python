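# Methods

This note records the models behind `predba`, the parameter choices that
matter, and what the synthetic fixtures do and do not establish.

## Structure parsing

PDB record reading is delegated to gemmi; the package owns the partition of
residues into protein and DNA chains.  A residue is an amino acid when its
name is one of the 20 standard three-letter codes; it is a deoxynucleotide
when named DA/DC/DG/DT, or named with a bare one-letter base *and* carrying a
C1' sugar atom (the legacy dialect check prevents a stray calcium or alanine
shorthand from being read as adenine).  DU/DI are recognized as nucleotides
so they stay in DNA chains, but sequence extraction refuses them: the
feature set is defined over A, C, G, T only.  Peptide-like nonstandard
residues inside protein chains (e.g. selenomethionine) are kept and rendered
as `X`; waters and ligands are dropped.  Chains mixing amino acids and
nucleotides are rejected rather than split — there is no principled way to
assign a chimera to one side of the interface.  Only MODEL 1 of multi-model
files is used; alternate locations resolve to the highest-occupancy copy
(ties to file order).  Author numbering is preserved because HELIX/SHEET
records reference it.

## Protein features

**Residue classes.**  The literature names the five properties but no
specific sets, so fixed, overridable tables are used: hydrophobic
{A,V,L,I,M,F,W,C,P,G} with hydrophilic as its complement (a
Kyte-Doolittle-style partition, asserted as a partition of the 20 codes);
aromatic-positive {F,W,Y,H,R,K}; polar {S,T,N,Q,C,Y}; charged {D,E,K,R,H}.
`X` belongs to no class but counts toward the length used in percentages.

**Masses.**  Average (not monoisotopic) residue masses with one water per
chain; `X` contributes 110.0 Da, the mean residue mass.  Helix/sheet masses
sum residue masses over annotated residues without a water term (they are
sequence fragments, not chains).

**Hydrogen bonds.**  The Kabsch-Sander electrostatic model:
E = 0.084·332·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN) kcal/mol, bond when
E < −0.5.  The amide hydrogen is reconstructed 1.0 Å from N along the
preceding residue's O→C direction, so chain-first residues (and prolines,
which have no amide H) are never donors.  Same-chain neighbors
(|i − j| ≤ 1) are excluded: the donor's H is built from the peptide bond to
residue i−1, and the i→i−1 "bond" is a covalent artifact that would always
pass the energy test.  A 9 Å CA-CA prefilter bounds the search; at that
separation the four reciprocal terms cancel to well above the cutoff, so the
filter cannot change the count.  Detectors behave identically with or
without deposited hydrogens because the H used is always the reconstructed
one.

**Secondary structure.**  Header HELIX/SHEET records are the default source;
a DSSP-output adapter (column 17: H/G/I → helix, E/B → sheet, contiguous
runs become segments) can replace them when a DSSP file is available.
Segments referencing missing residues are clipped with a warning.  Because
"the amount of the helix" is ambiguous between segments and residues, both
counts (and the residue percentage) are emitted; the fixed per-class feature
sets map "amount" to the segment count and "portion" to the residue
percentage.

**SASA.**  Shrake-Rupley with a deterministic golden-spiral quadrature
(960 points by default; the isolated-sphere error of the spiral at 960
points is below 0.1%, comfortably inside the 2% acceptance band), probe
1.4 Å, radii C 1.70, N 1.55, O 1.52, S 1.80, P 1.80, H 1.20, default 1.70 Å.
The value reported is the SASA of the protein component in isolation
(protein atoms occlude each other; DNA does not occlude the protein) —
"the SASA of the protein", not the buried-interface variant.

## DNA features

**Masses.**  ssDNA: N·303.7 + 79.0; dsDNA: pairs·607.4 + 157.9 with pairs =
round(N/2).  The duplex constant is interpreted per base pair
(607.4 ≈ 2·303.7), which keeps the two formulas dimensionally consistent.
Feature extraction switches to the duplex formula when the detected paired
fraction reaches the duplex threshold (0.6).

**Nearest-neighbor classes.**  A dinucleotide step and its reverse
complement describe the same duplex stack, so the 16 steps collapse to 10
classes; counts accumulate over every adjacent step of every DNA strand
(a duplex contributes both strands), which is deterministic and
class-consistent without choosing a "leading" strand.  Percentages divide by
the total step count.

**Watson-Crick pairs.**  Candidate pairs are complementary
purine/pyrimidine nucleotides with purine-N1 to pyrimidine-N3 distance in
[2.4, 3.5] Å and C1'-C1' distance in [9.0, 11.5] Å (canonical B-DNA
geometry: ~2.9 and ~10.4 Å); greedy matching in ascending N1-N3 distance
gives each nucleotide at most one partner.  G·C pairs are Saenger family
XIX, A·T family XX; their percentages use the total nucleotide count as
denominator.  The cis-WW pair count is the XIX + XX total — the other 26
Saenger families are out of scope.  Nucleotides missing the needed atoms are
excluded with a warning.

**Folding features.**  Ensemble diversity and MFE-structure frequency are
only ever read from an external folding run's output (an adapter, not a
reimplementation of the partition function).  When absent they are NaN and
drop out of ranking automatically; none of the fixed per-class feature sets
uses them.

## Classification

Binding-site residues: any protein atom within 5.0 Å (inclusive) of any DNA
atom, hydrogens included when present.  DNA form from the paired fraction:
≤ 0.2 single-stranded, ≥ 0.6 duplex, otherwise miscellaneous — thresholds
chosen so that a nicked or overhanging duplex still counts as duplex while a
hairpin-free single strand with incidental pairing stays SS; they are
config-exposed.  Duplex subclasses by binding-site percentage with closed
boundaries: exactly 10% is Double I, exactly 20% is Double III (the printed
ranges overlap at the boundaries; the closed rules make the five labels a
partition, which a property test asserts on a grid).

## Affinity

ΔG = −R·T·ln K_d, R = 1.987×10⁻³ kcal mol⁻¹ K⁻¹.  The value is stored
exactly as the formula produces it (positive for K_d < 1 M, a dissociation
free energy) and never re-signed.  Missing temperatures default to 298.15 K
with a warning.  Tables are UTF-8 TSV, '.' decimals, NA for missing.

## Feature selection and the stack

Ranking: |Pearson r| against ΔG, descending, ties broken by catalogue order;
features with missing values or zero variance are excluded; top 10 kept.

Greedy forward selection adds the candidate that maximizes the objective,
stopping at five features or when the improvement is ≤ 1e-4.  The default
objective is the **closed-form leave-one-out Pearson r of a ridge
regressor** (hat-matrix identity, standardized columns, unpenalized
intercept, α = 1e-6).  A cross-validated objective on the full stack is
available (`make_stack_cv_objective`) but costs three stack fits per
candidate evaluation; inside an honest leave-one-out loop that multiplies to
10⁵-10⁶ ensemble fits, which is not a usable default on one CPU.  The ridge
LOO objective evaluates in microseconds, is deterministic, and measures the
same thing the search needs — out-of-sample linear predictive value of the
candidate set — so the selected sets feed the nonlinear stack without having
been chosen by it.

The stack: GBRT (100 trees, depth 3, learning rate 0.1), AdaBoost over
depth-3 trees (50 estimators), bagged unlimited-depth trees (50 estimators)
on the first layer; XGBoost (100 trees, depth 2, learning rate 0.1, L2 = 1.0,
single-thread) on the second.  By default the meta-model trains on
out-of-fold base predictions (K = min(5, n−1) shuffled folds, seeded), after
which the base models are refit on all rows; the naive variant — base models
predict their own training data — is retained as `mode="paper_naive"` for
comparison, but its meta-inputs are in-sample and it overfits badly at the
class sizes this problem presents (n as low as 8).  All randomness derives
from one seed; identical inputs and seed give byte-identical evaluation
reports.

Evaluation: leave-one-out.  "Honest" mode refits ranking, selection and the
stack on every fold (selection happens inside the loop, so the reported r is
not contaminated by the held-out point); "paper" mode fixes the feature set
per class and refits only the stack.  Reported metrics: Pearson r, MAE, and
R² = 1 − SS_res/SS_tot (not squared Pearson — with biased predictions the
two differ, and the explained-variance form is the stricter, standard
reading).  Multi-class summaries average the five classes unweighted.

## Synthetic fixtures

The toy complex generator emulates the *geometry* the detectors consume, not
physical realism: B-form duplex placement (3.4 Å rise, 36° twist) with the
minimal atom set (P, C1', N1 or N3) positioned so every intended pair
satisfies the detection thresholds; unpaired tail nucleotides placed beyond
pairing range; a protein backbone (N, CA, C, O) built from ideal internal
coordinates (α-helix φ = −57°, ψ = −47° over the annotated span, extended
φ = −139°, ψ = 135° elsewhere) and rigidly translated until the nearest
protein-DNA atom distance equals the requested contact distance (±0.01 Å,
iterative closest-pair translation).  Every structure ships with a
ground-truth record (sequences, intended pairs, brute-force binding set,
class label) computed independently of the detectors under test.  Passing
tests on these fixtures establishes that the geometric rules are implemented
exactly as specified; they say nothing about detection robustness on
distorted, modified or partially resolved real structures — no sugar pucker,
propeller twist, side chains or solvent.

The table generator plants a sparse linear signal in i.i.d. standard-normal
features (defaults: 60 rows, 12 features, weights 2 and 1 on two of them,
noise SD 0.1).  Linear-plus-Gaussian is the cleanest recoverable signal for
testing the selection-plus-stack pipeline end to end; real affinity data are
smaller per class, collinear and nonlinear, so recovery there will be
weaker than on these fixtures.

## Numerical and degenerate-input choices

Zero-variance vectors make Pearson r undefined: ranking treats such features
as unusable (excluded), while metric reporting raises.  Greedy candidates
whose design is degenerate (leverage ≈ 1, constant column) are skipped with
a warning; if no candidate is usable the single top-ranked feature is used.
`fit_stack` requires n ≥ 5 and leave-one-out n ≥ 6; smaller classes should
be merged or evaluated with fixed features on pooled data.  Distance
comparisons at thresholds are inclusive (≤), matching the binding-site rule
as stated.  The SASA quadrature, fold splits and all tree seeds are
deterministic functions of the user seed (kept below 2³¹).

## Problem sizes

The test suite and the acceptance script run the honest pipeline at n = 60
(acceptance) and n = 25-30 (unit tests), 50 randomized geometry fixtures,
960-point SASA quadrature (10 000 points for the brute-force enclosure
check), and 1000 random vector pairs for the statistics oracles.  These
sizes mirror the scale of the intended application (classes of 8-33
complexes) while keeping a full run on one CPU in the low minutes.

## Known limitations

- Secondary structure from header records only (or a DSSP file); structures
  deposited without HELIX/SHEET records yield zero helix/sheet features
  unless a DSSP adapter file is supplied.
- Only canonical Watson-Crick pairs are detected; Hoogsteen, wobble and
  sugar-edge geometries are counted as unpaired.
- The binding-affinity model is trained per class; classes with fewer than
  six complexes cannot be evaluated by LOOCV.
- No mmCIF input, no assembly expansion, no network fetch of PDB codes.
- The 52-feature catalogue is this package's declared convention: the four
  feature families are enumerated exhaustively from their definitions, and
  the grouping into exactly 52 named columns is fixed here so tables are
  reproducible.
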