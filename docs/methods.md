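# Methods

This note records the model choices, parameter semantics and numerical
conventions behind `plifdet`, and what the synthetic-data tests do and do
not establish.

## Structures, box and binding-site list

PDB and PDBQT parsing is fixed-column and tolerant: a missing element
column is filled by inference from the atom name (two-letter elements such
as Cl/Br/Zn are recognised outside standard residues, where `CA` is an
alpha carbon). PDBQT elements come from the AutoDock atom-type column
(`A`→C, `OA`→O, `HD`→H, …) and each MODEL block must carry a
`REMARK VINA RESULT` line whose first numeric field is the affinity in
kcal/mol. Coordinates are Å throughout; round-trips preserve them to
3 decimals and atom/residue identity exactly.

The docking box is the heavy-atom axis-aligned bounding box of the
co-crystal ligand, expanded by `margin` (default 5 Å) on each side.
Hydrogens are excluded because their presence and placement depend on the
preparation protocol, whereas the heavy-atom envelope does not. A residue
belongs to the binding site when **any heavy atom** lies in the closed box
(`criterion="any_heavy"`, default; `"ca"` restricts to the alpha carbon).
The resulting list, sorted by (chain, residue number), *defines* the
fingerprint layout: bit k ↔ residue rank ⌊(k−1)/7⌋+1, type ((k−1) mod 7)+1.
The layout and the fixed type order 1–7 are validated against all 23
descriptor indices of the bundled reference listing, which they reproduce
exactly (23/23 type codes, strictly increasing ranks per receptor).

## Interaction detection

Protein typing is a per-residue template table (carboxylates → anion
centres, Lys/Arg → cation centres, Phe/Tyr/Trp/His rings, Ser/Thr/Tyr/…
donors and acceptors, apolar C/S atoms → hydrophobic). Charged-group
centres are midpoints of the equivalent terminal atoms (carboxylate O's,
guanidinium NH's), which is symmetric and orientation-independent. His is
aromatic by default and cationic only on request (`his_cationic`), matching
the edge-to-face role histidines play in aminergic binding sites. With
`nobb=True` (default) backbone atoms are removed from every category before
detection; with `nobb=False` the amide N donates and the carbonyl O
accepts. Unknown residues degrade to hydrophobic-only with a warning.

Ligand typing: bonds by distance (≤ 1.25 × the sum of covalent radii), then
hydrophobic = C/S not bonded to N/O; aromatic = planar (≤ 0.15 Å deviation)
5/6-rings of C/N/O/S; donors = N/O with explicit H, or — only when the pose
carries no hydrogens at all (implicit-H mode) — N/O with free valence;
acceptors = all O plus H-free N of heavy degree ≤ 2; cations = 4-coordinate
N and guanidinium carbons; anions = midpoints of ≥ 2 terminal oxygens on
C/S/P.

Geometric cutoffs (`GeomThresholds`, all configurable; the defaults follow
the classic interaction-fingerprint lineage — they are declared package
defaults, not literature claims):

| parameter | default | meaning |
|---|---|---|
| `hydrophobic_dmax` | 4.5 Å | apolar atom-pair distance |
| `aromatic_dmax` | 4.5 Å | ring centroid–centroid distance |
| `f2f_angle_max` | 30° | interplanar angle ≤ → face-to-face (closed bound) |
| `e2f_angle_max` | 90° | interplanar angle in (30, 90] → edge-to-face |
| `hbond_dmax` | 3.5 Å | donor–acceptor heavy-atom distance |
| `hbond_angle_min` | 135° | D–H…A angle with explicit hydrogens |
| `pseudo_angle_min` | 120° | D–H…A angle with a pseudo-hydrogen |
| `ionic_dmax` | 5.6 Å | charged-centre distance |

Degenerate cases are fixed by convention: an interplanar angle of exactly
30° is face-to-face; distances compare with `≤`. When a donor lacks
explicit hydrogens (common in PDB receptors), a pseudo-hydrogen is placed
1 Å from the donor, anti to the centroid of its bonded heavy neighbours,
and the D–H…A test is applied at a relaxed 120°. The angle is tested at
the pseudo-hydrogen rather than at the donor–neighbour frame because the
latter rejects ideal sp3 geometry (X–D–A ≈ 109.5° when the real H points
straight at the acceptor). A bare donor with no neighbours falls back to
the distance criterion alone.

Threshold-shrink monotonicity (tightening never sets a new bit) holds for
all distance cutoffs and for raising the angle minima; it deliberately does
*not* hold for `f2f_angle_max`, which is a classification boundary between
types 2 and 3, not a gate.

## ensPLIF

V_k is the fraction of retained poses with bit k set. By default all poses
(Vina `num_modes = 10`, `energy_range = 5`) are retained; a `score_cutoff`
keeps only poses with affinity ≤ cutoff, an optional sharpening step. A
compound whose ensemble is empty (no docking output, or nothing past the
cutoff) is routed to the table's exclusion list with its label, so the
screening metrics can count it — an excluded active is a false negative,
an excluded decoy a true negative.

## Recursive partitioning

`fit_tree` grows a binary tree by greedy Gini splitting over all
(variable, threshold) pairs, thresholds being midpoints of consecutive
distinct sorted values; growth respects `minsplit` (20), `minbucket`
(⌈minsplit/3⌉) and `maxdepth` (30). Pruning is weakest-link at
α = cp · R(root) on the misclassification risk, with `cp = 0.01` by
default; α ≤ 0 prunes nothing, so the cp = 0 tree is the full grown tree
including impurity-improving splits that change no classification, as in
rpart. Ties between equal-quality splits go to the lowest variable index,
then the smallest threshold, so fits are deterministic; the seed enters
only through cross-validation folds and permutation tests. An exhaustive
enumeration reference and scikit-learn (on tie-free continuous data)
reproduce the fitted trees in the test suite.

Class priors default to the **observed frequencies**, as in rpart. Equal
priors (`priors="equal"`) are available but not the default: with a
DUD-E-like 1:50 imbalance, equal priors up-weight each active ~50-fold and
let chance splits that isolate a handful of actives survive pruning — on
y-scrambled tables this retains spurious structure that observed-frequency
pruning removes. Since the y-scrambling diagnostic is part of the method,
the imbalance-robust default is kept; equal priors remain useful when a
sensitive, recall-oriented tree is wanted and chance correlation is checked
separately.

"Best tree" selection: `select_best_cp` picks the cp minimising the
cross-validated error over the tree's own pruning sequence (1-SE rule
optional); the default-cp tree is what `fit_tree` returns. `sanity_check`
reports the cross-validation curve with an overfitting flag (error at the
chosen cp above the minimum by more than one standard error), the |Pearson
r| matrix of the selected descriptors, and the y-scrambling distribution
(default 100 permutations, seeded) with the real tree's percentile.

Scrambled-label collapse is a statistical, not absolute, property: on
20-active/1000-decoy tables with 42 descriptors, roughly one scramble in
twenty contains a chance active-majority pocket whose split legitimately
survives default-cp pruning (R's rpart keeps the identical splits on the
same data). The acceptance checks therefore measure the collapse rate over
20 seeded replicates rather than asserting every draw.

## Determinant extraction and metrics

Determinants are the (variable, direction) pairs on root-to-ligand-leaf
paths: direction "≥ θ" means presence of the interaction favours ligand
calls (favorable), "< θ" the opposite. With frequency-valued descriptors
this direction rule reproduces the published unfavorable assignments. A
variable appearing with both directions on different branches yields two
records — a ligand-dependent determinant. Verification joins on
(receptor, residue number) against a mutation table; the bundled
`gpcrdb_mutations_synthetic.csv` is a synthetic stand-in constructed from
the reference listing's verification column, not an export of any curated
database. Verified percentages round half-up to 2 decimals (13/23 →
56.52).

EF = TPR/FPR with the sentinel `"n.d."` when FPR = 0 (a perfect screen has
an undefined enrichment ratio, not an infinite score that would sort
incomparably); F = 2PR/(P+R), defined as 0 when P + R = 0.

## Synthetic data: what it emulates and what it does not

`make_toy_complex` places idealised residue templates 25 Å apart — beyond
every detection cutoff — and positions chemically minimal ligand fragments
at chosen contact geometries with Gaussian jitter (σ = 0.05 Å per
coordinate by default). Fragment chemistry is picked so exactly one bit can
fire per site: the aromatic probe is an alternating C/N six-ring that
carries no hydrophobic atoms (real ring stacking always drags a
hydrophobic contact along; the probe isolates the aromatic detectors), the
h-bond probes are an ether oxygen and a methylamine, and the ionic probes
sit at centre distances whose O/N atom pairs stay outside the h-bond
cutoff. Planting ranges per type are chosen so the jittered geometry stays
strictly inside its own threshold and outside every other detector's
reach.

`make_synthetic_table` emulates the screening-table statistics rather than
the geometry: 20 actives vs 1000 decoys (the ~1:50 DUD-E ratio),
uninformative bits Beta-concentrated (concentration 30) around a 0.05
background frequency, planted bits around 0.9 in (a subgroup of) the
actives vs 0.05 in decoys, and a weakly separating affinity column
(N(−9, 0.7) vs N(−7.5, 0.7) kcal/mol). Planted bits restricted to active
subgroups emulate ligand-dependent determinants and force multi-branch
trees. These sizes keep the full suite and the acceptance script in the
low tens of seconds.

Passing tests on this material shows that the detectors, the aggregation,
the tree inducer and the extraction rule are each correct and compose
correctly — it does **not** show that the default thresholds are optimal
for real docking poses, that real binding sites (where contacts overlap and
residues crowd) yield single-bit fingerprints, or that real screens reach
the planted effect sizes. Reproducing published per-receptor EF/F values
would additionally require the original compound libraries and stochastic
docking runs, which is outside this package's scope.

## Bundled reference listing

`load_table1_fixture` ships a transcription of a 23-determinant listing
for four GPCR screening campaigns with per-receptor descriptor indices and
EF/F metrics. Where the source material contradicts itself the fixture
stores both variants with a discrepancy flag and a canonical choice (the
tabulated value): the AA2AR ionic determinant (Glu169 canonical vs a
Glu203 textual variant), the CXCR4 F-measure (0.333 vs 0.307), and the
interaction-type frequency claim (a stated two face-to-face occurrences
would sum the type counts to 24 for 23 records; the record-level count of
one is the consistent value).

## Known limitations

- No water-mediated, halogen-bond or cation–π detection; no Tanimoto-based
  similarity screening.
- Protonation/charge assignment is assumed done upstream; formal charges
  are inferred from connectivity (e.g. carboxylates), not read from input.
- Ring perception is geometric (planarity of small cycles), not electronic;
  exotic aromatics may be missed.
- The CART implementation covers the rpart behaviour used here (class
  method, Gini, cp pruning, xval); it does not implement surrogate splits
  or loss matrices.
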