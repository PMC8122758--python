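# plifdet

Identify **molecular determinants of ligand binding** — the residues and
interaction types that drive whether a docked compound is classified as a
ligand — from structure-based virtual-screening (SBVS) output.

The package is aimed at computational medicinal chemists who dock an
actives/decoys library (e.g. a DUD-E benchmark set) against a receptor with
AutoDock Vina and want an *interpretable* model of what separates binders
from non-binders, in the spirit of in-silico site-directed mutagenesis for
targets such as G protein-coupled receptors (GPCRs).

## The method

1. **Docking box & binding site** (`plifdet.structio`). The box is centred
   on the co-crystal ligand with a 5 Å margin beyond its heavy-atom
   envelope; the ordered list of residues with any heavy atom inside the
   box defines the fingerprint layout.
2. **Protein–ligand interaction fingerprints, PLIF** (`plifdet.ifp`). For
   each docked pose, every binding-site residue gets a 7-bit vector over the
   interaction types, in fixed order:

   | code | interaction |
   |---|---|
   | 1 | hydrophobic |
   | 2 | aromatic face-to-face |
   | 3 | aromatic edge-to-face |
   | 4 | h-bond (protein as donor) |
   | 5 | h-bond (protein as acceptor) |
   | 6 | ionic (protein as cation) |
   | 7 | ionic (protein as anion) |

   The `nobb` option drops protein backbone atoms before detection, so only
   side-chain (mutagenesis-like) contacts register. Descriptor index *k*
   (1-based) maps back to residue rank ⌊(k−1)/7⌋+1 and type ((k−1) mod 7)+1.
3. **ensPLIF** (`plifdet.ensplif`). A compound's ensemble PLIF is the
   per-bit frequency across its docking poses: V_k = (poses with bit k) /
   (poses), so V_k ∈ [0, 1]. The analysis table has columns
   `y,name,dg,V1,…,Vn` (y: 1 = active, 0 = decoy; dg: best Vina affinity).
   Compounds with no docking output are excluded and later counted as
   false negatives (actives) or true negatives (decoys).
4. **Recursive partitioning** (`plifdet.cart`). An rpart-style CART:
   greedy Gini splits with minsplit/minbucket/maxdepth control,
   cost-complexity pruning at `cp`, 10-fold cross-validated cp selection,
   and the three model-sanity diagnostics (overfitting via the
   cross-validation curve, descriptor cross-correlation, y-scrambling for
   chance correlation).
5. **Determinants & screening metrics** (`plifdet.determinants`). Every
   split on a root-to-ligand-leaf path yields a (residue, interaction type)
   determinant — *favorable* if the path takes the "≥ threshold" side,
   *unfavorable* otherwise. The implied classifier is scored with the
   enrichment factor EF = TPR/FPR (reported `n.d.` when FPR = 0) and the
   F-measure 2PR/(P+R), and determinants are cross-referenced against a
   site-directed-mutagenesis table.

`plifdet.fixtures` generates toy receptors and pose ensembles with planted
interactions, synthetic ensPLIF screening tables with known informative
bits, and ships a 23-determinant reference listing for four GPCR screening
campaigns (AA2AR, ADRB2, CXCR4, DRD3) with metrics and a synthetic
mutation-verification table.

## Worked example

Generate a toy screen — 6 actives that form a salt bridge to an aspartate
(plus an aromatic contact) and 30 decoys posed outside the site — then run
the pipeline:

```sh
plifdet fixtures --preset saltbridge --seed 7 --out-dir demo   # toy inputs
plifdet ensplif --poses-dir docked --actives actives.txt --decoys decoys.txt \
    --receptor receptor.pdb --residues box.txt -o table.csv
plifdet tree table.csv --minsplit 10 --permutations 50 -o tree.json
plifdet determinants tree.json --residues box.txt --receptor-name TOY
```

The tree step prints:

```
V7 (split at 0.5) [6 active / 30 decoy]
  V7 < 0.5 -> decoy [0 active / 30 decoy]
  V7 >= 0.5 -> ligand [6 active / 0 decoy]
selected variables: ['V7']
training F-measure: 1.000
chance correlation: 0.000 of 50 y-scrambles reach it (percentile 100.0)
overfitting flag: False; cross-correlated descriptors: False
```

and the determinant step:

```
receptor descriptor residue         interaction_type  favorable verification
     TOY  ensPLIF-7    Asp1 ionic (protein as anion)       True         n.a.
```

Read: descriptor V7 is residue rank 1 (the aspartate), type 7 (ionic with
the protein as the anion); compounds whose pose ensembles form that salt
bridge in ≥ 50% of poses are called ligands. The planted aromatic contact
co-occurs with the salt bridge in every active, so the tree needs only one
of the two — determinants are the *sufficient* splits, not every contact.
No y-scramble reaches the real model's F-measure, so the association is not
a chance correlation.

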