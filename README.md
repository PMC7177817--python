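# ppiddg

Fast, structure-based prediction of the change in protein–protein binding
free energy (ΔΔG, kcal/mol) caused by a single amino-acid mutation, plus a
binary variant that classifies mutations as *disruptive* (complex formation
abolished) or *non-disruptive*.

## Who this is for

Most disease-associated missense variants act by perturbing protein–protein
interactions. Physics-based ΔΔG predictors (FoldX, MM/PBSA pipelines) are
accurate but far too slow for genome-scale scans. `ppiddg` takes the
opposite trade: it featurizes only the *wild-type* complex structure with 33
cheap knowledge-based descriptors and lets a gradient-boosted tree ensemble
(XGBoost) learn the mapping to experimental ΔΔG, so a prediction takes
milliseconds. The package covers the full workflow: PDB parsing, dataset
curation from SKEMPI-v2.0-style affinity tables, featurization, training
with a repeated-split/cross-validation protocol, and evaluation.

## The model

For a mutation (chain, residue *i*, wild type *w* → mutant *m*) in a complex
the feature vector **x** ∈ ℝ³³ is

| slots | content |
|---|---|
| 1–3 | crystal temperature (K), crystallization pH, resolution (Å) |
| 4–6 | net volume V(m)−V(w), net hydrophobicity HI(m)−HI(w), net flexibility (rotamer-count change) |
| 7 | mutation-type label (one of the 20·19 = 380 ordered pairs) |
| 8–9 | chemical class of *w* and of *m* (7 classes; the pair spans 49 categories) |
| 10–13 | size (3×3 = 9), polarity (2×2 = 4), H-bond role (4×4 = 16) and hydropathy (3×3 = 9) class-pair labels |
| 14–23 | the 10 sequence neighbours (±5) of site *i*, label-encoded (20 labels per position + gap sentinel) |
| 24–33 | the 10 nearest residues on *other* chains within 10 Å, nearest first |

Label encodings are canonical (alphabetical), so they need no stored fit
state. A gradient-boosted tree regressor maps **x** → ΔΔG (positive =
destabilizing); the same features feed a classifier for the
disruptive/non-disruptive task. Training repeats a random 80/20 (or 90/10)
split, picks hyperparameters by 5-fold CV inside each training portion, and
reports metrics averaged over repeats: PCC/MSE for regression; AUC,
sensitivity, specificity, precision, accuracy and MCC
(= (TP·TN−FP·FN)/√((TP+FP)(TP+FN)(TN+FP)(TN+FN))) for classification.
Feature importances are gain-based and normalized to sum to 1.

Curation of an affinity table follows three stages: keep single point
mutations; merge replicate measurements of one mutation by their mean when
the ΔΔG sample SD is < 1.0 kcal/mol (drop the group otherwise, with
ΔΔG = R·T·(ln K_d,mut − ln K_d,wt)); drop mutations with unobserved residues
within ±5 sequence positions of the site. Adding hypothetical reverse
mutations (ΔΔG negated, a thermodynamic state-function identity) doubles the
dataset and symmetrizes the sign distribution.

Note an inherited property of this protocol family: splits randomize over
mutation records, not complexes, so different mutations of one complex can
land on both sides of a split. Held-out metrics therefore measure
within-distribution accuracy, not transfer to unseen complexes.

## Worked example

Everything below runs offline on generated inputs:

```python
import pathlib
from ppiddg import (featurize, parse_pdb, MutationSpec, train, SplitProtocol,
                    predict_ddg, classify_stability)
from ppiddg.synthetic_fixtures import (FixtureSpec, Contact, make_complex,
                                       make_feature_matrix, make_labeled_dataset,
                                       SyntheticLabelSpec)

# a two-chain complex with chain-B Ser3 planted 3.0 A from A:Gly6
cx = make_complex(FixtureSpec(sequences=["ACDEFGHIKLMN", "QRSTVWYACDEF"],
                              contacts=[Contact("B", 3, "A", 6, 3.0)], seed=0))
pathlib.Path("complex.pdb").write_text(cx.pdb_text)
struct = parse_pdb("complex.pdb")
fv = featurize(struct, MutationSpec("A", 6, "G", "W"))

# train on synthetic data whose targets are linear in four numeric features
X = make_feature_matrix(1000, seed=1)
y, _ = make_labeled_dataset(X, SyntheticLabelSpec(
    weights={"net_volume": 1.5, "net_hydrophobicity": 1.0,
             "crystal_temperature": 0.8, "resolution": 0.5}, noise_sd=0.2), seed=2)
bundle, report, _ = train(X, y, "regression",
                          SplitProtocol(test_fraction=0.2, n_repeats=3, base_seed=0),
                          param_grid={"learning_rate": [0.1], "max_depth": [4, 6],
                                      "n_estimators": [200]})
ddg = predict_ddg(bundle, fv.values)
```

Output (exact numbers; everything is seeded):

```
n features: 33
crystal_temperature = 298.0      # read from REMARK 200
net_volume = 167.7               # V(W) - V(G), A^3: the largest possible increase
net_hydrophobicity = -3.24       # G -> W, Moon-Fleming scale
mutation_type = 112.0            # canonical label of the ordered pair (G, W)
neighbor_01 = 15.0               # label of Ser: B:3 is the planted 3.0-A contact
held-out PCC: 0.991  MSE: 0.102
top importances: [('net_volume', 0.53), ('net_hydrophobicity', 0.225),
                  ('crystal_temperature', 0.134)]
predicted ddG: 1.833 destabilizing
```

The held-out PCC ≈ 0.99 against the known generative model (noise SD 0.2)
shows the protocol recovers a planted signal; the importance ranking mirrors
the planted weights.

The same workflow is available from the shell:

```bash
ppiddg featurize --pdb complex.pdb --chain A --resnum 6 --wt G --mut W
ppiddg curate --skempi affinities.csv --pdb-dir pdbs/ --out curated.tsv
ppiddg train --dataset curated.tsv --pdb-dir pdbs/ --task ddg --seed 1 --out model.json
ppiddg predict --model model.json --pdb complex.pdb --mutations List_Mutations.txt
```

## Training on real data

The shipped tests and examples use synthetic inputs only. To train on real
data, download the SKEMPI v2.0 CSV and the PDB structures it references,
then run `ppiddg curate` followed by `ppiddg train` as above — the curation
stages apply unchanged. This workflow needs network access and is not part
of the test suite.

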