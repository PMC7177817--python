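# Methods

## Scope and model

`ppiddg` predicts the binding free energy change ΔΔG (kcal/mol) of a single
point mutation in a protein–protein complex from the wild-type structure
alone. No mutant structure is modelled and no energy, conservation or
evolutionary features enter: the encoding is purely knowledge-based. A
gradient-boosted decision-tree ensemble (XGBoost, `hist` tree method,
single-threaded for reproducibility) is trained on curated experimental
data; the identical 33 features feed a second, binary model that separates
disruptive from non-disruptive mutations (the kind of label produced by
yeast two-hybrid screens).

Sign convention throughout: ΔΔG = ΔG_mut − ΔG_wt with ΔG = R·T·ln K_d, so
positive ΔΔG means weakened binding (destabilizing). R = 0.0019872
kcal/(mol·K); T is taken from the affinity record when present, else 298 K.

## Feature construction

**Metadata (3).** Resolution, data-collection temperature and
crystallization pH are read from PDB REMARK 2 / 200 / 280 records. A file
without them still predicts: values fall back to 2.5 Å / 298 K / pH 7.0 and
the feature vector carries an `*_imputed` provenance flag. The
data-collection temperature (REMARK 200) was chosen over the crystal-growth
temperature because it is the one that governs atomic mobility in the
deposited coordinates.

**Descriptor deltas (3).** Net volume, net hydrophobicity and net
flexibility are mutant-minus-wild-type differences over shipped constant
tables: Zamyatnin residue volumes (Å³), the Moon–Fleming side-chain
hydrophobicity scale (kcal/mol), and favoured rotamer counts from the
penultimate rotamer library (G/A = 1 by convention, having no χ angles).
Rotamer counts are a convention-dependent quantity, so the table — like the
other two — can be overridden from a flat text file without code changes,
and no test depends on the specific counts.

**Categorical labels (7).** The mutation type (380 ordered amino-acid
pairs), the chemical class of wild-type and of mutant residue (aliphatic /
aromatic / sulfur / hydroxyl / basic / acidic / amide — the ordered pair
spans 49 categories), and the ordered class pairs under the size (3),
polarity (2), hydrogen-bond role (4) and hydropathy (3) partitions. All
label encodings are **canonical**: categories are ordered alphabetically
(amino acids by one-letter code, class names lexicographically), so a label
integer is a pure function of the category, reproducible with no stored
encoder state. An insertion-order encoding ("first seen is 1, second is 2")
would tie the model file to the row order of its training set.

**Sequence window (10).** The five residues either side of the site along
the mutated chain, label-encoded over the shared 20-letter alphabet.
Positions past a terminus or at an interior numbering gap take a GAP
sentinel, which is the first reserved label above the 20 residue labels
(20), keeping residue labels dense.

**Cross-chain neighbours (10).** The ten nearest residues on *other* chains
within 10 Å of the site, nearest first, padded with the same sentinel when
fewer exist. Residue–residue distance is the **minimum heavy-atom
distance** — robust to missing Cβ and consistent with the contact intuition
behind the 10 Å cutoff; distance ties break by (chain id, residue number)
for determinism.

The arithmetic 3 + 3 + 1 + 2 + 4 + 10 + 10 = 33 is a committed
interpretation of the feature inventory (reading "chemical property of wild
type and of mutant" as two separate features whose product spans the 49
pair categories). It is isolated behind `featurizer.feature_schema()`, so an
alternative accounting is a one-table change.

## Structure handling

PDB files are read with gemmi. Waters and ligands are dropped; modified
residues with a standard parent (MSE → M, etc.) are mapped via gemmi's
chemical-component table, anything unmappable is excluded from
featurization. Alternate conformations reduce to the highest-occupancy
atom. A usable complex needs ≥ 2 chains with ≥ 1 standard residue each.

Chain termini are **not** missing residues: only interior numbering gaps,
or residue numbers declared unobserved in REMARK 465 (including beyond the
modelled termini), trigger the local-gap filter. A mutation two residues
from a genuine N-terminus is structure-resolved and legitimate.

The interface annotation used in evaluation strata (not as a model feature)
calls a residue interfacial when any heavy atom lies within 5.0 Å of
another chain — a common convention adopted because the quantity needs a
definition and none is canonical.

## Curation pipeline

Stage order, each stage logged with survivor counts:

1. **Single mutations only.** Multi-mutation records are out of scope.
2. **Replicate merging.** Records grouped by (complex, chain, position,
   insertion code, wt, mut); per-group ΔΔG sample SD (ddof = 1) < 1.0
   kcal/mol keeps the group mean, otherwise the whole group is dropped. The
   SD filter applies to ΔΔG (not raw affinities), the literal reading of
   "deviation of changes in binding affinity". Exact-zero ΔΔG records are
   retained for regression.
3. **Local-gap filter.** Mutations whose ±5 sequence window contains
   unobserved residues are dropped; unresolvable structures drop the record
   with a logged reason rather than aborting the run.

Reverse augmentation appends, for every record, the mutant→wild-type
substitution with negated ΔΔG; it is refused on an already-augmented set.
The augmented distribution is symmetric about 0 by construction, which
flatters correlation metrics — the regressor of record is trained on the
unaugmented set.

## Training protocol

For repeat r = 0 … n−1 with seed = base_seed + r: random train/test split
(test fraction 0.2 or 0.1, stratified for classification); hyperparameters
selected on the training portion by 5-fold CV over a grid (default:
learning rate {0.05, 0.1, 0.3} × depth {4, 6, 8} × rounds {200, 500};
subsample and column subsample fixed at 0.8); refit on the full training
portion; metrics on the test portion. The reported report averages metrics
over repeats (the pooled-prediction PCC is also recorded in `extras` —
averaged-over-repeats is the default because that is the convention for
this protocol family). The returned bundle is refit on **all** data with
the modal hyperparameters across repeats; its gain-based importances are
renormalized in float64 so they sum to 1 within 1e−9. CV ties prefer the
earlier grid point; a single-point grid skips the search. Early stopping is
deliberately not used inside CV: fixed round counts keep every fold's model
a deterministic function of (data, seed, grid point).

The DN classifier uses the same protocol with accuracy as the CV criterion
and calls a mutation disruptive when the predicted probability is ≥ 0.5.
Stability categories use strict inequalities — destabilizing (ΔΔG > 0) /
stabilizing (< 0) / neutral (= 0), and highly destabilizing (> 1.5) /
highly stabilizing (< −1.5) / intermediate — so boundary values fall in the
weaker class.

## Evaluation conventions

MCC with any zero denominator factor is defined as 0 (warned). Rates with a
zero denominator report `None`, never 0. PCC is undefined (`None`) for
constant inputs. AUC is trapezoidal over all thresholds and equals the
Mann–Whitney pair probability with half-credit ties. In the
classification view of regression output, sign-mode excludes exact-zero
observed ΔΔG (they carry no sign label) and strong-mode restricts to
|ΔΔG| > 1.5 before the ROC; the predicted ΔΔG is the score and its sign the
hard call. Strata smaller than 10 records are flagged `too-small` instead
of reporting an unstable PCC. Secondary-structure and complex-type strata
are consumed from external annotation files only; the package does not
assign secondary structure.

## Synthetic data: what it emulates and what it does not

The fixture generator produces multi-chain PDB files with idealized
geometry: extended backbones (3.8 Å Cα spacing), one side-chain
pseudo-atom per residue, chains 60 Å apart unless a contact is requested,
requested inter-chain minimum distances realized to 0.01 Å, REMARK
2/200/280/465 metadata embedded exactly as specified. Companion
ground-truth tables (all-pairs minimum distances, expected curation
outcomes) are computed with independent arithmetic inside the generator, so
they can serve as oracles for the geometry and curation code without
circularity.

The affinity-table generator plants replicate groups whose ΔΔG sample SDs
straddle the 1.0 kcal/mol cutoff (two measurements ddg and ddg + s·√2 have
sample SD exactly s) and mutations adjacent to interior gaps, with the
expected survivor set stated row by row.

Labeled datasets for model testing draw the 33 features independently and
uniformly over plausible ranges and impose either a linear target (weights
per standardized feature + Gaussian noise, default noise SD 0.2 kcal/mol,
comparable to experimental replicate error) or a planted threshold rule for
the binary task. What passing the recovery tests shows: the protocol can
recover a known signal of realistic strength at n = 2000 and ranks the
planted feature first by importance. What it does not show: performance on
real mutations, where features are correlated, targets are not additive,
and label noise is structured. Real-data accuracy must be established by
the download-gated SKEMPI workflow in the README.

## Problem sizes

Recovery experiments run at n = 2000 rows with 10 repeats and a compact CV
grid (learning rate 0.1, depth {4, 6}, 200 rounds); the permutation-null
and classifier checks use 5 repeats and a single grid point. The acceptance
script trains at n = 1000 with 3 repeats. These sizes were chosen as the
smallest at which the sampling error of the checked quantities is well
inside the asserted margins.

## Known limitations

* Record-level (not complex-level) splitting inflates held-out metrics
  relative to a leave-complex-out protocol; this matches the protocol the
  method family reports, and is documented rather than changed.
* The wild-type-only featurization cannot see mutant side-chain packing;
  large rearrangements are invisible to it.
* Descriptor tables are global constants; context-dependent hydrophobicity
  or rotamer preferences are not modelled.
* mmCIF input is not supported; the REMARK metadata parser covers the
  wwPDB v3.3 layout only.
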