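# bbbqsar

A fragment-based QSAR toolkit for predicting blood-brain-barrier (BBB)
permeability of small molecules from their 2D structure, aimed at
computational toxicologists and medicinal chemists who need an inspectable,
non-proprietary pipeline from raw rodent exposure data to validated binary
classifiers.

## What it does

**Endpoint.** The modelled quantity is log BB = log10(C_brain / C_blood), the
steady-state brain-to-blood (or plasma, or AUC-ratio) concentration ratio in
rodents. Compounds with log BB >= -1 are scored *permeable* (1), below -1
*non-permeable* (0); multi-region brain measurements are averaged before the
ratio, and replicate studies are reconciled (strict agreement by default,
conflicts excluded).

**Features.** Training molecules are fingerprinted with explicit, readable
structural fragments: linear heavy-atom paths (2-7 atoms, with aromatic and
ring-membership atom typing), fused ring systems, and Murcko scaffolds
(emitted under frequency >= 3, size >= 6 atoms, |Z| >= 1 constraints). Each
fragment's activity enrichment is a Z-score,

    z_raw = p_feature - p_all
    z_std = z_raw / sqrt(p_all (1 - p_all) / frequency)

where `p_feature` is the positive rate among carriers and `p_all` the
training base rate. Redundant (phi >= 0.95) and weak features are pruned.

**Two classifier styles.**

* *LS-style*: retained fragments + eight z-scaled physicochemical
  descriptors (MW, rotatable bonds, HBD, HBA, Lipinski violations, AlogP,
  TPSA, heavy atoms) -> PLS regression -> logistic calibration to a
  probability. Equivocal band 0.4-0.6; out-of-domain if no model feature
  matches or max Tanimoto similarity to any training compound (on the
  model's own fingerprints) is below 0.30.
* *CU-style*: structural alerts (z_std >= 2) and deactivating features
  (fragments lowering the positive rate among alert carriers) in one global
  logistic regression with signed weights; classification threshold chosen
  on the ROC curve to balance sensitivity and specificity, equivocal within
  +/-0.1 of it; out-of-domain if the molecule contains a three-atom fragment
  never seen in training and no positive-strength score.

**Validation and consensus.** Repeated stratified leave-many-out
cross-validation (10 x 10% folds, weights refit per fold, per-compound
probabilities averaged over repeats), Cooper statistics (sensitivity,
specificity, positive/negative predictivity, accuracy), MCC, Pearson
chi-squared and coverage, and a sensitivity-favouring two-model consensus
(any positive wins; a lone out-of-domain verdict is disregarded).

A seeded synthetic-data generator with planted fragment effects (fused
bicyclic aromatics and cyclic amines positive; carboxylic acids and
sulfonamides negative) plus a lipophilicity covariate provides ground truth
for testing every stage without any external data.

## Worked example

```python
import numpy as np
from rdkit import Chem
from bbbqsar import synthdata
from bbbqsar.qsar_model import fit_cu_style, predict

records = synthdata.generate_dataset(synthdata.SynthConfig(n_compounds=300, seed=7))
mols = [Chem.MolFromSmiles(r.structure) for r in records]
labels = [r.label for r in records]

model = fit_cu_style(mols, labels)
print(f"alerts: {len(model.alert_ids)}  deactivators: {len(model.deactivator_ids)}  "
      f"threshold: {model.threshold:.3f}")
for smiles in ["Cc1ccc2ccccc2c1", "OC(=O)c1ccc(S(N)(=O)=O)cc1", "CCP"]:
    call = predict(model, Chem.MolFromSmiles(smiles))
    p = "-" if call.probability is None else f"{call.probability:.3f}"
    print(f"{smiles:30s} {call.value.value:14s} p={p}")
```

prints

```
alerts: 15  deactivators: 87  threshold: 0.513
Cc1ccc2ccccc2c1                positive       p=0.892
OC(=O)c1ccc(S(N)(=O)=O)cc1     negative       p=0.012
CCP                            out_of_domain  p=-
```

2-methylnaphthalene carries the fused-aromatic alert and is called permeable
with high confidence; the sulfamoyl-benzoic acid carries two deactivating
groups and is called non-permeable; ethylphosphine contains three-atom
fragments never seen in training and is refused as out of domain rather than
guessed at.

The same workflow is available from the shell:

```bash
bbbqsar synth --n 800 --seed 7 --out train.sdf --truth-out truth.json
bbbqsar fit --style cu --in train.sdf --out model.json
bbbqsar predict --model model.json --in train.sdf --out predictions.csv
bbbqsar crossval --style ls --in train.sdf --repeats 10 --fold 0.1 --out cv.csv
```

## Layout

```
src/bbbqsar/
  chem_io.py               SDF/SMILES reading, salt neutralisation, curation rules
  activity_scoring.py      log BB computation, binarisation, replicate resolution
  features.py              fragment/scaffold enumeration, Z-scores, pruning, FG profiling
  descriptors.py           physicochemical descriptors, descriptor~log BB R^2
  qsar_model.py            LS-style and CU-style fitting, domains, prediction, JSON I/O
  validation_consensus.py  LMO cross-validation, Cooper statistics, ROC, consensus
  synthdata.py             seeded generator with planted ground truth
  cli_app.py               click command-line interface
docs/methods.md            model and generator documentation
```
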