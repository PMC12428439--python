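# pepscreen

Drug-likeness screening for peptide molecules: deterministic violation
counters for three structural filters, and Random Forest surrogate models
trained to predict those violation counts from molecular descriptors or
Morgan fingerprints.

## The problem

Peptide therapeutics routinely fall outside Lipinski's Rule of Five (Ro5),
the classical oral-bioavailability heuristic for small molecules. Adapted
filters — the beyond-Rule-of-Five (bRo5) bounds for peptide space and the
Muegge pharmacophore-point criteria — extend the idea, but every platform
computes descriptors slightly differently, and early-stage screening
pipelines increasingly want a learned model that tolerates such variance
rather than a brittle threshold script. `pepscreen` provides both halves:

* **Rule counters.** Each filter is a list of interval criteria over a
  nine-descriptor profile (Mw, logP, HBD, HBA, TPSA, rotatable bonds,
  carbon/heteroatom/ring counts). The violation count of a molecule is the
  number of failed criteria:

  | rule | criteria |
  |---|---|
  | `ro5` | Mw ≤ 500 Da, logP ∈ [0, 5], HBD ≤ 5, HBA ≤ 10 |
  | `bro5` | Mw ≤ 1000 Da, logP ∈ [−2, 10], HBD ≤ 6, HBA ≤ 15, TPSA ≤ 250 Å², NRotB ≤ 20 |
  | `muegge` (core-6) | Mw ∈ [200, 600], logP ∈ [−2, 5], TPSA ≤ 150, NRotB ≤ 15, HBA ≤ 10, HBD ≤ 5 |

  HBD counts N–H plus O–H hydrogens and HBA counts N plus O atoms (the
  Lipinski convention); logP is Wildman–Crippen, TPSA is Ertl, rotatable
  bonds use the strict definition. Bounds are inclusive for compliance.
  A `full` Muegge variant adds rings ≤ 7, carbons > 4, heteroatoms > 1.

* **Surrogate models.** scikit-learn-style estimators
  (`ViolationCountClassifier`, `ViolationCountRegressor`) wrap Random
  Forests with default hyperparameters at ensemble sizes 10/20/30 and learn
  the counters from labelled descriptor (or fingerprint) tables. Because
  the label is a deterministic function of the descriptors, a sufficiently
  trained surrogate should recover the counter almost exactly — and the
  held-out metrics verify that it does.

No external dataset is required: a stratified descriptor-space sampler and
a residue-fragment peptide SMILES assembler generate all training and test
material. A comparison module scores predictions against reference counts
(e.g. SwissADME/Molinspiration exports) with exact-match, off-by-one, and
missing-reference accounting.

## Worked example

Count violations for two peptides (a glycine dimer and a Phe-Leu-Ser
tripeptide) from a `.smi` file:

```sh
$ pepscreen count --rule ro5 demo.smi
id,rule,variant,violations
diglycine,ro5,lower-on,1
FLS,ro5,lower-on,2

$ pepscreen count --rule bro5 demo.smi
id,rule,variant,violations
diglycine,bro5,standard,0
FLS,bro5,standard,0
```

Diglycine breaks Ro5 once (its Crippen logP of −1.85 sits below the lower
logP bound, which is on by default; `--ro5-logp-lower off` reproduces the
web-platform convention where only logP > 5 counts); both peptides sit
comfortably inside the wider bRo5 envelope.

Train and evaluate a surrogate on synthetic descriptor rows:

```sh
$ pepscreen simulate --n 20000 --seed 7 --stratify-rule ro5 --out ds.csv
$ pepscreen train --dataset ds.csv --rule ro5 --n-trees 20 --out ro5.joblib
$ pepscreen evaluate --model ro5.joblib --dataset ds.csv
{
  "metrics": {
    "accuracy": 0.9995,
    "auc_micro": 0.9999999296875,
    "averaging": "micro",
    ...
  }
}
```

The 20-tree classifier recovers the Ro5 counter on 99.95 % of held-out rows
even at this reduced scale; micro accuracy, precision, recall and F1
coincide because the metrics pool one-vs-rest decisions (micro averaging).
The Python API mirrors the CLI — `builtin_ruleset`, `count_violations`,
`sample_descriptor_vectors`, `train_model`, `compare_predictions` — and the
estimators compose with sklearn pipelines and model selection.

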