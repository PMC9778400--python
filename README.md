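# flavoscreen

Fingerprint-similarity clustering, GA-selected MLR-QSAR modelling and a
ligand-based virtual-screening funnel for discovering small-molecule enzyme
inhibitors, built around an embedded reference set of 27 dietary flavonoids
with measured α-glucosidase pIC50 values.

## What it does

- **compound_io** — SMILES/CSV/SDF molecule tables, canonicalization,
  IC50 ⇄ pIC50 conversion, and the embedded fixtures (27-flavonoid
  reference set with both published model predictions, the five screened
  candidates).
- **fingerprints_clustering** — hashed path fingerprints and Morgan/ECFP4
  circular fingerprints, Tanimoto similarity matrices, deterministic
  single-linkage clustering with documented tie-breaking.
- **descriptors_2d** — a native engine for the five descriptors of the
  published 2D equation (Moreau–Broto autocorrelations ATS4v/AATS7m,
  neighborhood-symmetry information content MIC1/CIC3, Kier–Hall E-state
  minssCH2), plus ingestion/cleaning/correlation-filtering of externally
  computed descriptor tables.
- **qsar_model** — OLS fitting, the two published regression equations,
  brute-force leave-one-out CV, the nine-metric validation report
  (Q²_LOO, R², adjusted R², RSS, PRESS, SDEC, SDEP, MSE, MAE), and a
  seeded genetic algorithm for fixed-size descriptor-subset selection.
- **screening** — similarity enrichment against seeds, canonical-SMILES
  deduplication, QED/MW drug-likeness and element filters, activity
  prediction and candidate ranking.
- **energy_audit** — MMGBSA component-table parsing ("value ± uncertainty"
  cells) and arithmetic auditing of printed decomposition tables.
- **synthetic_data** — seeded generators for known-truth linear datasets
  and flavonoid-like screening libraries with planted seed variants, so
  every experiment runs offline.

Note on descriptor scales: the native descriptor engine uses raw atomic
mass / Bondi-volume weights and is oracle-tested for self-consistency; it
does not reproduce the original third-party descriptor software
bit-for-bit, so predictions of the *published* equations are only
meaningful on externally computed descriptor tables (the ingestion path).
Models fitted with `flavoscreen fit` on native descriptors are fully
self-consistent.

## CLI

```sh
flavoscreen cluster --fingerprint path --nclusters 6 --in reference --out clusters.csv
flavoscreen descriptors --in reference --out desc.csv
flavoscreen fit --desc desc.csv --activity reference --k 5 --seed 1
flavoscreen validate --model model.json --desc desc.csv --activity reference --split-seed 1
flavoscreen predict --model 2d-published --desc padel.csv
flavoscreen screen --library lib.smi --seeds reference --model 2d-published --sim 0.8 --qed 0.5 --mw 650
flavoscreen energy-audit --in mmgbsa.csv --tol 0.015
flavoscreen synth linear --n 60 --p 40 --k 5 --noise 0.1 --seed 1 --out synth/
flavoscreen synth library --n 500 --seeds reference --seed 1 --out lib.smi
```

`--in reference` (and `--seeds reference`) use the embedded 27-compound
fixture anywhere a compound table is expected.

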