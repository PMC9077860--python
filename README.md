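# etaqsar

A 2D-QSAR pipeline for small-molecule activity modeling built on
**Extended Topochemical Atom (ETA) descriptors**, genetic-algorithm
descriptor selection under **double cross-validation**, and **NIPALS
PLS** regression with a full validation and applicability-domain suite.

It is written for the typical small-dataset QSAR setting — on the order
of 40–80 compounds with a measured activity such as a larvicidal pLC50
(= −log10 LC50) — where descriptor-selection bias and chance
correlation are the dominant risks, and every modeling choice must be
seeded and reproducible.

## What it computes

**ETA descriptors** are topological indices built from three atomic
quantities on the hydrogen-suppressed molecular graph: a core count
α = [(Z−Zv)/Zv]/(PN−1), an electronegativity measure ε = −α + 0.3 Zv,
and a valence-electron-mobile count β that books sigma (0.5 similar /
0.75 dissimilar electronegativity), pi (1.0/1.5), aromatic (2.0) and
conjugated-lone-pair (0.5) contributions. Composite indices compare the
molecule against its *reference alkane* (heteroatoms → C, all bonds
single) and its *saturated carbon skeleton* (only C–C multiple bonds
made single), giving among others:

| descriptor | meaning |
|---|---|
| `ETA_dEpsilon_C` = ε₃ − ε₄ | electronegative-atom content (≤ 0) |
| `ETA_dEpsilon_D` = ε₅ − ε₂ | hydrogen-bond-donor content (≥ 0) |
| `ETA_dAlpha_B` | polar-surface measure (0 for hydrocarbons) |
| `ETA_BetaP_s` = Σβ_s/Nv | sigma VEM content per vertex |
| `ETA_EtaP_F` = (η_R − η)/Nv | functionality (heteroatoms + unsaturation) relative to size |

The modeling chain is: descriptor pretreatment (missing / SD < 1e-4 /
|r| ≥ 0.95 removal) → k-medoids clustering with an activity-ranked 66/34
train–test division → GA subset search scored by repeated stratified
10-fold cross-validation inside the training set (the test set never
enters selection) → PLS1 fit (default 3 latent variables) → validation
(R², Q²LOO, Q²F1/F2, SEE, F, RMSE), Y-randomization (100 permutations,
R²/Q² intercept thresholds 0.3 / 0.05), Hotelling T² and DModX
applicability domain.

## Worked example

Generate a synthetic 60-compound set (terpene/phenylpropanoid-like
chemistry, activity linear in three ETA descriptors at 9:1
signal:noise), compute descriptors, divide, and validate a 3-LV PLS
model on the known subset:

```sh
etaqsar simulate --n 60 --seed 7
etaqsar descriptors synthetic.smi --out desc.csv
etaqsar split desc.csv synthetic_activity.csv --k 5 --seed 7 --out split.json
etaqsar validate desc.csv synthetic_activity.csv split.json \
    -d ETA_dEpsilon_D -d ETA_EtaP_F -d ETA_BetaP_s --n-lv 3 --out val.json
```

which prints

```
train=39 test=21 -> split.json
| metric | value |
|---|---|
| R2 (train) | 0.9313 |
| Q2 (LOO) | 0.9168 |
| SEE | 0.4268 |
| F(3, 35) | 158.16 |
| RMSE (train) | 0.4043 |
| Q2_F1 | 0.8966 |
| Q2_F2 | 0.8943 |
| RMSE (test) | 0.4545 |
```

R² ≈ 0.93 is the expected fit at a 9:1 signal-to-noise ratio; the
close agreement between the leave-one-out Q² and the external Q²F1/F2
says the model generalizes rather than memorizes, and SEE/RMSE are on
the pLC50 scale. The full selection pipeline (GA under double
cross-validation, applicability domain, Y-randomization) runs from a
YAML config with `etaqsar run-all config.yaml`, writing every
intermediate artifact plus a reproducibility manifest; the same
functionality is available as a library (`etaqsar.run_all`,
`etaqsar.fit_published_model`, ...).

## Layout

```
src/etaqsar/
  chemio.py      SMILES/SDF <-> molecular graphs, activity I/O
  eta.py         atomic ETA quantities and the composite descriptor block
  preprocess.py  pretreatment, k-medoids, activity-ranked division
  select.py      GA-MLR subset search under double cross-validation
  pls.py         NIPALS PLS1, VIP, Hotelling T2, DModX
  metrics.py     R2/Q2 family, SEE, F, Y-randomization
  synth.py       synthetic molecule/activity generator, named fixtures
  pipeline.py    end-to-end orchestration with manifest
  cli.py         `etaqsar` command-line interface
docs/methods.md  model, conventions, parameter defaults, limitations
```
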