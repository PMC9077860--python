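# Methods

## Scope

`etaqsar` implements a complete 2D-QSAR workflow for small organic
molecules: Extended Topochemical Atom (ETA) descriptor computation from
molecular graphs, descriptor-matrix pretreatment, k-medoids-based
train/test division, genetic-algorithm (GA) descriptor selection under
double cross-validation (DCV), NIPALS PLS1 regression, and a validation
and applicability-domain suite (R², Q²LOO, Q²F1/F2, SEE, F,
Y-randomization, Hotelling T², DModX). A synthetic-data generator
provides molecule sets and activities with the statistical structure the
analysis assumes, so every stage is testable without external data.

## ETA descriptors

All descriptors are computed on the hydrogen-suppressed, Kekulized
molecular graph; they are purely topological (stereo-blind, no 3D
geometry). Atomic quantities:

- core count `alpha = [(Z - Zv)/Zv] / (PN - 1)` (Z atomic number, Zv
  valence electrons of the neutral element, PN period); `alpha(H) = 0`.
- electronegativity measure `epsilon = -alpha + 0.3 Zv` (H 0.3, C 0.7,
  N 1.1, O 1.4667, Cl 1.7857).
- VEM (valence-electron-mobile) count `beta`, summed per atom over
  incident heavy-atom bonds: sigma part 0.5 when the bonded atoms'
  epsilons differ by at most 0.3 ("similar"), 0.75 otherwise; pi part
  1.0/1.5 per extra bond order by the same similarity rule; 2.0 per
  aromatic ring bond; plus 0.5 once for a lone-pair atom conjugated to a
  pi system (aromatic neighbor, or a neighbor carrying a multiple bond
  to a third atom — a carbonyl oxygen therefore gets the pi term, not
  the lone-pair term). Every bond, aromatic included, contributes its
  sigma part to `beta_s`; a benzene carbon thus has `beta_s = 1.0`,
  `beta_ns = 4.0`. All constants sit in one table at the top of
  `eta.py`.

Two auxiliary graphs anchor the composite indices: the **reference
alkane** (heteroatoms -> carbon, all bonds single, hydrogens re-filled
to valence 4) and the **saturated carbon skeleton** (heteroatoms kept,
only C–C multiple bonds made single; a C=O survives). Mean-epsilon
variants: eps1 (heavy atoms), eps2 (all atoms), eps3 (reference alkane
incl. H), eps4 (saturated skeleton incl. H), eps5 (molecule with
hydrogens on N/O/S deleted). Derived measures and their guaranteed
signs:

- `ETA_dEpsilon_C = eps3 - eps4 <= 0`, 0 iff no heteroatoms
  (electronegative-atom content);
- `ETA_dEpsilon_D = eps5 - eps2 >= 0`, > 0 iff H-bond-donor hydrogens
  exist;
- `ETA_dAlpha_B = max(0, 0.5 - mean alpha) >= 0`, 0 for pure
  hydrocarbons (polar-surface measure; 0.5 is the per-vertex alpha of
  any alkane carbon);
- `ETA_BetaP_s = sum(beta_s)/Nv` (sigma VEM content per vertex; the
  per-atom sum counts each bond at both endpoints);
- `ETA_EtaP_F = (eta_R - eta)/Nv` with
  `eta = sum_{i<j} sqrt(gamma_i gamma_j)/d_ij`, `gamma = alpha/beta`,
  d the topological distance, and `eta_R` the same index on the
  reference alkane (functionality relative to size). Single-heavy-atom
  molecules get `eta = F = 0`.

These five are the model descriptors and are covered by hand-derived
tests. The remaining members of the block (shape fractions, psi, local
eta, the other delta terms) are computed with the same machinery but
flagged unvalidated in output metadata: no external tabulation was
available to confirm their exact conventions.

## Pretreatment and division

Pretreatment removes, in order: all-missing columns, any-missing
columns, columns with SD < 1e-4, and one member of each pair with
|Pearson r| >= 0.95 (the lower-variance member; ties keep the earlier
column — the keep rule is a package choice). The operation is
idempotent.

Division uses a PAM-style k-medoids (default k = 5 for ~60 compounds)
on autoscaled descriptors with Euclidean distance: seeded farthest-point
initialization, then alternation of nearest-medoid assignment and
cost-minimizing medoid update until stable (<= 300 iterations; an
emptied cluster is re-seeded from the globally farthest point). The
alternation is the "simple and fast" variant: it does not perform PAM
swap moves and can stop in a local optimum on unstructured data; on
separated clusters it reaches the exhaustive-search optimum (tested).
Within each cluster, members are sorted by activity and every third
member (ranks 2, 5, 8, ...) is assigned to the test set up to the
per-cluster quota round(0.34 x size), topping up in rank order if the
stride runs out; ties in activity fall back to input order. For 61
compounds this yields a 41/20 split up to +-1.

## Selection: GA under double cross-validation

The outer DCV loop is the train/test division above; the test set never
enters selection. Fitness of a descriptor subset is the pooled
validation error of per-fold OLS fits under stratified 10-fold
cross-validation of the training set (folds stratified by response
quantile), averaged over 10 reshuffled fold assignments; the default
error is MAE (RMSE available). Degenerate subsets (empty, larger than a
calibration fold, rank-deficient) score +inf.

The GA uses tournament selection (size 2), one-point crossover
(p = 0.9), per-bit mutation (p = 0.01), elitism of 1, population 50,
100 generations, subsets capped at 5 descriptors (the final model
size). Hyperparameters are config-exposed; fitness evaluations are
memoized per subset, and the search is bit-identical under a fixed
seed. Top candidates are re-fitted on the full training set and
reported with external metrics (Q²F1/F2, RMSE) on the untouched test
set, ties broken by subset size then column order. An exhaustive-search
mode provides the oracle for small pools and the plain-MLR baseline.

## PLS modeling and diagnostics

NIPALS PLS1 on autoscaled X (unit variance; config-exposed) and
centered y, with X deflation per component and the q-positive sign
convention (each component flipped so its y-loading is non-negative),
making all reported weights, scores and coefficients reproducible
across runs and platforms. The attainable component count is the rank
of centered X; requesting more raises. Degenerate y (zero variance)
returns the mean model. Original-scale coefficients come from
`b = W (P'W)^-1 q` mapped through the scaling; at full rank PLS
predictions equal OLS (tested to 1e-8), and the implementation is
cross-checked against an independent PLS implementation in the test
suite.

- **VIP**: `VIP_j = sqrt(p sum_a SSY_a (w_ja/||w_a||)^2 / sum_a SSY_a)`
  with `SSY_a = q_a^2 t_a't_a`; satisfies `sum VIP² = p` to 1e-10.
- **Hotelling T²**: `T²_i = sum_a t_ia²/var(t_a)`, limit
  `a(n-1)/(n-a) F(a, n-a)` at the chosen confidence (default 95% for
  the score-plot ellipse).
- **DModX** (normalized): per-row residual SD after projection,
  `s_i = sqrt(sum_j e_ij²/(p-a))`, over the pooled training residual
  `s_0` with `(n-a-1)(p-a)` degrees of freedom; critical value
  `sqrt(F)` at the stated confidence (default 99%). This is the
  normalized variant with those df corrections; other software's
  internally rescaled critical values are not reproduced bit-for-bit,
  and no correction factor is applied for new observations. A perfect
  projection (zero pooled residual) makes DModX undefined and raises.

## Validation metrics

R² = 1 - RSS/TSS; SEE uses n - a - 1 degrees of freedom with a = the
number of latent variables (the effective regression variables; a =
number of descriptors is config-exposed); F = (R²/a)/((1-R²)/(n-a-1)).
Q²LOO refits the full PLS (including re-centering/scaling) on each
leave-one-out fold; a fold losing rank falls back to its training mean.
Q²F1 and Q²F2 scale the test-set prediction error by deviations from
the training and test response means respectively. Y-randomization
(default 100 permutations) refits the model on each permuted response,
records R² and LOO-Q² against c = |corr(y_perm, y)|, and extrapolates
straight lines (including the unpermuted model at c = 1; exclusion is a
config flag) to c = 0; the model passes when the R² intercept is below
0.3 and the Q² intercept below 0.05. Per-permutation Q² uses LOO.

## Synthetic data

The generator emulates a plant-derived larvicide set: cyclohexane /
benzene / decalin cores (weights 0.4/0.4/0.2) with 0–3 substituents
drawn from methyl, isopropyl, vinyl, allyl, hydroxy, methoxy, chloro
and acetoxy fragments, capped at 25 heavy atoms, deduplicated by
canonical SMILES. Under the default seed a 60-compound set contains at
least 15 heteroatom-bearing and 15 pure-hydrocarbon molecules, covering
the zero and non-zero regimes of every model descriptor. Activity is
linear in three autoscaled ETA descriptors
(`ETA_dEpsilon_D`, `ETA_EtaP_F`, `ETA_BetaP_s`; coefficients
-1.0/0.8/-0.6) plus Gaussian noise at a 9:1 signal-to-noise variance
ratio — the regime where a correct model reaches R² ~ 0.9. What passing
tests on these sets show is that the machinery recovers a known linear
signal at realistic size and noise; they do not show anything about
real larvicidal SAR, and the generator does not emulate features of the
real data such as enantiomer pairs with distinct measured activities
but identical 2D descriptors (a structural limitation of any
topological-descriptor model).

The selection-recovery study runs at n = 60 with a 30-column pool: the
three true descriptors, every other computed descriptor whose
correlation with each truth column stays below 0.7 (near-duplicate
distractor pairs at |r| >= 0.95 pruned), and seeded standard-normal
noise columns padding to 30. The proxy exclusion is what makes
"contains the true subset" a well-posed question: the full ETA block
contains column groups that jointly reconstruct the truth almost
exactly, in which case selection among them is statistically
indifferent.

## Numerical choices and degenerate inputs

Similarity threshold for the 0.5/0.75 and 1.0/1.5 VEM rules: 0.3 (in
epsilon units), consistent with the C/N/O separations of the scheme;
exposed as a constant. Distances in eta use squared topological
distance under the square root, i.e. `sqrt(gamma_i gamma_j)/d`. Charged
input is accepted but Zv is taken from the neutral element. k-medoids
ties and GA ties break deterministically (input order; subset size then
column order). All randomness flows from explicit integer seeds through
`numpy.random.Generator`; reruns are byte-identical.

## Problem sizes used in the shipped checks

The test suite and acceptance script run at desk scale by design: the
descriptor checks use the 15 curated named compounds, metric oracles
use 200 random inputs of up to 10 rows, and the recovery study uses 10
seeds of the n = 60 study conditions (about half a minute in total).
The pipeline itself has no size limits beyond memory; the k-medoids
distance matrix is O(n²).

## Known limitations

- Descriptors outside the validated subset follow plausible but
  unconfirmed conventions (flagged in output metadata).
- DModX critical values are from the normalized-variant F approximation
  and will not bit-match other software's internally rescaled values.
- The k-medoids alternation is a local search; different seeds can give
  different (equally valid) divisions on weakly clustered data.
- Which descriptor subset wins selection on a given dataset depends on
  GA settings and fold composition; the pipeline therefore also exposes
  the fixed-subset modeling path (`fit_published_model`) for
  reproducing a known model specification exactly.
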