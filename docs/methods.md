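# Methods

specres maps sequence variation to enzyme function for panels of
acyl-ACP thioesterase (TE) variants. A TE's substrate specificity — its
acyl chain-length preference — is observed as the fatty-acid profile it
produces in vivo (mol% over species such as 8:0 … 16:1). The package
asks: *which alignment positions determine that specificity?* It
answers in four stages, each exposed as a library function and a CLI
subcommand, plus a synthetic-panel generator that makes every stage
testable by parameter recovery.

## 1. Profile clustering

Profiles are z-scored per fatty-acid species using the sample (n−1)
standard deviation; species with zero spread are flagged constant and
set to all-zero rather than dropped, so column indices keep matching
species labels. Enzymes are clustered by Ward's variance-minimizing
linkage on Euclidean distances of the scaled profiles (SciPy's `ward`,
i.e. the Ward.D2 form appropriate for Euclidean input).

The dendrogram is pruned with an **adaptive tree cut**
(`specres.treecut`) rather than a fixed-height cut, so the number of
clusters follows from tree shape. Merges are scanned bottom-up; a
branch qualifies as a cluster core when it has at least
`min_cluster_size` leaves (default 4) and joins the tree at a height
whose gap above the branch's own internal merges exceeds a fraction of
the total height span — the fraction set by `deep_split` (0–4, default
1 ⇒ 0.25; larger values split more finely). Once two qualifying
branches are kept apart, every merge above them only glues distinct
clusters. Branches too small or too shallow to qualify are assigned
leaf-by-leaf to the nearest cluster centroid, so every enzyme is
labelled. This is the same two-stage idea as the "dynamic hybrid"
cut (shape-based branch detection, then a PAM-like assignment stage),
implemented natively here. Determinism: there is no randomness anywhere
in this stage; merge-height ties are resolved by SciPy's stable
ordering.

PCA runs on the scaled matrix (centered, no re-scaling) and reports
variance fractions in percent; tests pin these against a direct
covariance eigendecomposition at 1e−8.

## 2. Pairwise encoding

Every unordered enzyme pair is one instance: feature j is 1 iff the two
sequences differ at alignment column j. The gap character is treated as
a 21st residue letter (gap/gap → 0, gap/residue → 1): natural variant
panels contain indels and a same/different rule over all characters is
the only encoding that needs no further assumptions. Monomorphic
columns are kept as all-zero features so feature indices equal
alignment positions end-to-end. The response is 1 for between-cluster
pairs. A control column of i.i.d. Bernoulli(0.5) draws — the
maximum-entropy binary variable — rides along as a negative control and
is redrawn per replicate classifier. Pairs are ordered lexicographically
by id, making the dataset independent of input row order.

## 3. Random-forest importance

Forests use Gini impurity, bootstrap sampling (n rows per tree), and
`mtry = floor(sqrt(p))` candidate features per split; defaults are 500
trees and 10 replicate classifiers. Importance is the **unnormalized**
total decrease in node Gini impurity attributed to a feature, weighted
by node sample counts and averaged over trees (scikit-learn's
normalized `feature_importances_` would distort cross-model
comparisons; the unnormalized form is the scale R's `ranger` reports).
Features never selected score exactly 0.

P-values come from an explicit response-permutation null: per
replicate, the response is permuted `n_null_permutations` times
(default 100), the forest refit, and each feature's observed importance
compared with its own null sample, p = (1 + #{null ≥ obs}) / (1 + N).
This Altmann-style scheme is distribution-free and fully specified. Per
feature the reported p-value is the **maximum over replicates**
(conservative), the importance the replicate mean.
Benjamini–Hochberg correction runs across all L+1 features (positions
plus control, which is carried as a residue-like feature);
`significant` means q below the configured threshold (default 0.05).

A structural caveat: permutation p-values are floored at 1/(1+N), so a
small set of k true positives among L features can only clear the BH
threshold k/L·q when N ≳ L/(k·q). Panels with few determinant positions
therefore need more permutations (the acceptance script uses N = 999),
whereas a regime with hundreds of associated positions is comfortable
at the default. `compute_pvalues=False` skips the null entirely when
only the ranking is needed.

## 4. Incremental feature selection

Positions are ranked once, globally, by mean importance (control
excluded; ties toward the smaller position). Models use the top k
positions for k = 2..k_max. Each (k, repetition) draws a fresh
stratified fold partition of the pair rows (default 10 folds, 20
repetitions); per fold a forest is trained on the remaining rows and
the held-out predictions are pooled into one confusion table per
repetition (micro-averaging — per-fold MCC is unstable on small folds).
Folds are over pairs, not enzymes, so enzymes are shared between train
and test pairs; that leakage is inherent to the pairwise design and is
why the metrics describe *relationship* classification, not prediction
for unseen enzymes. A partition whose training side loses a class is
redrawn (logged, max 10).

Recall = TP/(TP+FN), specificity = TN/(TN+FP), and
MCC = (TP·TN − FP·FN)/√((TP+FP)(TP+FN)(TN+FP)(TN+FN)), with
between-cluster pairs as positives; a zero marginal makes MCC undefined
and it is reported as 0 with a degeneracy flag.

The **optimal** model maximizes mean MCC (ties → smallest k). The
**plateau** model operationalizes "statistically flat": adjacent model
sizes are compared by two-sample Student t-tests on their repetition
MCC values (equal-variance by default, Welch by flag; exactly constant
samples with equal means give p = 1), BH-corrected over all adjacent
comparisons; k_plateau is the smallest k such that its comparison and
all later ones up to the optimum have q > α (default 0.05). Requiring
*all* subsequent steps non-significant is the conservative reading; the
first single non-significant step is also reported. When no k
qualifies, k_plateau falls back to the optimum.

## Synthetic panels and what they show

`generate_panel` emulates the statistical structure the analysis
assumes: round-robin class assignment (3 classes by default), a random
consensus sequence, planted columns carrying one residue letter per
class, non-planted polymorphic columns scattering 2–8 letters
independent of class, and profiles drawn as class means over seven
species (8:0 … 16:1; C8-dominant / broad / C14-C16-dominant templates)
plus Gaussian noise (default sd 2.0 mol%), truncated at zero and
renormalized to 100 mol%. Defaults (57 enzymes, 350 columns, 100
polymorphic, 12 planted) mirror a realistic directed-evolution panel.

With full penetrance every planted column encodes to the *same*
pairwise feature (different iff different class), i.e. one planted
position is already a perfect predictor and the IFS plateau sits
trivially at k = 2. The `leakage` parameter (per-enzyme probability of
drawing another class's letter) breaks this redundancy; at leakage 0.25
a single planted column is a distinctly imperfect predictor and the
determinant signal is genuinely distributed across the planted set, so
ranking and plateau recovery become non-trivial tests. Recovery checks
and the acceptance script use this regime.

What the generator does **not** emulate: phylogenetic correlation
between sequences (real variant panels share ancestry, inflating
between-position correlation), compositional noise structure in GC-MS
profiles, recurrent isolates, or class-imbalanced panels. Passing
recovery tests therefore shows the statistical machinery is correct and
calibrated, not that real panels carry as clean a signal.

## Problem sizes and numerics

Test and acceptance-script simulations are sized for a single-CPU
desk-scale run: 100-tree forests, 2–3 replicate classifiers, 5-fold ×
5-repetition IFS over k ≤ 30, 20 seeds for ranking recovery and 5 seeds
for plateau recovery, 50 simulations for null calibration (20-enzyme,
100-column panels, 20 permutations), and N = 999 permutations in the
acceptance script where FDR significance itself is reported. Library
defaults remain at the full protocol (500 trees, 10 replicates, 10×20
CV). All randomness flows from one master seed through named
`SeedSequence` streams (`derive_seeds`), making every result
bit-reproducible; seeds are kept below 2^31.

## Known limitations

- Cluster labels feed the response; enzymes misclustered due to profile
  noise propagate label noise into the classifier, and nothing
  downstream corrects for it.
- The adaptive cut's gap thresholds are heuristic; very unbalanced or
  chained data may need `deep_split` adjusted.
- Importance spreads credit over correlated positions (including true
  co-determinants), so per-position scores understate redundant signal;
  the IFS stage is the remedy, not the raw ranking.
- No class-imbalance correction is applied; class proportions are
  logged in the run metadata.
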