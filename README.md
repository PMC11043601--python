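# specres

**Specificity-determining residue discovery for acyl-ACP thioesterases
(and similar enzyme panels).**

Acyl-ACP thioesterases (TEs) terminate fatty-acid synthesis by
hydrolyzing the acyl–ACP thioester bond; which chain lengths a TE
releases — its substrate specificity — is read out as the fatty-acid
profile (mol% of 8:0 … 16:1) the enzyme produces in vivo. Given a
multiple sequence alignment of TE variants and their profiles, specres
identifies the alignment positions that govern specificity:

1. **Cluster** enzymes by specificity: per-species z-scoring, Ward
   linkage on Euclidean distances, adaptive (dynamic) tree cut; PCA
   variance decomposition of the profiles.
2. **Encode** every enzyme pair as a binary vector over alignment
   columns (1 = residues differ), plus a random control feature, with a
   binary response (1 = different specificity clusters).
3. **Score** each position by replicated random-forest Gini importance
   (500 trees × 10 replicates by default), with response-permutation
   p-values (replicate maximum) and Benjamini–Hochberg FDR control.
4. **Select** a minimal position set by incremental feature selection:
   models over the top-k ranked positions, scored by repeated
   stratified cross-validation with recall = TP/(TP+FN),
   specificity = TN/(TN+FP) and
   MCC = (TP·TN − FP·FN)/√((TP+FP)(TP+FN)(TN+FP)(TN+FN));
   the optimal model maximizes mean MCC and the plateau model is the
   smallest k whose MCC is statistically indistinguishable (adjacent
   t-tests, FDR-corrected q > 0.05) from everything up to the optimum.

A synthetic-panel generator with planted determinant positions and
class-structured profiles makes every stage verifiable by parameter
recovery; see `docs/methods.md` for the model and its assumptions.

## Worked example

```python
import specres

# a 57-enzyme panel, 350 columns, 12 planted determinants; leakage
# makes single determinants imperfect so the signal is distributed
panel, truth = specres.generate_panel(seed=1, leakage=0.25)

clusters = specres.cluster_enzymes(specres.normalize_profiles(panel))
pairs = specres.build_dataset(panel, clusters, control_seed=1)

cfg = specres.ForestConfig(n_trees=100, n_replicates=3, n_null_permutations=20)
imp = specres.importance_scores(pairs, cfg, seed=7, compute_pvalues=False)
ranking = specres.rank_positions(imp)

ifs = specres.ifs_curve(pairs, ranking, k_max=25, config=cfg, seed=11,
                        folds=5, reps=5)
specres.mcc_plateau(ifs)
```

Running `python examples/04_incremental_selection.py` (this exact
analysis) prints:

```
optimal model: k=21 (recall 100%, specificity 98%, MCC 0.98)
plateau model: k=11, positions [39, 122, 332, 176, 194, 214, 237, 44, 23, 187, 172]
planted determinants in plateau set: 11/12
```

Read: 1596 enzyme pairs were classified; a 21-position model predicts
whether two enzymes share specificity essentially perfectly (MCC 0.98),
but already 11 positions reach the statistical MCC plateau — and all 11
are planted determinants (11 of the 12 planted). The `examples/` scripts
walk through each capability; the `specres` CLI
(`simulate | cluster | encode | importance | ifs | run`) exposes the
same stages for shell pipelines, e.g.

```sh
specres run --config run.yml
```

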