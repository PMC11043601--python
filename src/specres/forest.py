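"""Replicated random-forest importance with permutation p-values and FDR.

The classifier learns to predict, from the pairwise binary difference
vectors, whether two enzymes share a specificity cluster. Per-position
importance is the Gini-impurity decrease accumulated over tree nodes
(unnormalized, on the scale a count-weighted impurity sum gives),
averaged over the trees of a forest. Because forest construction is
stochastic, the whole fit is replicated with fresh seeds and a freshly
drawn control column; the reported importance is the replicate mean and
the reported p-value the replicate maximum — a conservative aggregate.
P-values come from an explicit response-permutation null: the response
vector is shuffled, the forest refit, and the observed importance
compared with each feature's own null distribution. Benjamini-Hochberg
controls the FDR across features.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from statsmodels.stats.multitest import multipletests

from .encoding import CONTROL_COLUMN, PairDataset

_SEED_MASK = 2**31 - 1


def derive_seeds(master_seed: int, n: int, stream: str = "") -> np.ndarray:
    """Derive ``n`` independent 31-bit sub-seeds from a master seed.

    A named stream decorrelates seeds used for different purposes
    (replicates, permutations, folds) under the same master seed.
    """
    entropy = [master_seed] + [ord(c) for c in stream]
    ss = np.random.SeedSequence(entropy)
    return (ss.generate_state(n, dtype=np.uint32) & _SEED_MASK).astype(np.int64)


@dataclass
class ForestConfig:
    """Settings of the replicated forest analysis.

    ``mtry=None`` means floor(sqrt(number of features)), resolved at fit
    time so incremental models with few features get a matching value.
    """

    n_trees: int = 500
    mtry: int | None = None
    n_replicates: int = 10
    n_null_permutations: int = 100
    fdr_threshold: float = 0.05

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.n_null_permutations < 20:
            raise ValueError("n_null_permutations must be >= 20")


def _resolve_mtry(config: ForestConfig, n_features: int) -> int:
    if config.mtry is not None:
        return min(config.mtry, n_features)
    return max(1, int(np.sqrt(n_features)))


def fit_forest(
    X: np.ndarray, y: np.ndarray, config: ForestConfig, seed: int
) -> tuple[RandomForestClassifier, np.ndarray]:
    """Fit one Gini forest and return it with unnormalized importances.

    Importance of feature f = mean over trees of the total decrease in
    node Gini impurity at nodes splitting on f, weighted by the number
    of samples reaching the node (so the scale is per-sample-count, as
    an impurity-sum over a dataset of this size). Features never chosen
    for a split score exactly 0.
    """
    y = np.asarray(y)
    if np.unique(y).size < 2:
        raise ValueError("response has a single class; importance is undefined")
    clf = RandomForestClassifier(
        n_estimators=config.n_trees,
        criterion="gini",
        max_features=_resolve_mtry(config, X.shape[1]),
        bootstrap=True,
        random_state=int(seed),
        n_jobs=1,
    )
    clf.fit(X, y)
    n = X.shape[0]
    imp = np.zeros(X.shape[1])
    for est in clf.estimators_:
        imp += est.tree_.compute_feature_importances(normalize=False) * n
    imp /= len(clf.estimators_)
    return clf, imp


def fit_forest_on_pairs(
    data: PairDataset, config: ForestConfig, seed: int
) -> tuple[RandomForestClassifier, np.ndarray]:
    """`fit_forest` on a pair dataset's full feature block (incl. control)."""
    return fit_forest(data.features, data.response, config, seed)


@dataclass
class ImportanceTable:
    """Per-feature importance summary over replicate forests.

    One row per alignment position plus one for the control feature.
    ``p_value`` is the maximum over replicates; ``q_value`` the BH-FDR
    adjusted value across all features; NaN when p-values were not
    computed.
    """

    table: pd.DataFrame
    fdr_threshold: float
    n_replicates: int

    def to_frame(self) -> pd.DataFrame:
        return self.table.copy()

    @property
    def n_significant(self) -> int:
        return int(self.table["significant"].sum())

    def significant_positions(self) -> list[int]:
        t = self.table
        mask = t["significant"] & (t["feature"] != CONTROL_COLUMN)
        return [int(p) for p in t.loc[mask, "position"]]


def _replicate_pvalues(
    data: PairDataset,
    config: ForestConfig,
    observed: np.ndarray,
    perm_seeds: np.ndarray,
) -> np.ndarray:
    """Permutation p-values for one replicate: p = (1 + #null>=obs)/(1 + N)."""
    exceed = np.zeros_like(observed)
    y = data.response
    for pseed in perm_seeds:
        rng = np.random.default_rng(int(pseed))
        y_perm = rng.permutation(y)
        _, null_imp = fit_forest(data.features, y_perm, config, int(pseed))
        exceed += null_imp >= observed
    return (1.0 + exceed) / (1.0 + len(perm_seeds))


def importance_scores(
    data: PairDataset,
    config: ForestConfig,
    seed: int,
    compute_pvalues: bool = True,
) -> ImportanceTable:
    """Replicated importance analysis of a pair dataset.

    Each replicate uses a distinct forest seed and a freshly drawn
    control column. When ``compute_pvalues`` is False only the mean
    importances are produced (sufficient for ranking), which skips the
    permutation refits entirely.
    """
    L = data.n_positions
    rep_seeds = derive_seeds(seed, config.n_replicates, "replicates")
    control_seeds = derive_seeds(seed, config.n_replicates, "controls")

    importances = np.zeros((config.n_replicates, L + 1))
    pvals = np.full((config.n_replicates, L + 1), np.nan)
    for r in range(config.n_replicates):
        rep_data = data.with_control(int(control_seeds[r]))
        _, imp = fit_forest_on_pairs(rep_data, config, int(rep_seeds[r]))
        importances[r] = imp
        if compute_pvalues:
            perm_seeds = derive_seeds(
                int(rep_seeds[r]), config.n_null_permutations, "null"
            )
            pvals[r] = _replicate_pvalues(rep_data, config, imp, perm_seeds)

    mean_imp = importances.mean(axis=0)
    features = [str(j) for j in range(1, L + 1)] + [CONTROL_COLUMN]
    positions = list(range(1, L + 1)) + [np.nan]
    if compute_pvalues:
        p_max = pvals.max(axis=0)
        q, flags = fdr_correct(p_max, config.fdr_threshold)
    else:
        p_max = np.full(L + 1, np.nan)
        q = np.full(L + 1, np.nan)
        flags = np.zeros(L + 1, dtype=bool)

    table = pd.DataFrame(
        {
            "feature": features,
            "position": positions,
            "mean_importance": mean_imp,
            "p_value": p_max,
            "q_value": q,
            "significant": flags,
        }
    )
    return ImportanceTable(
        table=table, fdr_threshold=config.fdr_threshold, n_replicates=config.n_replicates
    )


def fdr_correct(
    p_values: np.ndarray, q_threshold: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up q-values and significance flags.

    Returns ``(q_values, flags)`` aligned with the input order; an empty
    input yields empty arrays.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q, q < q_threshold
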