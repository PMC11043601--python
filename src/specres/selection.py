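"""Incremental feature selection over importance-ranked positions.

Positions are ranked once, globally, by mean importance. A series of
forests is then grown: the first on the two top-ranked positions, each
subsequent one adding the next position in rank order. Every model is
scored by cross-validation — recall, specificity and the Matthews
correlation coefficient (MCC) on the pooled held-out predictions — and
the whole procedure is repeated with fresh fold partitions to get a
spread of MCC values per model size. Two model sizes are then singled
out: the size with the best mean MCC (optimal model) and the smallest
size beyond which adjacent models are statistically indistinguishable
(MCC plateau, adjacent two-sample t-tests with BH-FDR correction).

Between-cluster pairs (response 1) are the positive class throughout:
recall = TP/(TP+FN), specificity = TN/(TN+FP).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import StratifiedKFold

from .encoding import CONTROL_COLUMN, PairDataset
from .forest import ForestConfig, derive_seeds, fdr_correct, fit_forest

logger = logging.getLogger(__name__)


@dataclass
class ConfusionCounts:
    tp: int
    fn: int
    tn: int
    fp: int

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.tn + self.fp

    @classmethod
    def from_predictions(cls, y_true: np.ndarray, y_pred: np.ndarray) -> "ConfusionCounts":
        y_true = np.asarray(y_true).astype(int)
        y_pred = np.asarray(y_pred).astype(int)
        return cls(
            tp=int(np.sum((y_true == 1) & (y_pred == 1))),
            fn=int(np.sum((y_true == 1) & (y_pred == 0))),
            tn=int(np.sum((y_true == 0) & (y_pred == 0))),
            fp=int(np.sum((y_true == 0) & (y_pred == 1))),
        )


@dataclass
class MetricTriple:
    recall: float
    specificity: float
    mcc: float
    degenerate: bool = False  # a confusion-table marginal was zero


def compute_metrics(counts: ConfusionCounts) -> MetricTriple:
    """Recall, specificity and MCC from a confusion table.

    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)); when any
    marginal is zero the MCC is undefined and reported as 0 with the
    degenerate flag set. Recall/specificity with a zero denominator are
    reported as 0 under the same flag.
    """
    if counts.total == 0:
        raise ValueError("empty confusion table")
    tp, fn, tn, fp = counts.tp, counts.fn, counts.tn, counts.fp
    degenerate = False
    pos, neg = tp + fn, tn + fp
    recall = tp / pos if pos else 0.0
    specificity = tn / neg if neg else 0.0
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        mcc, degenerate = 0.0, True
    else:
        mcc = (tp * tn - fp * fn) / np.sqrt(denom)
    if pos == 0 or neg == 0:
        degenerate = True
    return MetricTriple(recall=recall, specificity=specificity, mcc=mcc, degenerate=degenerate)


def rank_positions(importance) -> list[int]:
    """Alignment positions in descending mean-importance order.

    The control feature is excluded; ties break toward the smaller
    position index.
    """
    table = importance.to_frame() if hasattr(importance, "to_frame") else importance
    rows = table[table["feature"] != CONTROL_COLUMN]
    if rows.empty:
        raise ValueError("importance table has no positions to rank")
    ordered = rows.sort_values(
        ["mean_importance", "position"], ascending=[False, True], kind="mergesort"
    )
    return [int(p) for p in ordered["position"]]


@dataclass
class IFSResult:
    """Cross-validated metrics per candidate model size.

    ``replicate_metrics[k]`` holds a (reps, 3) array of per-repetition
    recall/specificity/MCC; ``curve`` their means per k. The plateau
    fields are filled in by :func:`mcc_plateau`.
    """

    k_grid: list[int]
    replicate_metrics: dict[int, np.ndarray]
    curve: pd.DataFrame
    ranking: list[int]
    k_optimal: int
    k_plateau: int | None = None
    plateau_positions: list[int] | None = None
    adjacent_tests: pd.DataFrame | None = None
    first_nonsignificant_step: int | None = None
    n_fold_redraws: int = 0

    def selected_positions(self, k: int) -> list[int]:
        return self.ranking[:k]

    def mean_mcc(self) -> pd.Series:
        return self.curve.set_index("k")["mcc"]

    def to_frame(self) -> pd.DataFrame:
        df = self.curve.copy()
        if self.adjacent_tests is not None:
            df = df.merge(
                self.adjacent_tests[["k", "p_value", "q_value"]], on="k", how="left"
            )
        return df


def _cv_metrics_one_rep(
    X: np.ndarray,
    y: np.ndarray,
    config: ForestConfig,
    fold_seed: int,
    forest_seed: int,
    folds: int,
) -> tuple[MetricTriple, int]:
    """One repetition: fresh stratified partition, pooled held-out confusion.

    A partition whose training side loses a class is redrawn (up to 10
    times); the redraw count is returned for logging.
    """
    redraws = 0
    while True:
        splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=fold_seed)
        splits = list(splitter.split(X, y))
        if all(np.unique(y[tr]).size == 2 for tr, _ in splits):
            break
        redraws += 1
        fold_seed = int(derive_seeds(fold_seed, 1, "redraw")[0])
        if redraws > 10:
            raise ValueError("could not draw folds with both classes in training")
    y_pred = np.empty_like(y)
    tree_seeds = derive_seeds(forest_seed, folds, "folds")
    for f, (train, test) in enumerate(splits):
        clf, _ = fit_forest(X[train], y[train], config, int(tree_seeds[f]))
        y_pred[test] = clf.predict(X[test])
    counts = ConfusionCounts.from_predictions(y, y_pred)
    return compute_metrics(counts), redraws


def ifs_curve(
    data: PairDataset,
    ranking: list[int],
    k_max: int,
    config: ForestConfig,
    seed: int,
    folds: int = 10,
    reps: int = 20,
) -> IFSResult:
    """Build the incremental model series and score each size by CV.

    For every model size k (2..k_max) and every repetition, the pair
    rows are split into stratified folds anew, a forest is trained per
    fold on the k top-ranked position columns only, and the held-out
    predictions are pooled into one confusion table. mtry follows
    floor(sqrt(k)) unless pinned in ``config``.
    """
    if k_max > len(ranking):
        raise ValueError(f"k_max={k_max} exceeds ranking length {len(ranking)}")
    if folds < 2:
        raise ValueError("folds must be >= 2")
    k_grid = list(range(2, k_max + 1))
    y = data.response.astype(int)
    X_all = data.position_features()
    # ranking holds 1-based alignment positions
    col_order = [p - 1 for p in ranking]

    fold_seeds = derive_seeds(seed, len(k_grid) * reps, "ifs-folds").reshape(
        len(k_grid), reps
    )
    forest_seeds = derive_seeds(seed, len(k_grid) * reps, "ifs-forests").reshape(
        len(k_grid), reps
    )

    replicate_metrics: dict[int, np.ndarray] = {}
    total_redraws = 0
    for ki, k in enumerate(k_grid):
        X = X_all[:, col_order[:k]]
        out = np.empty((reps, 3))
        for r in range(reps):
            triple, redraws = _cv_metrics_one_rep(
                X, y, config, int(fold_seeds[ki, r]), int(forest_seeds[ki, r]), folds
            )
            total_redraws += redraws
            out[r] = (triple.recall, triple.specificity, triple.mcc)
        replicate_metrics[k] = out
    if total_redraws:
        logger.info("fold partitions redrawn %d times", total_redraws)

    curve = pd.DataFrame(
        {
            "k": k_grid,
            "recall": [replicate_metrics[k][:, 0].mean() for k in k_grid],
            "specificity": [replicate_metrics[k][:, 1].mean() for k in k_grid],
            "mcc": [replicate_metrics[k][:, 2].mean() for k in k_grid],
        }
    )
    result = IFSResult(
        k_grid=k_grid,
        replicate_metrics=replicate_metrics,
        curve=curve,
        ranking=list(ranking),
        k_optimal=0,
        n_fold_redraws=total_redraws,
    )
    result.k_optimal = select_optimal(result)
    return result


def select_optimal(result: IFSResult) -> int:
    """Model size with the highest mean MCC; ties go to the smaller size."""
    mcc = result.mean_mcc()
    return int(mcc.index[np.argmax(mcc.to_numpy())])


def mcc_plateau(
    result: IFSResult,
    alpha: float = 0.05,
    equal_var: bool = True,
) -> int:
    """Smallest model size at the statistical MCC plateau.

    Adjacent model sizes k and k+1 are compared by a two-sample t-test
    on their replicate MCC values (classic equal-variance Student form
    by default; ``equal_var=False`` gives Welch). P-values are BH-FDR
    corrected over all adjacent comparisons. The plateau is the smallest
    k whose comparison with k+1 — and every later comparison up to the
    optimal size — is non-significant (q > alpha). Fills the plateau
    fields of ``result`` and returns k_plateau.
    """
    if len(result.k_grid) < 2:
        raise ValueError("need at least two model sizes to locate a plateau")
    ks, pvals = [], []
    for k in result.k_grid[:-1]:
        a = result.replicate_metrics[k][:, 2]
        b = result.replicate_metrics[k + 1][:, 2]
        if np.isclose(np.var(a), 0, atol=1e-24) and np.isclose(np.var(b), 0, atol=1e-24):
            p = 1.0 if np.isclose(np.mean(a), np.mean(b)) else 0.0
        else:
            with warnings.catch_warnings():
                # near-identical samples trip a precision warning; the
                # resulting p is replaced below when it degenerates
                warnings.simplefilter("ignore", RuntimeWarning)
                p = float(stats.ttest_ind(a, b, equal_var=equal_var).pvalue)
            if np.isnan(p):  # numerically identical samples
                p = 1.0
        ks.append(k)
        pvals.append(min(max(p, np.finfo(float).tiny), 1.0))
    q, _ = fdr_correct(np.array(pvals), alpha)
    tests = pd.DataFrame({"k": ks, "p_value": pvals, "q_value": q})

    k_opt = result.k_optimal or select_optimal(result)
    upto = [i for i, k in enumerate(ks) if k < k_opt]
    k_plateau = None
    for i in upto:
        if all(q[j] > alpha for j in upto if j >= i):
            k_plateau = ks[i]
            break
    first_ns = next((ks[i] for i in range(len(ks)) if q[i] > alpha), None)
    if k_plateau is None:
        # MCC still changing significantly right up to the optimum
        k_plateau = k_opt

    result.k_plateau = int(k_plateau)
    result.plateau_positions = result.selected_positions(int(k_plateau))
    result.adjacent_tests = tests
    result.first_nonsignificant_step = first_ns
    return int(k_plateau)
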