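import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from sklearn.metrics import matthews_corrcoef

import specres
from specres import ConfusionCounts, ForestConfig, IFSResult, compute_metrics
from specres.encoding import CONTROL_COLUMN, PairDataset


class TestComputeMetrics:
    @pytest.mark.parametrize(
        "counts, expected",
        [
            (ConfusionCounts(10, 0, 10, 0), (1.0, 1.0, 1.0)),
            (ConfusionCounts(0, 10, 0, 10), (0.0, 0.0, -1.0)),
            (ConfusionCounts(5, 5, 5, 5), (0.5, 0.5, 0.0)),
        ],
    )
    def test_reference_tables(self, counts, expected):
        m = compute_metrics(counts)
        assert (m.recall, m.specificity, m.mcc) == pytest.approx(expected)

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            compute_metrics(ConfusionCounts(0, 0, 0, 0))

    def test_degenerate_marginal_flagged(self):
        m = compute_metrics(ConfusionCounts(5, 5, 0, 0))
        assert m.degenerate and m.mcc == 0.0

    @given(st.integers(0, 2**32 - 1))
    def test_matches_per_instance_counting_and_sklearn(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 40))
        y_true = rng.integers(0, 2, n)
        y_pred = rng.integers(0, 2, n)
        counts = ConfusionCounts.from_predictions(y_true, y_pred)
        # brute-force oracle: count each instance individually
        tp = sum(1 for t, p in zip(y_true, y_pred) if t == 1 and p == 1)
        fn = sum(1 for t, p in zip(y_true, y_pred) if t == 1 and p == 0)
        tn = sum(1 for t, p in zip(y_true, y_pred) if t == 0 and p == 0)
        fp = sum(1 for t, p in zip(y_true, y_pred) if t == 0 and p == 1)
        assert (counts.tp, counts.fn, counts.tn, counts.fp) == (tp, fn, tn, fp)
        m = compute_metrics(counts)
        if not m.degenerate:
            assert m.mcc == pytest.approx(matthews_corrcoef(y_true, y_pred))


def _importance_frame(positions, scores, with_control=True):
    feats = [str(p) for p in positions]
    pos = list(positions)
    if with_control:
        feats.append(CONTROL_COLUMN)
        pos.append(np.nan)
        scores = list(scores) + [0.1]
    return pd.DataFrame(
        {"feature": feats, "position": pos, "mean_importance": scores}
    )


class TestRankPositions:
    def test_descending_by_importance(self):
        table = _importance_frame([5, 2], [3.0, 7.0])
        assert specres.rank_positions(table) == [2, 5]

    def test_ties_break_to_smaller_position(self):
        table = _importance_frame([9, 4], [2.0, 2.0])
        assert specres.rank_positions(table) == [4, 9]

    def test_control_feature_excluded(self):
        table = _importance_frame([1, 2], [1.0, 2.0])
        assert CONTROL_COLUMN not in [str(p) for p in specres.rank_positions(table)]


def _result_from_mcc(mcc_by_k):
    k_grid = sorted(mcc_by_k)
    reps = {k: np.column_stack([np.ones(len(v)), np.ones(len(v)), np.asarray(v)])
            for k, v in mcc_by_k.items()}
    curve = pd.DataFrame(
        {
            "k": k_grid,
            "recall": 1.0,
            "specificity": 1.0,
            "mcc": [np.mean(mcc_by_k[k]) for k in k_grid],
        }
    )
    res = IFSResult(
        k_grid=k_grid,
        replicate_metrics=reps,
        curve=curve,
        ranking=list(range(1, max(k_grid) + 1)),
        k_optimal=0,
    )
    res.k_optimal = specres.select_optimal(res)
    return res


class TestSelectOptimal:
    def test_ties_resolve_to_smallest_k(self):
        res = _result_from_mcc({2: [0.5], 3: [0.8], 4: [0.8], 5: [0.7]})
        assert res.k_optimal == 3

    def test_monotone_curve_selects_kmax(self):
        res = _result_from_mcc({k: [0.1 * k] for k in range(2, 7)})
        assert res.k_optimal == 6


class TestMccPlateau:
    def test_constructed_curve_plateaus_where_values_stabilize(self, rng):
        # below k=4 the MCC climbs in clear steps; from k=4 on it is flat
        mcc = {
            2: 0.5 + rng.normal(0, 0.01, 20),
            3: 0.7 + rng.normal(0, 0.01, 20),
            4: 0.9 + rng.normal(0, 0.01, 20),
            5: 0.9 + rng.normal(0, 0.01, 20),
            6: 0.9 + rng.normal(0, 0.01, 20),
        }
        res = _result_from_mcc(mcc)
        k_plateau = specres.mcc_plateau(res, alpha=0.05)
        assert k_plateau == 4
        assert res.plateau_positions == [1, 2, 3, 4]
        assert res.adjacent_tests["q_value"].iloc[0] < 0.05

    def test_identical_replicates_everywhere_plateau_at_start(self):
        res = _result_from_mcc({k: [0.8, 0.8, 0.8] for k in range(2, 6)})
        # zero variance, equal means -> p = 1 by convention at every step
        assert specres.mcc_plateau(res) == 2

    def test_single_k_curve_rejected(self):
        res = _result_from_mcc({2: [0.5, 0.6]})
        with pytest.raises(ValueError, match="two model sizes"):
            specres.mcc_plateau(res)

    def test_still_climbing_at_optimum_falls_back_to_optimum(self, rng):
        mcc = {2: 0.2 + rng.normal(0, 0.01, 10), 3: 0.5 + rng.normal(0, 0.01, 10),
               4: 0.9 + rng.normal(0, 0.01, 10)}
        res = _result_from_mcc(mcc)
        assert specres.mcc_plateau(res) == res.k_optimal == 4


def _pair_dataset(rng, n_rows=120, n_pos=8):
    X = rng.integers(0, 2, size=(n_rows, n_pos + 1)).astype(np.uint8)
    y = X[:, 0].copy()  # position 1 predicts perfectly
    return PairDataset(
        pairs=[(f"a{i}", f"b{i}") for i in range(n_rows)],
        features=X,
        response=y,
        control_seed=0,
    )


class TestIfsCurve:
    def test_perfect_predictor_keeps_mcc_at_one_for_all_k(self, rng):
        data = _pair_dataset(rng)
        cfg = ForestConfig(n_trees=25, n_null_permutations=20)
        res = specres.ifs_curve(
            data, ranking=list(range(1, 9)), k_max=5, config=cfg, seed=3, folds=4, reps=2
        )
        assert np.allclose(res.curve["mcc"], 1.0)
        assert res.k_optimal == 2

    def test_bit_identical_for_fixed_seed(self, rng):
        data = _pair_dataset(rng)
        cfg = ForestConfig(n_trees=10, n_null_permutations=20)
        kw = dict(ranking=list(range(1, 9)), k_max=4, config=cfg, folds=3, reps=2)
        r1 = specres.ifs_curve(data, seed=9, **kw)
        r2 = specres.ifs_curve(data, seed=9, **kw)
        pd.testing.assert_frame_equal(r1.curve, r2.curve)
        for k in r1.k_grid:
            np.testing.assert_array_equal(r1.replicate_metrics[k], r2.replicate_metrics[k])

    def test_kmax_beyond_ranking_rejected(self, rng):
        data = _pair_dataset(rng)
        with pytest.raises(ValueError, match="k_max"):
            specres.ifs_curve(
                data, ranking=[1, 2, 3], k_max=5,
                config=ForestConfig(n_trees=5, n_null_permutations=20), seed=0,
            )
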