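"""The CART engine: split search vs brute-force enumeration, growth,
cross-validation, grid selection, surrogates, importance, serialization."""

import itertools
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import murtree as mt
from murtree.errors import UndefinedStatisticError
from murtree.tree import (
    CartGridSearch,
    CartRegressor,
    FitConfig,
    best_split,
    cross_validate,
)


# ---------------------------------------------------------------------------
# independent brute-force oracle (kept deliberately naive)


def oracle_best_reduction(x, y, ordered_levels=None):
    """Exhaustively enumerate every proper non-empty level subset and return
    the maximal SSE reduction (None if no positive reduction exists)."""
    x = np.asarray(x, dtype=object)
    y = np.asarray(y, dtype=float)
    levels = sorted(set(x)) if ordered_levels is None else list(ordered_levels)
    best = 0.0

    def sse(v):
        return ((v - v.mean()) ** 2).sum() if len(v) else 0.0

    parent = sse(y)
    if ordered_levels is None:
        subsets = itertools.chain.from_iterable(
            itertools.combinations(levels, k) for k in range(1, len(levels))
        )
    else:
        subsets = (tuple(levels[:k]) for k in range(1, len(levels)))
    for left in subsets:
        mask = np.isin(x, left)
        if not mask.any() or mask.all():
            continue
        red = parent - sse(y[mask]) - sse(y[~mask])
        best = max(best, red)
    return best if best > 1e-12 else None


def oracle_greedy_tree(X, y, cp, minsplit, maxdepth, sse_root=None, depth=0):
    """Reference greedy grower: returns the list of leaf (indices, mean)."""
    y = np.asarray(y, dtype=float)
    if sse_root is None:
        sse_root = ((y - y.mean()) ** 2).sum()
    idx = np.arange(len(y))
    if len(y) < minsplit or depth >= maxdepth:
        return [(idx, y.mean())]
    best, best_col, best_left = None, None, None
    for col in X.columns:
        levels = sorted(set(X[col]))
        for k in range(1, len(levels)):
            for left in itertools.combinations(levels, k):
                mask = X[col].isin(left).to_numpy()
                if not mask.any() or mask.all():
                    continue
                sse = lambda v: ((v - v.mean()) ** 2).sum()
                red = sse(y) - sse(y[mask]) - sse(y[~mask])
                if best is None or red > best + 1e-12:
                    best, best_col, best_left = red, col, left
    if best is None or best < cp * sse_root - 1e-12:
        return [(idx, y.mean())]
    mask = X[best_col].isin(best_left).to_numpy()
    out = []
    for m in (mask, ~mask):
        sub = oracle_greedy_tree(
            X[m].reset_index(drop=True), y[m], cp, minsplit, maxdepth, sse_root, depth + 1
        )
        out.extend((idx[m][ii], mean) for ii, mean in sub)
    return out


def random_fixture(rng, n_max=12, n_levels_max=4):
    n = int(rng.integers(4, n_max + 1))
    k = int(rng.integers(2, n_levels_max + 1))
    x = rng.choice([chr(65 + i) for i in range(k)], n)
    y = np.round(rng.normal(50, 20, n), 3)
    return x, y


# ---------------------------------------------------------------------------


class TestBestSplit:
    def test_hand_computed_reduction(self):
        # parent SSE 1600, both children pure
        spec = best_split(["A", "A", "B", "B"], [10, 10, 50, 50])
        assert spec.left_levels == ("A",)
        assert spec.sse_reduction == pytest.approx(1600.0)

    def test_constant_outcome_returns_none(self):
        assert best_split(["A", "B", "A", "B"], [7, 7, 7, 7]) is None

    def test_matches_oracle_on_random_fixtures(self):
        rng = np.random.default_rng(5)
        for _ in range(300):
            x, y = random_fixture(rng)
            spec = best_split(x, y)
            expect = oracle_best_reduction(x, y)
            if expect is None:
                assert spec is None or spec.sse_reduction < 1e-9
            else:
                assert spec.sse_reduction == pytest.approx(expect, rel=1e-9)

    def test_mean_sort_shortcut_agrees_with_exhaustive(self):
        rng = np.random.default_rng(6)
        for _ in range(200):
            x, y = random_fixture(rng)
            a = best_split(x, y, method="exhaustive")
            b = best_split(x, y, method="mean_sort")
            if a is None:
                assert b is None
            else:
                assert b.sse_reduction == pytest.approx(a.sse_reduction, rel=1e-9)
                assert set(a.left_levels) in (set(b.left_levels), set(b.right_levels))

    def test_ordered_variable_only_order_respecting_cuts(self):
        # y is high for the middle level: a nominal split would isolate it,
        # an ordered split cannot
        x = ["lo", "mid", "hi", "lo", "mid", "hi"]
        y = [0, 100, 0, 0, 100, 0]
        nominal = best_split(x, y)
        assert set(nominal.left_levels) in ({"mid"}, {"hi", "lo"})
        ordered = best_split(x, y, ordered_levels=("lo", "mid", "hi"))
        expect = oracle_best_reduction(x, y, ordered_levels=("lo", "mid", "hi"))
        assert ordered.sse_reduction == pytest.approx(expect)
        assert ordered.sse_reduction < nominal.sse_reduction

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=40, derandomize=True, deadline=None)
    def test_children_sse_never_exceeds_parent(self, seed):
        rng = np.random.default_rng(seed)
        x, y = random_fixture(rng)
        spec = best_split(x, y)
        if spec is not None:
            assert spec.sse_reduction >= 0


class TestGrowth:
    def test_perfect_binary_separation(self):
        X = pd.DataFrame({"v": ["A", "A", "B", "B"]})
        tree = CartRegressor(cp=0.01, minsplit=2, maxdepth=8).fit(X, [1, 1, 9, 9])
        assert tree.n_terminal_ == 2
        assert tree.rel_error_ == pytest.approx(0.0)
        assert tree.r2_train_ == pytest.approx(1.0)

    def test_cp_one_blocks_imperfect_splits(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame({"v": rng.choice(["A", "B"], 40)})
        y = np.where(X["v"] == "A", 10.0, 20.0) + rng.normal(0, 3, 40)
        tree = CartRegressor(cp=1.0, minsplit=5).fit(X, y)
        assert tree.n_terminal_ == 1
        assert tree.predict(X) == pytest.approx(np.full(40, y.mean()))

    def test_matches_exhaustive_greedy_reference(self):
        rng = np.random.default_rng(12)
        X = pd.DataFrame(
            {
                "a": rng.choice(list("ABC"), 20),
                "b": rng.choice(["x", "y"], 20),
                "c": rng.choice(["p", "q"], 20),
            }
        )
        y = np.round(rng.normal(100, 30, 20), 2)
        tree = CartRegressor(cp=0.01, minsplit=4, maxdepth=4).fit(X, y)
        ref = oracle_greedy_tree(X, y, cp=0.01, minsplit=4, maxdepth=4)
        ours = sorted(
            round(nd.prediction, 9) for nd in tree.nodes_.values() if nd.is_leaf
        )
        assert ours == sorted(round(m, 9) for _, m in ref)

    def test_heap_numbering_and_child_counts(self, small_ppr_tree):
        nodes = small_ppr_tree.nodes_
        for nid, nd in nodes.items():
            if nid != 1:
                assert nid // 2 in nodes
            if not nd.is_leaf:
                assert nodes[2 * nid].n + nodes[2 * nid + 1].n == nd.n
                assert nodes[2 * nid].sse + nodes[2 * nid + 1].sse <= nd.sse + 1e-9

    def test_leaf_residuals_sum_to_zero(self, small_aggregated, small_ppr_tree):
        X = small_aggregated[list(mt.PPR_PREDICTORS)]
        y = small_aggregated["ppr"].to_numpy()
        leaves = small_ppr_tree.predict_node(X)
        preds = small_ppr_tree.predict(X)
        for leaf in np.unique(leaves):
            assert (y - preds)[leaves == leaf].sum() == pytest.approx(0.0, abs=1e-8)

    def test_rel_error_non_increasing_in_depth(self, small_aggregated):
        X = small_aggregated[list(mt.PPR_PREDICTORS)]
        y = small_aggregated["ppr"].to_numpy()
        rels = [
            CartRegressor(cp=0.01, minsplit=5, maxdepth=d).fit(X, y).rel_error_
            for d in (1, 2, 3, 5, 8)
        ]
        assert all(a >= b - 1e-12 for a, b in zip(rels, rels[1:]))

    def test_rel_error_equals_one_minus_squared_correlation(self, small_aggregated):
        X = small_aggregated[list(mt.PPR_PREDICTORS)]
        y = small_aggregated["ppr"].to_numpy()
        tree = CartRegressor(cp=0.01, minsplit=5, maxdepth=8).fit(X, y)
        r2 = np.corrcoef(y, tree.predict(X))[0, 1] ** 2
        assert 1 - tree.rel_error_ == pytest.approx(r2, abs=1e-12)

    def test_constant_outcome_rel_error_undefined(self):
        X = pd.DataFrame({"v": ["A", "B", "A", "B"]})
        tree = CartRegressor().fit(X, [5.0, 5.0, 5.0, 5.0])
        with pytest.raises(UndefinedStatisticError):
            mt.rel_error(tree)


class TestPrediction:
    def test_training_rows_get_their_leaf_mean(self, small_aggregated, small_ppr_tree):
        X = small_aggregated[list(mt.PPR_PREDICTORS)]
        preds = small_ppr_tree.predict(X)
        leaves = small_ppr_tree.predict_node(X)
        for p, l in zip(preds, leaves):
            assert p == small_ppr_tree.nodes_[l].prediction

    def test_root_only_tree_predicts_grand_mean(self):
        X = pd.DataFrame({"v": ["A", "B", "A"]})
        y = [1.0, 2.0, 6.0]
        tree = CartRegressor(cp=1.0).fit(X, y)
        assert tree.predict(pd.DataFrame({"v": ["Z"]}))[0] == pytest.approx(3.0)

    def test_perfect_surrogate_routes_masked_variable(self):
        # 'copy' duplicates 'v' exactly: agreement 1.0 surrogate
        X = pd.DataFrame({"v": ["A", "A", "B", "B"] * 3, "copy": ["A", "A", "B", "B"] * 3})
        y = [10, 10, 50, 50] * 3
        tree = CartRegressor(cp=0.01, minsplit=2).fit(X, y)
        masked = pd.DataFrame({"v": [np.nan, np.nan], "copy": ["A", "B"]})
        unmasked = pd.DataFrame({"v": ["A", "B"], "copy": ["A", "B"]})
        assert (tree.predict_node(masked) == tree.predict_node(unmasked)).all()
        surr = tree.nodes_[1].surrogates
        assert surr and surr[0].variable == "copy" and surr[0].agreement == 1.0


class TestCrossValidation:
    def test_same_seed_is_deterministic(self, small_aggregated):
        X = small_aggregated[list(mt.PPR_PREDICTORS)]
        y = small_aggregated["ppr"].to_numpy()
        a = cross_validate(X, y, FitConfig(seed=4))
        b = cross_validate(X, y, FitConfig(seed=4))
        assert a.xerror == b.xerror
        assert (a.fold_assignment == b.fold_assignment).all()

    def test_folds_balanced(self, small_aggregated):
        res = cross_validate(
            small_aggregated[list(mt.PPR_PREDICTORS)],
            small_aggregated["ppr"].to_numpy(),
            FitConfig(seed=1),
        )
        sizes = np.bincount(res.fold_assignment)
        assert sizes.max() - sizes.min() <= 1

    def test_pure_noise_xerror_near_or_above_one(self):
        rng = np.random.default_rng(3)
        xerrs = []
        for _ in range(200):
            X = pd.DataFrame({"v": rng.choice(list("AB"), 30)})
            y = rng.normal(0, 1, 30)
            xerrs.append(cross_validate(X, y, FitConfig(minsplit=5, seed=0)).xerror)
        assert np.mean(xerrs) > 0.95

    def test_strong_signal_xerror_below_one(self):
        rng = np.random.default_rng(4)
        X = pd.DataFrame({"v": rng.choice(list("AB"), 200)})
        y = np.where(X["v"] == "A", 0.0, 10.0) + rng.normal(0, 1, 200)
        assert cross_validate(X, y, FitConfig(seed=0)).xerror < 0.5


class TestGridSearch:
    def test_default_grid_has_128_rows(self, small_aggregated):
        gs = CartGridSearch(seed=0, ordered=dict(mt.ORDERED_PREDICTORS)).fit(
            small_aggregated[list(mt.PPR_PREDICTORS)], small_aggregated["ppr"].to_numpy()
        )
        assert len(gs.results_) == 128
        assert gs.best_estimator_.xerror_ == gs.results_["xerror"].min()

    def test_degenerate_grid_single_row(self, small_aggregated):
        gs = CartGridSearch(minsplit_range=[5], maxdepth_range=[8], seed=0).fit(
            small_aggregated[list(mt.PPR_PREDICTORS)], small_aggregated["ppr"].to_numpy()
        )
        assert len(gs.results_) == 1
        assert gs.best_params_["minsplit"] == 5 and gs.best_params_["maxdepth"] == 8

    def test_truncation_equals_direct_growth(self, small_aggregated):
        """The maximal-tree truncation used by the grid must reproduce the
        xerror of an independent per-configuration cross-validation."""
        X = small_aggregated[list(mt.PPR_PREDICTORS)]
        y = small_aggregated["ppr"].to_numpy()
        gs = CartGridSearch(seed=7, ordered=dict(mt.ORDERED_PREDICTORS)).fit(X, y)
        for ms, md in [(5, 8), (12, 9), (20, 15), (7, 11)]:
            direct = cross_validate(
                X, y, FitConfig(minsplit=ms, maxdepth=md, seed=7),
                ordered=dict(mt.ORDERED_PREDICTORS),
            )
            row = gs.results_.query("minsplit == @ms and maxdepth == @md")
            assert row["xerror"].iloc[0] == pytest.approx(direct.xerror, abs=1e-12)

    def test_empty_range_rejected(self, small_aggregated):
        with pytest.raises(ValueError):
            CartGridSearch(minsplit_range=[]).fit(
                small_aggregated[list(mt.PPR_PREDICTORS)],
                small_aggregated["ppr"].to_numpy(),
            )


class TestVariableImportance:
    def test_single_split_full_credit(self):
        X = pd.DataFrame({"v": ["A", "A", "B", "B"], "w": ["p", "q", "p", "q"]})
        tree = CartRegressor(cp=0.01, minsplit=2).fit(X, [1, 1, 9, 9])
        vi = tree.variable_importance()
        assert vi["v"] == pytest.approx(100.0)

    def test_duplicate_predictor_shares_importance(self):
        X = pd.DataFrame({"v": ["A", "A", "B", "B"] * 3, "copy": ["A", "A", "B", "B"] * 3})
        tree = CartRegressor(cp=0.01, minsplit=2).fit(X, [10, 10, 50, 50] * 3)
        vi = tree.variable_importance()
        assert vi["v"] > 0 and vi["copy"] > 0
        assert vi["v"] == pytest.approx(vi["copy"])

    def test_importance_sums_to_100(self, small_ppr_tree):
        assert small_ppr_tree.variable_importance().sum() == pytest.approx(100.0, abs=1e-9)

    def test_root_only_tree_empty_table(self):
        X = pd.DataFrame({"v": ["A", "B"]})
        tree = CartRegressor(cp=1.0).fit(X, [1.0, 1.2])
        assert tree.variable_importance().empty


class TestSerialization:
    def test_round_trip_preserves_predictions(self, small_aggregated, small_ppr_tree):
        X = small_aggregated[list(mt.PPR_PREDICTORS)]
        clone = mt.tree_from_dict(mt.tree_to_dict(small_ppr_tree))
        assert (clone.predict(X) == small_ppr_tree.predict(X)).all()
        assert clone.xerror_ == small_ppr_tree.xerror_

    def test_save_load_file(self, small_ppr_tree, tmp_path):
        path = tmp_path / "tree.json"
        mt.save_tree(small_ppr_tree, path)
        clone = mt.load_tree(path)
        assert mt.tree_to_dict(clone) == mt.tree_to_dict(small_ppr_tree)

    def test_render_mentions_split_variables(self, small_ppr_tree):
        text = mt.render_text(small_ppr_tree)
        root_var = small_ppr_tree.nodes_[1].split.variable
        assert root_var in text and "leaf" in text


class TestRpartCrossCheck:
    def test_leaf_structure_matches_rpart(self, tmp_path):
        """Independent oracle: the R rpart implementation grown at identical
        settings produces the same leaves (sizes and means) on a mixed
        categorical fixture."""
        rng = np.random.default_rng(7)
        n = 60
        X = pd.DataFrame(
            {
                "cat": rng.choice(list("ABCD"), n),
                "flag": rng.choice(["no", "yes"], n),
                "size": rng.choice(["s", "m", "l"], n),
            }
        )
        base = {"A": 10.0, "B": 10.0, "C": 40.0, "D": 70.0}
        y = np.array(
            [base[c] + (15.0 if f == "yes" else 0.0) for c, f in zip(X["cat"], X["flag"])]
        )
        y += rng.normal(0, 3, n)
        ours = CartRegressor(cp=0.01, minsplit=5, maxdepth=8).fit(X, y)

        df = X.copy()
        df["y"] = y
        df.to_csv(tmp_path / "fix.csv", index=False)
        script = textwrap.dedent(
            f"""
            library(rpart)
            d <- read.csv("{tmp_path}/fix.csv", stringsAsFactors=TRUE)
            fit <- rpart(y ~ cat + flag + size, data=d, method="anova",
                         control=rpart.control(cp=0.01, minsplit=5, maxdepth=8,
                                               minbucket=1, xval=0))
            fr <- fit$frame
            leaves <- fr[fr$var == "<leaf>", c("n","yval")]
            leaves <- leaves[order(leaves$yval),]
            write.csv(leaves, "{tmp_path}/leaves.csv", row.names=FALSE)
            """
        )
        (tmp_path / "s.R").write_text(script)
        subprocess.run(
            ["Rscript", str(tmp_path / "s.R")], check=True, capture_output=True
        )
        rl = pd.read_csv(tmp_path / "leaves.csv")
        ours_leaves = sorted(
            (nd.prediction, nd.n) for nd in ours.nodes_.values() if nd.is_leaf
        )
        theirs = sorted(zip(rl["yval"], rl["n"]))
        assert len(ours_leaves) == len(theirs)
        for (m1, n1), (m2, n2) in zip(ours_leaves, theirs):
            assert n1 == n2
            assert m1 == pytest.approx(m2, rel=1e-6)
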