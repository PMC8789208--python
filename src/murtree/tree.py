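"""Recursive-partitioning regression trees for categorical predictors.

This is a from-scratch CART engine for a continuous outcome (a rate per
10,000 attendees) over dichotomous/categorical predictors only — continuous
predictors are categorized a priori upstream, never dichotomized by the tree.

Splitting.  Each node is split on the binary partition of one variable's
levels that maximizes the reduction in the within-node sum of squared errors,
``SSE(parent) - SSE(left) - SSE(right)``.  Nominal variables are searched by
exhaustive enumeration of all proper non-empty level subsets (at most 12
levels; six occur in practice); ordered variables only admit order-respecting
cuts.  A split is kept when its reduction is at least ``cp`` times the root
SSE, the node holds at least ``minsplit`` observations, its depth is below
``maxdepth`` and both children hold at least ``minbucket`` observations.

Surrogates.  At every split, substitute splits on the other variables are
ranked by agreement (the fraction of node cases they send the same way as the
primary split, among cases with both variables observed); surrogates that do
not beat the majority-direction baseline are discarded.  Prediction routes an
unseen or missing value through the first applicable surrogate, else the
majority direction.

Model selection.  ``cross_validate`` computes the cross-validated relative
error (xerror): held-out squared errors from trees grown per training fold,
scaled by the full-data root SSE.  ``CartGridSearch`` evaluates every
(minsplit, maxdepth) combination — 16 x 8 = 128 under the default ranges —
and selects the minimal-xerror tree (ties: fewer leaves, then the smaller
parameter pair).  The one-standard-error rule is deliberately not used.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin

from .errors import RoutingError, UndefinedStatisticError

_EPS = 1e-12
_MAX_EXHAUSTIVE_LEVELS = 12


# ---------------------------------------------------------------------------
# model structures


@dataclass
class SplitSpec:
    """A binary partition of one variable's levels.

    ``left_levels``/``right_levels`` record the level labels sent each way at
    fit time; ``agreement`` is 1.0 for a primary split and, for a surrogate,
    the fraction of node cases it sends the same way as the primary split.
    """

    variable: str
    left_levels: tuple[str, ...]
    right_levels: tuple[str, ...]
    sse_reduction: float
    agreement: float = 1.0


@dataclass
class TreeNode:
    """One node, heap-numbered: root 1, children of k are 2k and 2k + 1."""

    node_id: int
    n: int
    prediction: float
    sd: float
    sse: float
    depth: int
    split: SplitSpec | None = None
    surrogates: list[SplitSpec] = field(default_factory=list)
    majority_left: bool = True

    @property
    def is_leaf(self) -> bool:
        return self.split is None


@dataclass
class CrossValResult:
    """10-fold (by default) cross-validated relative error."""

    xerror: float
    xstd: float
    fold_assignment: np.ndarray


@dataclass(frozen=True)
class FitConfig:
    """Tree-growing and cross-validation hyperparameters."""

    cp: float = 0.01
    minsplit: int = 5
    maxdepth: int = 8
    minbucket: int = 1
    n_folds: int = 10
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.cp <= 1:
            raise ValueError("cp must be in [0, 1]")
        if self.minsplit < 2 or self.maxdepth < 1 or self.n_folds < 2:
            raise ValueError("invalid FitConfig")


# ---------------------------------------------------------------------------
# split search


def _partition_reductions(s, c, masks_bits):
    """SSE reduction for each candidate left-subset of present levels.

    ``s``/``c`` are per-level outcome sums and counts; ``masks_bits`` is a
    (n_masks, p) boolean matrix selecting the left levels.  Uses the identity
    reduction = S_L^2/n_L + S_R^2/n_R - S^2/n.
    """
    S, N = s.sum(), c.sum()
    sl = masks_bits @ s
    cl = masks_bits @ c
    return sl**2 / cl + (S - sl) ** 2 / (N - cl) - S**2 / N


def _nominal_masks(p: int) -> np.ndarray:
    """All proper non-empty left-subsets containing level 0 (each partition
    once), as a (2**(p-1) - 1, p) boolean matrix."""
    masks = np.arange(1, 2**p, 2)  # odd -> bit 0 set
    masks = masks[masks != 2**p - 1]
    return (masks[:, None] >> np.arange(p)) & 1 > 0


def _ordered_masks(p: int) -> np.ndarray:
    return np.tril(np.ones((p - 1, p), dtype=bool), k=0)


def _best_split_codes(codes, y, levels, ordered, method="exhaustive"):
    """Best binary partition for one variable at one node, or None.

    ``codes`` are level indices (-1 = missing) for the node's observations.
    ``method="mean_sort"`` uses the classic CART shortcut for nominal
    variables (sort levels by node mean, scan contiguous cuts); it must agree
    with the exhaustive search and exists as a verified optimization.
    """
    obs = codes >= 0
    if obs.sum() < 2:
        return None
    k = len(levels)
    c = np.bincount(codes[obs], minlength=k).astype(float)
    s = np.bincount(codes[obs], weights=y[obs], minlength=k)
    present = np.flatnonzero(c > 0)
    p = len(present)
    if p < 2:
        return None
    sp, cp_ = s[present], c[present]

    if ordered:
        bits = _ordered_masks(p)
    elif method == "mean_sort":
        order = np.argsort(sp / cp_, kind="stable")
        sp, cp_, present = sp[order], cp_[order], present[order]
        bits = _ordered_masks(p)
    else:
        if p > _MAX_EXHAUSTIVE_LEVELS:
            raise NotImplementedError(f"{p} levels exceed exhaustive search bound")
        bits = _nominal_masks(p)

    red = _partition_reductions(sp, cp_, bits)
    best = red.max()
    if best <= _EPS:
        return None
    # among numerically tied partitions prefer the lexicographically smallest
    # left level set (determinism; the data never disambiguates exact ties)
    tied = np.flatnonzero(red >= best - _EPS * max(1.0, best))
    left_codes = min(tuple(sorted(present[bits[i]])) for i in tied)
    right_codes = tuple(l for l in sorted(present) if l not in left_codes)
    return SplitSpec(
        variable="",
        left_levels=tuple(levels[i] for i in left_codes),
        right_levels=tuple(levels[i] for i in right_codes),
        sse_reduction=float(best),
    )


def best_split(
    x: Sequence,
    y: Sequence[float],
    ordered_levels: Sequence[str] | None = None,
    method: str = "exhaustive",
) -> SplitSpec | None:
    """Best binary partition of ``x``'s levels for outcome ``y``.

    ``ordered_levels`` restricts the search to order-respecting cuts along the
    given level order.  Returns None when no partition reduces the SSE (e.g.
    constant outcome).
    """
    x = np.asarray(x, dtype=object)
    y = np.asarray(y, dtype=float)
    if ordered_levels is not None:
        levels = tuple(ordered_levels)
    else:
        levels = tuple(sorted({v for v in x if not _is_missing(v)}))
    lut = {lv: i for i, lv in enumerate(levels)}
    codes = np.array([lut.get(v, -1) if not _is_missing(v) else -1 for v in x])
    return _best_split_codes(codes, y, levels, ordered=ordered_levels is not None, method=method)


def _is_missing(v) -> bool:
    return v is None or (isinstance(v, float) and np.isnan(v))


# ---------------------------------------------------------------------------
# surrogate search


def _surrogates_for_split(columns, idx, went_left, primary_obs, primary_var):
    """Rank substitute splits by agreement with the primary direction.

    Only cases with both the primary and the candidate variable observed are
    compared; surrogates not beating the majority-direction baseline are
    dropped (they would add nothing over blind majority routing).
    """
    out = []
    for col in columns:
        if col.name == primary_var:
            continue
        codes = col.codes[idx]
        mask = (codes >= 0) & primary_obs
        total = int(mask.sum())
        if total == 0:
            continue
        nl_cnt = int(went_left[mask].sum())
        baseline = max(nl_cnt, total - nl_cnt) / total
        k = len(col.levels)
        nl = np.bincount(codes[mask & went_left], minlength=k)
        nr = np.bincount(codes[mask & ~went_left], minlength=k)
        present = np.flatnonzero(nl + nr > 0)
        if len(present) < 2:
            continue
        if col.ordered:
            best_agree, best_left = -1.0, None
            cum_l = np.cumsum(nl[present])
            cum_r = np.cumsum(nr[present])
            for j in range(1, len(present)):
                # prefix goes left ...
                a = (cum_l[j - 1] + (cum_r[-1] - cum_r[j - 1])) / total
                if a > best_agree:
                    best_agree, best_left = a, tuple(present[:j])
                # ... or prefix goes right
                a = (cum_r[j - 1] + (cum_l[-1] - cum_l[j - 1])) / total
                if a > best_agree:
                    best_agree, best_left = a, tuple(present[j:])
        else:
            left = tuple(l for l in present if nl[l] > nr[l])
            if not left or len(left) == len(present):
                continue
            best_left = left
            best_agree = (nl[list(left)].sum() + nr[[l for l in present if l not in left]].sum()) / total
        if best_left is None or best_agree <= baseline + _EPS:
            continue
        right = tuple(l for l in present if l not in best_left)
        out.append(
            SplitSpec(
                variable=col.name,
                left_levels=tuple(col.levels[i] for i in sorted(best_left)),
                right_levels=tuple(col.levels[i] for i in sorted(right)),
                sse_reduction=0.0,  # filled by caller with the primary reduction
                agreement=float(best_agree),
            )
        )
    out.sort(key=lambda s: -s.agreement)
    return out


# ---------------------------------------------------------------------------
# the estimator


@dataclass
class _Column:
    name: str
    levels: tuple[str, ...]
    ordered: bool
    codes: np.ndarray  # int, -1 = missing


def _encode_columns(X: pd.DataFrame, ordered: Mapping[str, Sequence[str]] | None):
    ordered = ordered or {}
    cols = []
    for name in X.columns:
        vals = X[name].to_numpy(dtype=object)
        if name in ordered:
            levels = tuple(ordered[name])
            is_ordered = True
        else:
            levels = tuple(sorted({str(v) for v in vals if not _is_missing(v)}))
            is_ordered = False
        lut = {lv: i for i, lv in enumerate(levels)}
        codes = np.array(
            [-1 if _is_missing(v) else lut.get(str(v), -1) for v in vals], dtype=np.int64
        )
        cols.append(_Column(name, levels, is_ordered, codes))
    return cols


class CartRegressor(BaseEstimator, RegressorMixin):
    """Regression tree over categorical predictors (anova splitting).

    Parameters
    ----------
    cp : float
        Minimum SSE reduction for a split, as a fraction of the root SSE.
    minsplit : int
        Minimum node size for a split to be attempted.
    maxdepth : int
        Maximum node depth (root = 0).
    minbucket : int
        Minimum child size.
    ordered : mapping or None
        ``{column: level order}`` for predictors whose split search must
        respect an order; all other columns are treated as nominal.

    Attributes (after ``fit``)
    --------------------------
    nodes_ : dict[int, TreeNode]
        Heap-numbered tree nodes.
    rel_error_ : float
        SSE(tree)/SSE(root); NaN when the outcome is constant.
    r2_train_ : float
        1 - rel_error_, the squared observed/predicted correlation on the
        training data.
    """

    def __init__(self, cp=0.01, minsplit=5, maxdepth=8, minbucket=1, ordered=None):
        self.cp = cp
        self.minsplit = minsplit
        self.maxdepth = maxdepth
        self.minbucket = minbucket
        self.ordered = ordered

    # -- fitting ------------------------------------------------------------

    def fit(self, X: pd.DataFrame, y):
        y = np.asarray(y, dtype=float)
        if len(X) == 0:
            raise ValueError("empty training data")
        if len(X) != len(y):
            raise ValueError("X and y length mismatch")
        FitConfig(cp=self.cp, minsplit=self.minsplit, maxdepth=self.maxdepth)
        cols = _encode_columns(pd.DataFrame(X), self.ordered)
        self.feature_names_in_ = tuple(c.name for c in cols)
        self.levels_ = {c.name: c.levels for c in cols}
        self.ordered_vars_ = tuple(c.name for c in cols if c.ordered)
        self.nodes_ = {}
        self.sse_root_ = float(((y - y.mean()) ** 2).sum())
        self._grow(cols, y, np.arange(len(y)), node_id=1, depth=0)
        sse_leaves = sum(nd.sse for nd in self.nodes_.values() if nd.is_leaf)
        if self.sse_root_ > _EPS:
            self.rel_error_ = sse_leaves / self.sse_root_
        else:
            self.rel_error_ = float("nan")
        self.r2_train_ = 1.0 - self.rel_error_
        self.n_terminal_ = sum(nd.is_leaf for nd in self.nodes_.values())
        return self

    def _grow(self, cols, y, idx, node_id, depth):
        yn = y[idx]
        n = len(idx)
        mean = float(yn.mean())
        sse = float(((yn - mean) ** 2).sum())
        node = TreeNode(
            node_id=node_id,
            n=n,
            prediction=mean,
            sd=float(yn.std(ddof=1)) if n > 1 else 0.0,
            sse=sse,
            depth=depth,
        )
        self.nodes_[node_id] = node
        if n < self.minsplit or depth >= self.maxdepth or sse <= _EPS:
            return
        best, best_col = None, None
        for col in cols:
            spec = _best_split_codes(col.codes[idx], y[idx], col.levels, col.ordered)
            if spec is None:
                continue
            spec.variable = col.name
            if best is None or spec.sse_reduction > best.sse_reduction + _EPS:
                best, best_col = spec, col
        if best is None or best.sse_reduction < self.cp * self.sse_root_ - _EPS:
            return
        codes = best_col.codes[idx]
        left_set = {best_col.levels.index(lv) for lv in best.left_levels}
        obs = codes >= 0
        went_left = np.isin(codes, list(left_set))
        node.surrogates = _surrogates_for_split(cols, idx, went_left, obs, best.variable)
        for s in node.surrogates:
            s.sse_reduction = best.sse_reduction
        # cases with the primary variable missing route via surrogate/majority
        nl_obs = int(went_left[obs].sum())
        node.majority_left = nl_obs >= int(obs.sum()) - nl_obs
        if (~obs).any():
            row_vals = {c.name: c.codes[idx] for c in cols}
            for i in np.flatnonzero(~obs):
                went_left[i] = self._route_missing(node, cols, row_vals, i)
        n_left = int(went_left.sum())
        if n_left < self.minbucket or n - n_left < self.minbucket or n_left in (0, n):
            node.surrogates = []
            return
        node.split = best
        self._grow(cols, y, idx[went_left], 2 * node_id, depth + 1)
        self._grow(cols, y, idx[~went_left], 2 * node_id + 1, depth + 1)

    @staticmethod
    def _route_missing(node, cols, row_vals, i):
        by_name = {c.name: c for c in cols}
        for s in node.surrogates:
            col = by_name[s.variable]
            code = row_vals[s.variable][i]
            if code >= 0:
                label = col.levels[code]
                if label in s.left_levels:
                    return True
                if label in s.right_levels:
                    return False
        return node.majority_left

    # -- prediction ---------------------------------------------------------

    def _route_value(self, node: TreeNode, row: Mapping) -> bool:
        """True = left.  Applies primary, then surrogates, then majority."""
        for spec in [node.split, *node.surrogates]:
            if spec.variable not in row:
                raise RoutingError(f"variable {spec.variable!r} absent from input")
            v = row[spec.variable]
            if _is_missing(v):
                continue
            v = str(v)
            if v in spec.left_levels:
                return True
            if v in spec.right_levels:
                return False
        return node.majority_left

    def _leaf_for_row(self, row: Mapping, stop=None) -> TreeNode:
        node = self.nodes_[1]
        while not node.is_leaf and not (stop is not None and stop(node)):
            node = self.nodes_[2 * node.node_id + (0 if self._route_value(node, row) else 1)]
        return node

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        X = pd.DataFrame(X)
        rows = X.to_dict("records")
        return np.array([self._leaf_for_row(r).prediction for r in rows])

    def predict_node(self, X: pd.DataFrame) -> np.ndarray:
        """Terminal node id for each observation."""
        rows = pd.DataFrame(X).to_dict("records")
        return np.array([self._leaf_for_row(r).node_id for r in rows])

    def _full_path(self, row: Mapping) -> list[TreeNode]:
        node = self.nodes_[1]
        path = [node]
        while not node.is_leaf:
            node = self.nodes_[2 * node.node_id + (0 if self._route_value(node, row) else 1)]
            path.append(node)
        return path

    # -- diagnostics --------------------------------------------------------

    def variable_importance(self) -> pd.Series:
        """Percent importance per variable: primary-split SSE reductions plus
        agreement-weighted reductions for surrogate roles; sums to 100."""
        raw: dict[str, float] = {}
        for nd in self.nodes_.values():
            if nd.split is None:
                continue
            raw[nd.split.variable] = raw.get(nd.split.variable, 0.0) + nd.split.sse_reduction
            for s in nd.surrogates:
                raw[s.variable] = raw.get(s.variable, 0.0) + s.agreement * s.sse_reduction
        if not raw:
            return pd.Series(dtype=float)
        out = pd.Series(raw, dtype=float)
        return out / out.sum() * 100.0


def rel_error(tree: CartRegressor) -> float:
    """SSE(tree)/SSE(root) on the training data."""
    if not np.isfinite(tree.rel_error_):
        raise UndefinedStatisticError("rel error undefined: zero outcome variance")
    return float(tree.rel_error_)


def r_squared_train(tree: CartRegressor) -> float:
    """1 - rel error; equals the squared observed/predicted correlation on
    the training data."""
    return 1.0 - rel_error(tree)


# ---------------------------------------------------------------------------
# cross-validation and the hyperparameter grid


def _fold_assignment(n: int, n_folds: int, seed: int) -> np.ndarray:
    """Balanced fold labels (sizes within +-1) from a seeded permutation."""
    rng = np.random.default_rng(seed)
    folds = np.empty(n, dtype=np.int64)
    folds[rng.permutation(n)] = np.arange(n) % n_folds
    return folds


def cross_validate(
    X: pd.DataFrame, y, config: FitConfig = FitConfig(), ordered=None
) -> CrossValResult:
    """Cross-validated relative error for one fixed configuration.

    Trees are regrown on each training fold with the same configuration and
    evaluated on the held-out fold; xerror scales the pooled held-out squared
    error by the full-data root SSE.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < config.n_folds:
        raise ValueError("need at least n_folds observations")
    sse_root = float(((y - y.mean()) ** 2).sum())
    if sse_root <= _EPS:
        raise UndefinedStatisticError("xerror undefined: zero outcome variance")
    folds = _fold_assignment(n, config.n_folds, config.seed)
    X = pd.DataFrame(X).reset_index(drop=True)
    errors = np.empty(n)
    for f in range(config.n_folds):
        test = folds == f
        est = CartRegressor(
            cp=config.cp,
            minsplit=config.minsplit,
            maxdepth=config.maxdepth,
            minbucket=config.minbucket,
        )
        est.ordered = ordered
        est.fit(X[~test], y[~test])
        errors[test] = (y[test] - est.predict(X[test])) ** 2
    xerror = errors.sum() / sse_root
    xstd = float(np.sqrt(errors.var() * n) / sse_root)
    return CrossValResult(xerror=float(xerror), xstd=xstd, fold_assignment=folds)


class CartGridSearch(BaseEstimator):
    """Minimal-xerror selection over the (minsplit, maxdepth) grid.

    The default ranges (minsplit 5..20, maxdepth 8..15) enumerate 128
    configurations.  Because the greedy split at a node depends only on that
    node's data and cp/minbucket are fixed across the grid, one maximal tree
    per CV fold (grown at the loosest constraints) yields every
    configuration's tree by truncation; equivalence with direct growth is
    covered by the test suite.  Fold assignment is shared across the grid.

    Attributes: ``best_estimator_`` (with ``xerror_``, ``xstd_``,
    ``fold_assignment_`` attached), ``best_params_``, ``results_`` (one row
    per configuration).
    """

    def __init__(
        self,
        minsplit_range=range(5, 21),
        maxdepth_range=range(8, 16),
        cp=0.01,
        minbucket=1,
        n_folds=10,
        seed=0,
        ordered=None,
    ):
        self.minsplit_range = minsplit_range
        self.maxdepth_range = maxdepth_range
        self.cp = cp
        self.minbucket = minbucket
        self.n_folds = n_folds
        self.seed = seed
        self.ordered = ordered

    def fit(self, X: pd.DataFrame, y):
        ms_list = list(self.minsplit_range)
        md_list = list(self.maxdepth_range)
        if not ms_list or not md_list:
            raise ValueError("hyperparameter ranges must be non-empty")
        y = np.asarray(y, dtype=float)
        X = pd.DataFrame(X).reset_index(drop=True)
        n = len(y)
        sse_root = float(((y - y.mean()) ** 2).sum())
        if sse_root <= _EPS:
            raise UndefinedStatisticError("xerror undefined: zero outcome variance")
        grid = list(itertools.product(ms_list, md_list))
        folds = _fold_assignment(n, self.n_folds, self.seed)

        def maximal(mask):
            est = CartRegressor(
                cp=self.cp,
                minsplit=min(ms_list),
                maxdepth=max(md_list),
                minbucket=self.minbucket,
                ordered=self.ordered,
            )
            return est.fit(X[mask], y[mask])

        # held-out squared error per observation per configuration
        errors = np.empty((n, len(grid)))
        for f in range(self.n_folds):
            test = folds == f
            est = maximal(~test)
            rows = X[test].to_dict("records")
            for i, row in zip(np.flatnonzero(test), rows):
                path = est._full_path(row)
                for g, (ms, md) in enumerate(grid):
                    pred = _truncated_prediction(path, ms, md)
                    errors[i, g] = (y[i] - pred) ** 2

        full = maximal(np.ones(n, dtype=bool))
        xerr = errors.sum(axis=0) / sse_root
        xstd = np.sqrt(errors.var(axis=0) * n) / sse_root
        leaves = [_truncated_leaf_count(full, ms, md) for ms, md in grid]
        self.results_ = pd.DataFrame(
            {
                "minsplit": [g[0] for g in grid],
                "maxdepth": [g[1] for g in grid],
                "xerror": xerr,
                "xstd": xstd,
                "n_leaves": leaves,
            }
        )
        order = sorted(
            range(len(grid)), key=lambda g: (xerr[g], leaves[g], grid[g][0], grid[g][1])
        )
        best = order[0]
        ms, md = grid[best]
        self.best_params_ = {"minsplit": ms, "maxdepth": md, "cp": self.cp}
        est = CartRegressor(
            cp=self.cp, minsplit=ms, maxdepth=md, minbucket=self.minbucket, ordered=self.ordered
        ).fit(X, y)
        est.xerror_ = float(xerr[best])
        est.xstd_ = float(xstd[best])
        est.fold_assignment_ = folds
        self.best_estimator_ = est
        return self

    def predict(self, X):
        return self.best_estimator_.predict(X)


def _config_terminal(node: TreeNode, minsplit: int, maxdepth: int) -> bool:
    return node.split is None or node.n < minsplit or node.depth >= maxdepth


def _truncated_prediction(path: list[TreeNode], minsplit: int, maxdepth: int) -> float:
    for node in path:
        if _config_terminal(node, minsplit, maxdepth):
            return node.prediction
    return path[-1].prediction


def _truncated_leaf_count(tree: CartRegressor, minsplit: int, maxdepth: int) -> int:
    def count(node_id):
        node = tree.nodes_[node_id]
        if _config_terminal(node, minsplit, maxdepth):
            return 1
        return count(2 * node_id) + count(2 * node_id + 1)

    return count(1)


def grid_search(
    X: pd.DataFrame,
    y,
    minsplit_range=range(5, 21),
    maxdepth_range=range(8, 16),
    cp=0.01,
    n_folds=10,
    seed=0,
    ordered=None,
) -> tuple[CartRegressor, pd.DataFrame]:
    """Functional wrapper: returns (selected tree, grid report)."""
    gs = CartGridSearch(
        minsplit_range=minsplit_range,
        maxdepth_range=maxdepth_range,
        cp=cp,
        n_folds=n_folds,
        seed=seed,
        ordered=ordered,
    ).fit(X, y)
    return gs.best_estimator_, gs.results_


def grow_tree(X: pd.DataFrame, y, config: FitConfig = FitConfig(), ordered=None) -> CartRegressor:
    """Grow a single tree at a fixed configuration."""
    return CartRegressor(
        cp=config.cp,
        minsplit=config.minsplit,
        maxdepth=config.maxdepth,
        minbucket=config.minbucket,
        ordered=ordered,
    ).fit(X, y)


# ---------------------------------------------------------------------------
# serialization and rendering


def tree_to_dict(tree: CartRegressor) -> dict:
    def spec_dict(s: SplitSpec | None):
        return None if s is None else asdict(s)

    params = tree.get_params()
    if params.get("ordered"):
        params["ordered"] = {k: list(v) for k, v in params["ordered"].items()}
    return {
        "params": params,
        "feature_names": list(tree.feature_names_in_),
        "levels": {k: list(v) for k, v in tree.levels_.items()},
        "ordered_vars": list(tree.ordered_vars_),
        "sse_root": tree.sse_root_,
        "rel_error": tree.rel_error_,
        "xerror": getattr(tree, "xerror_", None),
        "xstd": getattr(tree, "xstd_", None),
        "nodes": [
            {
                "node_id": nd.node_id,
                "n": nd.n,
                "prediction": nd.prediction,
                "sd": nd.sd,
                "sse": nd.sse,
                "depth": nd.depth,
                "majority_left": nd.majority_left,
                "split": spec_dict(nd.split),
                "surrogates": [spec_dict(s) for s in nd.surrogates],
            }
            for nd in sorted(tree.nodes_.values(), key=lambda nd: nd.node_id)
        ],
    }


def tree_from_dict(d: dict) -> CartRegressor:
    tree = CartRegressor(**dict(d["params"]))
    tree.feature_names_in_ = tuple(d["feature_names"])
    tree.levels_ = {k: tuple(v) for k, v in d["levels"].items()}
    tree.ordered_vars_ = tuple(d["ordered_vars"])
    tree.sse_root_ = d["sse_root"]
    tree.rel_error_ = d["rel_error"] if d["rel_error"] is not None else float("nan")
    tree.r2_train_ = 1.0 - tree.rel_error_
    if d.get("xerror") is not None:
        tree.xerror_ = d["xerror"]
        tree.xstd_ = d.get("xstd")

    def spec(s):
        if s is None:
            return None
        return SplitSpec(
            variable=s["variable"],
            left_levels=tuple(s["left_levels"]),
            right_levels=tuple(s["right_levels"]),
            sse_reduction=s["sse_reduction"],
            agreement=s["agreement"],
        )

    tree.nodes_ = {
        nd["node_id"]: TreeNode(
            node_id=nd["node_id"],
            n=nd["n"],
            prediction=nd["prediction"],
            sd=nd["sd"],
            sse=nd["sse"],
            depth=nd["depth"],
            split=spec(nd["split"]),
            surrogates=[spec(s) for s in nd["surrogates"]],
            majority_left=nd["majority_left"],
        )
        for nd in d["nodes"]
    }
    tree.n_terminal_ = sum(nd.is_leaf for nd in tree.nodes_.values())
    return tree


def save_tree(tree: CartRegressor, path: str | Path) -> None:
    Path(path).write_text(json.dumps(tree_to_dict(tree), indent=1))


def load_tree(path: str | Path) -> CartRegressor:
    return tree_from_dict(json.loads(Path(path).read_text()))


def render_text(tree: CartRegressor) -> str:
    """Plain-text rendering: split variable and level partition per internal
    node, mean +- sd and n per leaf."""
    lines = []

    def walk(node_id, indent):
        nd = tree.nodes_[node_id]
        pad = "  " * indent
        if nd.is_leaf:
            lines.append(
                f"{pad}leaf {nd.node_id}: mean={nd.prediction:.1f} sd={nd.sd:.1f} n={nd.n}"
            )
        else:
            s = nd.split
            lines.append(
                f"{pad}node {nd.node_id}: {s.variable} in "
                f"{{{', '.join(s.left_levels)}}} (n={nd.n}, mean={nd.prediction:.1f})"
            )
            walk(2 * node_id, indent + 1)
            walk(2 * node_id + 1, indent + 1)

    walk(1, 0)
    return "\n".join(lines)
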