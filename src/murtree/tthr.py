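"""Cascaded transfer-to-hospital-rate model.

TTHR is predicted with a second regression tree over the same nine base
predictors plus three cascade features: the terminal node of the fitted
(unadjusted) PPR tree — entered as a categorical node label, mirroring how
the TTHR tree's splits are reported — and binned distance and travel time to
the nearest hospital.  Predicted rather than observed PPR is used so the
model reflects forecasting an upcoming event.  TTHR predictions are never
temperature-adjusted.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .data import ORDERED_PREDICTORS, PPR_PREDICTORS
from .tree import CartGridSearch, CartRegressor

#: default hospital-proximity bins (km and minutes); config-overridable
DISTANCE_EDGES = (5.0, 15.0)
DISTANCE_CLASSES = ("d_le5km", "d_5_15km", "d_gt15km")
TIME_EDGES = (10.0, 20.0)
TIME_CLASSES = ("t_le10min", "t_10_20min", "t_gt20min")

TTHR_PREDICTORS = PPR_PREDICTORS + (
    "ppr_node",
    "hospital_distance_class",
    "hospital_time_class",
)

TTHR_ORDERED = dict(
    ORDERED_PREDICTORS,
    hospital_distance_class=DISTANCE_CLASSES,
    hospital_time_class=TIME_CLASSES,
)


def _bin(values, edges, classes) -> pd.Series:
    idx = np.searchsorted(edges, np.asarray(values, dtype=float), side="left")
    index = values.index if isinstance(values, pd.Series) else None
    return pd.Series([classes[i] for i in idx], index=index)


def classify_hospital_distance(km) -> pd.Series:
    """<=5, 5–15, >15 km."""
    return _bin(km, DISTANCE_EDGES, DISTANCE_CLASSES)


def classify_hospital_time(minutes) -> pd.Series:
    """<=10, 10–20, >20 minutes."""
    return _bin(minutes, TIME_EDGES, TIME_CLASSES)


def build_tthr_features(
    events: pd.DataFrame, ppr_tree: CartRegressor
) -> pd.DataFrame:
    """The 12 candidate TTHR predictors, plus a ``ppr_pred`` column.

    ``ppr_node`` is the PPR tree's terminal node id for each event (as label
    ``node_<id>``); ``ppr_pred`` carries that node's mean PPR for reference
    and is not itself a predictor.
    """
    feats = events[list(PPR_PREDICTORS)].copy()
    node_ids = ppr_tree.predict_node(events[list(ppr_tree.feature_names_in_)])
    feats["ppr_node"] = [f"node_{i}" for i in node_ids]
    feats["hospital_distance_class"] = classify_hospital_distance(
        events["hospital_distance_km"]
    ).to_numpy()
    feats["hospital_time_class"] = classify_hospital_time(
        events["hospital_time_min"]
    ).to_numpy()
    feats["ppr_pred"] = [ppr_tree.nodes_[i].prediction for i in node_ids]
    return feats


class TthrModel:
    """Grid-searched regression tree for TTHR, cascaded on a fitted PPR tree.

    The hyperparameter protocol is identical to the PPR model (cp 0.01,
    minsplit 5..20 x maxdepth 8..15, 10-fold CV, minimal xerror).
    """

    def __init__(
        self,
        minsplit_range=range(5, 21),
        maxdepth_range=range(8, 16),
        cp=0.01,
        n_folds=10,
        seed=0,
    ):
        self.minsplit_range = minsplit_range
        self.maxdepth_range = maxdepth_range
        self.cp = cp
        self.n_folds = n_folds
        self.seed = seed

    def fit(self, events: pd.DataFrame, y, ppr_tree: CartRegressor) -> "TthrModel":
        feats = build_tthr_features(events, ppr_tree)
        self.ppr_tree_ = ppr_tree
        y = np.asarray(y, dtype=float)
        if np.ptp(y) == 0:
            # constant outcome: cross-validated error is undefined and the
            # tree is necessarily root-only
            self.tree_ = CartRegressor(cp=self.cp, ordered=TTHR_ORDERED).fit(
                feats[list(TTHR_PREDICTORS)], y
            )
            self.results_ = None
            self.best_params_ = None
            return self
        gs = CartGridSearch(
            minsplit_range=self.minsplit_range,
            maxdepth_range=self.maxdepth_range,
            cp=self.cp,
            n_folds=self.n_folds,
            seed=self.seed,
            ordered=TTHR_ORDERED,
        ).fit(feats[list(TTHR_PREDICTORS)], np.asarray(y, dtype=float))
        self.tree_ = gs.best_estimator_
        self.results_ = gs.results_
        self.best_params_ = gs.best_params_
        return self

    def predict(self, events: pd.DataFrame) -> np.ndarray:
        feats = build_tthr_features(events, self.ppr_tree_)
        return self.tree_.predict(feats[list(TTHR_PREDICTORS)])


def fit_tthr(
    events: pd.DataFrame, tthr: np.ndarray, ppr_tree: CartRegressor, **kwargs
) -> TthrModel:
    """Functional wrapper over :class:`TthrModel`."""
    return TthrModel(**kwargs).fit(events, tthr, ppr_tree)
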