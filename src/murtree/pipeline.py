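"""End-to-end model development and the serializable model bundle.

``develop_model`` runs the full protocol on an aggregated event table:
grid-searched PPR tree (cp 0.01, minsplit 5..20 x maxdepth 8..15, 10-fold
CV, minimal xerror), temperature-adjustment derivation from reference-event
daily data, the TTHR association check that justifies never adjusting TTHR,
and the cascaded TTHR tree.  The resulting :class:`ModelBundle` serializes
to JSON so validation runs off the stored model alone.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .data import ORDERED_PREDICTORS, PPR_PREDICTORS
from .temperature import (
    AdjustmentParams,
    TemperatureAdjustment,
    adjust_ppr,
    check_temperature_association,
    event_temperature,
)
from .tree import CartGridSearch, CartRegressor, tree_from_dict, tree_to_dict
from .tthr import TthrModel


@dataclass
class ModelBundle:
    """Fitted PPR/TTHR trees plus temperature-adjustment coefficients."""

    ppr_tree: CartRegressor
    tthr_model: TthrModel | None = None
    adj_t_av: AdjustmentParams | None = None
    adj_t_max: AdjustmentParams | None = None
    tthr_temp_verdicts: dict | None = None  # {"t_av": bool, "t_max": bool}
    reference_event_id: str | None = None

    def adjustment(self, which: str) -> AdjustmentParams | None:
        return {"t_av": self.adj_t_av, "t_max": self.adj_t_max}[which]

    def predict_ppr(
        self,
        events: pd.DataFrame,
        temperatures: pd.DataFrame | None = None,
        variant: str = "crude",
    ) -> np.ndarray:
        """Tree predictions, optionally temperature-adjusted.

        ``variant`` is "crude", "t_av" or "t_max"; adjusted variants apply
        only to outdoor June–September events, all others pass through.
        """
        base = self.ppr_tree.predict(events[list(PPR_PREDICTORS)])
        if variant == "crude":
            return base
        params = self.adjustment(variant)
        if params is None:
            raise ValueError(f"no {variant} adjustment fitted")
        rows = events.to_dict("records")
        out = np.empty(len(rows))
        for i, (p, ev) in enumerate(zip(base, rows)):
            t = (
                event_temperature(ev, temperatures, which=variant)
                if temperatures is not None
                else float("nan")
            )
            out[i] = adjust_ppr(p, t, params, ev)
        return out

    def predict_tthr(self, events: pd.DataFrame) -> np.ndarray:
        """Cascade prediction; never temperature-adjusted."""
        if self.tthr_model is None:
            raise ValueError("no TTHR model fitted")
        return self.tthr_model.predict(events)

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        def adj(a):
            return None if a is None else {
                "slope_b": a.slope_b,
                "pivot_t": a.pivot_t,
                "reference_ppr": a.reference_ppr,
                "which": a.which,
            }

        return {
            "ppr_tree": tree_to_dict(self.ppr_tree),
            "tthr_tree": None
            if self.tthr_model is None
            else tree_to_dict(self.tthr_model.tree_),
            "adj_t_av": adj(self.adj_t_av),
            "adj_t_max": adj(self.adj_t_max),
            "tthr_temp_verdicts": self.tthr_temp_verdicts,
            "reference_event_id": self.reference_event_id,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelBundle":
        def adj(a):
            return None if a is None else AdjustmentParams(**a)

        ppr_tree = tree_from_dict(d["ppr_tree"])
        tthr_model = None
        if d["tthr_tree"] is not None:
            tthr_model = TthrModel.__new__(TthrModel)
            tthr_model.tree_ = tree_from_dict(d["tthr_tree"])
            tthr_model.ppr_tree_ = ppr_tree
        return cls(
            ppr_tree=ppr_tree,
            tthr_model=tthr_model,
            adj_t_av=adj(d["adj_t_av"]),
            adj_t_max=adj(d["adj_t_max"]),
            tthr_temp_verdicts=d["tthr_temp_verdicts"],
            reference_event_id=d["reference_event_id"],
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "ModelBundle":
        return cls.from_dict(json.loads(Path(path).read_text()))


def develop_model(
    aggregated: pd.DataFrame,
    reference_daily: pd.DataFrame | None = None,
    reference_event: Mapping | None = None,
    fit_tthr: bool = True,
    minsplit_range=range(5, 21),
    maxdepth_range=range(8, 16),
    cp: float = 0.01,
    n_folds: int = 10,
    seed: int = 0,
) -> ModelBundle:
    """Full development protocol on a categorized aggregated-event table.

    ``reference_daily`` (columns ``t_av``, ``t_max``, ``ppr_day`` and
    optionally ``tthr_day``) drives the temperature adjustment; the pivot is
    anchored at the tree-predicted PPR of ``reference_event`` (a row of the
    aggregated table).  Without reference data the bundle is crude-only.
    """
    gs = CartGridSearch(
        minsplit_range=minsplit_range,
        maxdepth_range=maxdepth_range,
        cp=cp,
        n_folds=n_folds,
        seed=seed,
        ordered=dict(ORDERED_PREDICTORS),
    ).fit(aggregated[list(PPR_PREDICTORS)], aggregated["ppr"].to_numpy())
    ppr_tree = gs.best_estimator_
    ppr_tree.grid_results_ = gs.results_

    adj_t_av = adj_t_max = None
    verdicts = None
    ref_id = None
    if reference_daily is not None and reference_event is not None:
        ref_df = pd.DataFrame([dict(reference_event)])
        reference_ppr = float(ppr_tree.predict(ref_df[list(PPR_PREDICTORS)])[0])
        ref_id = reference_event.get("event_id")
        adj_t_av = TemperatureAdjustment("t_av").fit(reference_daily, reference_ppr).params_
        adj_t_max = TemperatureAdjustment("t_max").fit(reference_daily, reference_ppr).params_
        if "tthr_day" in reference_daily.columns:
            daily_tthr = reference_daily.drop(columns="ppr_day").rename(
                columns={"tthr_day": "ppr_day"}
            )[["ppr_day", "t_av", "t_max"]]
            verdicts = {
                which: check_temperature_association(daily_tthr, which)[1]
                for which in ("t_av", "t_max")
            }

    tthr_model = None
    if fit_tthr:
        tthr_model = TthrModel(
            minsplit_range=minsplit_range,
            maxdepth_range=maxdepth_range,
            cp=cp,
            n_folds=n_folds,
            seed=seed,
        ).fit(aggregated, aggregated["tthr"].to_numpy(), ppr_tree)

    return ModelBundle(
        ppr_tree=ppr_tree,
        tthr_model=tthr_model,
        adj_t_av=adj_t_av,
        adj_t_max=adj_t_max,
        tthr_temp_verdicts=verdicts,
        reference_event_id=ref_id,
    )
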