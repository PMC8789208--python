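"""Shared fixtures: small synthetic registries and the 100-seed
parameter-recovery harness (computed once per session, consumed by the
recovery and cascade tests)."""

from __future__ import annotations

import collections

import numpy as np
import pytest

import murtree as mt
from murtree.data import ORDERED_PREDICTORS, PPR_PREDICTORS
from murtree.tthr import TTHR_PREDICTORS

#: recovery-harness study conditions: 200 events, temperature pinned at the
#: pivot, event-level noise sd 6 per 10,000 (12.5% of the smallest
#: between-leaf gap of the generating surface)
RECOVERY_NOISE_SD = 6.0
RECOVERY_SEEDS = range(100)


@pytest.fixture(scope="session")
def small_registry():
    return mt.generate_registry(
        mt.GeneratorConfig(n_series=10, editions_per_series=5, seed=11)
    )


@pytest.fixture(scope="session")
def small_aggregated(small_registry):
    return mt.aggregate_events(small_registry.events, small_registry.encounters)


@pytest.fixture(scope="session")
def small_ppr_tree(small_aggregated):
    tree, _ = mt.grid_search(
        small_aggregated[list(PPR_PREDICTORS)],
        small_aggregated["ppr"].to_numpy(),
        ordered=dict(ORDERED_PREDICTORS),
        seed=0,
    )
    return tree


def _partition_refines(truth_labels, leaf_ids) -> bool:
    """Every fitted leaf is pure with respect to the generating labels
    (i.e. every generating split is present; extra splits allowed)."""
    groups = collections.defaultdict(set)
    for lab, leaf in zip(truth_labels, leaf_ids):
        groups[leaf].add(lab)
    return all(len(v) == 1 for v in groups.values())


def _recovery_one_seed(seed: int) -> dict:
    cfg = mt.GeneratorConfig(
        n_series=40,
        editions_per_series=5,
        noise_sd=RECOVERY_NOISE_SD,
        constant_temperature=25.6,  # the generating pivot: surface is flat
        seed=seed,
    )
    reg = mt.generate_registry(cfg)
    agg = mt.aggregate_events(reg.events, reg.encounters)
    X = agg[list(PPR_PREDICTORS)]
    tree, _ = mt.grid_search(
        X, agg["ppr"].to_numpy(), ordered=dict(ORDERED_PREDICTORS), seed=seed
    )
    truth = reg.ground_truth
    labels = truth.partition_labels(agg)
    structure = _partition_refines(labels, tree.predict_node(X))

    # leaf means vs truth, margin = 2 exact generating standard errors
    base = truth.base_ppr(agg)
    expected = (
        truth.per_event.set_index("event_id")
        .loc[agg["event_id"], "expected_ppr"]
        .to_numpy()
    )
    var_event = RECOVERY_NOISE_SD**2 + 1e4 * expected / agg["attendance"].to_numpy(float)
    preds = tree.predict(X)
    leaf_ok = {}
    for lab in np.unique(labels):
        idx = labels == lab
        se = np.sqrt(var_event[idx].sum()) / idx.sum()
        leaf_ok[lab] = bool(abs(preds[idx].mean() - base[idx][0]) <= 2 * se)

    # cascaded TTHR tree: partition must refine the generating TTHR surface
    tthr_model = mt.fit_tthr(agg, agg["tthr"].to_numpy(), tree, seed=seed)
    feats = mt.build_tthr_features(agg, tree)
    tthr_refines = _partition_refines(
        truth.tthr_partition_labels(agg),
        tthr_model.tree_.predict_node(feats[list(TTHR_PREDICTORS)]),
    )
    return {"structure": structure, "leaf_ok": leaf_ok, "tthr_refines": tthr_refines}


@pytest.fixture(scope="session")
def recovery_results():
    return [_recovery_one_seed(s) for s in RECOVERY_SEEDS]
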