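"""Linear temperature adjustment of tree-predicted presentation rates.

Ambient temperature is kept out of the regression tree (no sensible cut-offs
exist in the Belgian summer range) and instead enters as a post-hoc linear
correction.  The daily PPR of a multi-day reference festival — the only event
with daily attendance, hence daily PPR — is regressed on the daily 24 h
average (``t_av``) or daily maximum (``t_max``) temperature.  The fitted
slope ``b`` is transferred proportionally to any other outdoor summer event
``i`` through

    PPR_adj(i) = PPR_tree(i) + PPR_tree(i) / PPR_ref * b * (T - T_pivot)

where ``PPR_ref`` is the tree-predicted PPR of the reference event and the
pivot ``T_pivot`` is the temperature at which the fitted line passes through
``PPR_ref`` (so at the pivot the adjustment vanishes for every event).  The
correction applies only to outdoor events held entirely in June–September;
hospital-transfer rates are never adjusted (the reference event shows no
temperature association for TTHR).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .data import official_days
from .errors import AdjustmentError, UndefinedStatisticError

SUMMER_MONTHS = frozenset({6, 7, 8, 9})


@dataclass(frozen=True)
class LinearFit:
    """OLS fit of daily PPR on one temperature variable."""

    intercept: float
    slope: float
    n: int
    p_slope: float
    r2: float


@dataclass(frozen=True)
class AdjustmentParams:
    """Transferable temperature-correction coefficients."""

    slope_b: float  # PPR per deg C
    pivot_t: float  # deg C at which the adjustment is zero
    reference_ppr: float  # tree-predicted PPR of the reference event
    which: str = "t_max"  # temperature variable the fit used


def fit_daily_linear(observations: pd.DataFrame, which: str = "t_max") -> LinearFit:
    """Ordinary least squares of ``ppr_day`` on ``t_av`` or ``t_max``.

    ``observations`` needs columns ``ppr_day`` and the chosen temperature;
    one row per event-day.
    """
    if which not in ("t_av", "t_max"):
        raise ValueError("which must be 't_av' or 't_max'")
    t = observations[which].to_numpy(dtype=float)
    y = observations["ppr_day"].to_numpy(dtype=float)
    if len(t) < 3:
        raise ValueError("need at least 3 datapoints")
    if np.ptp(t) == 0:
        raise UndefinedStatisticError("temperature is constant; slope undefined")
    if np.ptp(y) == 0:
        # flat outcome: slope exactly 0, nothing explained
        return LinearFit(intercept=float(y[0]), slope=0.0, n=len(t), p_slope=1.0, r2=0.0)
    res = stats.linregress(t, y)
    return LinearFit(
        intercept=float(res.intercept),
        slope=float(res.slope),
        n=len(t),
        p_slope=float(res.pvalue),
        r2=float(res.rvalue**2),
    )


def derive_adjustment(
    fit: LinearFit, reference_ppr: float, which: str = "t_max"
) -> AdjustmentParams:
    """Invert the reference fit: the pivot is the temperature at which the
    fitted line equals the reference event's tree-predicted PPR."""
    if fit.slope == 0:
        raise UndefinedStatisticError("zero slope: pivot temperature undefined")
    pivot = (reference_ppr - fit.intercept) / fit.slope
    return AdjustmentParams(
        slope_b=fit.slope, pivot_t=pivot, reference_ppr=reference_ppr, which=which
    )


def is_adjustable(event: Mapping) -> bool:
    """Outdoor and every official day in June–September."""
    if bool(event["indoor"]):
        return False
    return all(d.month in SUMMER_MONTHS for d in official_days(event))


def adjust_ppr(
    ppr_tree: float,
    temperature: float | None,
    params: AdjustmentParams,
    event: Mapping,
) -> float:
    """Temperature-adjusted PPR for one event (unchanged if not adjustable).

    ``temperature`` is the event-period mean of the relevant daily series.
    The linear form can go negative at unseasonably low temperatures; the
    result is floored at 0.
    """
    if not is_adjustable(event):
        return float(ppr_tree)
    if temperature is None or (isinstance(temperature, float) and np.isnan(temperature)):
        raise AdjustmentError(
            f"event {event.get('event_id', '?')} is adjustable but has no temperature"
        )
    adjusted = ppr_tree + ppr_tree / params.reference_ppr * params.slope_b * (
        temperature - params.pivot_t
    )
    return float(max(adjusted, 0.0))


def event_temperature(
    event: Mapping, temperatures: pd.DataFrame, which: str = "t_max"
) -> float:
    """Unweighted mean of the daily temperature over the official days."""
    col = {"t_av": "t_av_c", "t_max": "t_max_c"}[which]
    days = official_days(event)
    sub = temperatures[pd.to_datetime(temperatures["day"]).isin(days)]
    if len(sub) < len(days):
        return float("nan")
    return float(sub[col].mean())


def check_temperature_association(
    observations: pd.DataFrame, which: str = "t_max", alpha: float = 0.05
) -> tuple[LinearFit, bool]:
    """Fit plus verdict: is the outcome associated with temperature?

    Used to justify *not* adjusting TTHR: the reference-event TTHR shows no
    association with either temperature variable.
    """
    fit = fit_daily_linear(observations, which)
    return fit, bool(fit.p_slope < alpha)


class TemperatureAdjustment:
    """Estimator-style wrapper: fit on reference daily data, then adjust.

    ``fit`` derives :class:`AdjustmentParams` from daily observations of the
    reference event and its tree-predicted PPR; ``transform`` maps arrays of
    tree predictions, temperatures and events to adjusted predictions.
    """

    def __init__(self, which: str = "t_max"):
        self.which = which

    def fit(self, observations: pd.DataFrame, reference_ppr: float) -> "TemperatureAdjustment":
        self.fit_ = fit_daily_linear(observations, self.which)
        self.params_ = derive_adjustment(self.fit_, reference_ppr, self.which)
        return self

    def transform(self, ppr_tree, temperatures, events: pd.DataFrame) -> np.ndarray:
        ppr_tree = np.asarray(ppr_tree, dtype=float)
        temperatures = np.asarray(temperatures, dtype=float)
        rows = events.to_dict("records")
        return np.array(
            [
                adjust_ppr(p, t, self.params_, ev)
                for p, t, ev in zip(ppr_tree, temperatures, rows)
            ]
        )
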