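"""Calibration and temporal/external validation of the fitted models.

Predictive performance is summarized as R²: the squared Pearson correlation
between observed and predicted outcomes.  Note that this R² is invariant to
affine transforms of the predictions, so it measures association, not bias —
the ±25% deviation bands complement it with absolute-agreement accounting.
Confidence intervals use the Fisher z transform on r with endpoints squared
(the interval is clipped to [0, 1] and collapses to 0 at the low end when
the r interval straddles zero); a seeded bootstrap percentile interval is
available as an alternative.  Validation is pure evaluation: predictions
come from the serialized model bundle, nothing is refit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import UndefinedStatisticError


def r_squared(observed, predicted) -> float:
    """Squared Pearson correlation between observed and predicted values."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if len(obs) < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(obs) == 0 or np.ptp(pred) == 0:
        raise UndefinedStatisticError("R^2 undefined for a constant vector")
    r = np.corrcoef(obs, pred)[0, 1]
    return float(r**2)


def r_squared_ci(
    observed,
    predicted,
    level: float = 0.95,
    method: str = "fisher",
    n_boot: int = 2000,
    seed: int = 0,
) -> tuple[float, float]:
    """Confidence interval for R².

    ``method="fisher"`` (default): normal interval for atanh(r) with
    SE 1/sqrt(n - 3), endpoints squared.  ``method="bootstrap"``: seeded
    percentile interval of r² over ``n_boot`` case resamples.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    n = len(obs)
    if n < 4:
        raise ValueError("need at least 4 pairs for an interval")
    r_squared(obs, pred)  # raises on degenerate input
    from scipy import stats

    if method == "fisher":
        r = float(np.corrcoef(obs, pred)[0, 1])
        r = float(np.clip(r, -1 + 1e-15, 1 - 1e-15))
        z = np.arctanh(r)
        half = stats.norm.ppf(0.5 + level / 2) / np.sqrt(n - 3)
        r_lo, r_hi = np.tanh(z - half), np.tanh(z + half)
        if r_lo <= 0 <= r_hi:
            lo = 0.0
        else:
            lo = min(r_lo**2, r_hi**2)
        hi = max(r_lo**2, r_hi**2)
        return float(np.clip(lo, 0, 1)), float(np.clip(hi, 0, 1))
    if method == "bootstrap":
        rng = np.random.default_rng(seed)
        vals = []
        for _ in range(n_boot):
            idx = rng.integers(0, n, n)
            o, p = obs[idx], pred[idx]
            if np.ptp(o) == 0 or np.ptp(p) == 0:
                continue
            vals.append(np.corrcoef(o, p)[0, 1] ** 2)
        lo, hi = np.quantile(vals, [(1 - level) / 2, 0.5 + level / 2])
        return float(lo), float(hi)
    raise ValueError(f"unknown method {method!r}")


def deviation_bands(observed, predicted, band: float = 0.25) -> pd.DataFrame:
    """Per-event deviation flags against a relative band (inclusive).

    ``within`` means |predicted - observed| <= band * observed.  Events with
    observed 0 and predicted > 0 have an undefined ratio and are excluded
    from band counts (flagged ``undefined_ratio``).  ``over50``/``under50``
    flag over-/under-prediction beyond 50%.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    undefined = (obs == 0) & (pred > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(obs > 0, pred / obs, np.where(pred == 0, 1.0, np.nan))
    dev = np.abs(pred - obs)
    within = ~undefined & (dev <= band * obs + 1e-12)
    return pd.DataFrame(
        {
            "observed": obs,
            "predicted": pred,
            "ratio": ratio,
            "within": within,
            "over50": ~undefined & (pred - obs > 0.5 * obs),
            "under50": ~undefined & (obs - pred > 0.5 * obs),
            "undefined_ratio": undefined,
        }
    )


@dataclass
class CalibrationReport:
    """Observed-vs-predicted summary for one outcome and one variant."""

    n_events: int
    r2: float
    r2_ci_low: float
    r2_ci_high: float
    n_within_25pct: int
    n_over50: int
    n_under50: int
    n_undefined_ratio: int
    ci_method: str
    table: pd.DataFrame = field(repr=False)


def calibration_report(
    observed, predicted, level: float = 0.95, ci_method: str = "fisher", seed: int = 0
) -> CalibrationReport:
    tab = deviation_bands(observed, predicted)
    r2 = r_squared(observed, predicted)
    lo, hi = r_squared_ci(observed, predicted, level=level, method=ci_method, seed=seed)
    return CalibrationReport(
        n_events=len(tab),
        r2=r2,
        r2_ci_low=lo,
        r2_ci_high=hi,
        n_within_25pct=int(tab["within"].sum()),
        n_over50=int(tab["over50"].sum()),
        n_under50=int(tab["under50"].sum()),
        n_undefined_ratio=int(tab["undefined_ratio"].sum()),
        ci_method=ci_method,
        table=tab,
    )


def validate(
    bundle,
    dataset: pd.DataFrame,
    temperatures: pd.DataFrame | None = None,
    mode: str = "development",
    ci_method: str = "fisher",
) -> dict[str, CalibrationReport]:
    """Evaluate a fitted model bundle on an aggregated-event table.

    Returns reports keyed ``ppr_crude``, ``ppr_t_av``, ``ppr_t_max`` (the
    latter two only when the bundle carries the adjustment and temperatures
    are available) and ``tthr``.  The dataset must be categorized with the
    development class definitions; predictions never refit anything, and
    TTHR is never temperature-adjusted.
    """
    if mode not in ("development", "temporal", "external"):
        raise ValueError(f"unknown mode {mode!r}")
    out: dict[str, CalibrationReport] = {}
    crude = bundle.predict_ppr(dataset, temperatures=None, variant="crude")
    out["ppr_crude"] = calibration_report(dataset["ppr"], crude, ci_method=ci_method)
    if temperatures is not None:
        for which in ("t_av", "t_max"):
            if bundle.adjustment(which) is None:
                continue
            adj = bundle.predict_ppr(dataset, temperatures=temperatures, variant=which)
            out[f"ppr_{which}"] = calibration_report(
                dataset["ppr"], adj, ci_method=ci_method
            )
    if bundle.tthr_model is not None:
        pred_tthr = bundle.predict_tthr(dataset)
        out["tthr"] = calibration_report(dataset["tthr"], pred_tthr, ci_method=ci_method)
    return out
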