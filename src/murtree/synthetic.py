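"""Synthetic mass-gathering registries with known ground truth.

The MedTRIS-style registry the pipeline was designed for is not public, so
this module generates event, encounter and temperature tables that emulate
its documented shape: six event categories with category-specific mean PPR
(a piecewise-constant ground-truth tree over category and number of days,
leaf means spanning 12–273 per 10,000), attendance from roughly 10^4 to above
10^6, audience age mixtures per age class with ~23% missing ages, ~10%
missing dismissal destinations, seasonal daily temperatures, and a linear
temperature effect on outdoor June–September events transferred exactly the
way the adjustment equation assumes.  Every draw flows from one seed, so a
registry is byte-identical across runs and each generated quantity has a
recoverable expectation — the module doubles as the parameter-recovery
harness for the tree engine.

Count law: patient counts are Poisson with mean attendance x expected PPR /
10,000 after an event-level multiplicative lognormal overdispersion whose
additive standard deviation is ``noise_sd`` (per 10,000); both pieces can be
switched off for exact-recovery oracles.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .data import CATEGORIES
from .errors import ConfigError

# ---------------------------------------------------------------------------
# ground-truth effect surfaces

#: PPR leaf means per profile; outdoor music splits on number of days.
#: Profiles sharing a value belong to one generating leaf (the recoverable
#: partition groups by value, not label); gaps are wide enough that every
#: generating split clears the cp = 0.01 lack-of-fit bound by a safe margin
#: under the default noise — a smaller gap is unrecoverable by the protocol
#: itself, regardless of noise.  The 183 leaf doubles as the reference
#: event's tree-predicted PPR used by the temperature transfer.
DEFAULT_TRUE_EFFECTS: dict[str, float] = {
    "city_festival": 12.0,
    "indoor_dance": 60.0,
    "sports_event": 60.0,
    "indoor_edm": 120.0,
    "outdoor_edm": 183.0,
    "outdoor_music_d1d2": 183.0,
    "outdoor_music_d3plus": 273.0,
}

#: TTHR per PPR-leaf (profiles sharing a PPR leaf share a TTHR); 0–5.9 with
#: indoor EDM highest.  As with the PPR surface, the between-leaf gaps are
#: sized so that every generating split clears the cp bound even from the
#: smallest category (10 events at n=200).
DEFAULT_TTHR_EFFECTS: dict[str, float] = {
    "city_festival": 0.0,
    "indoor_dance": 1.5,
    "sports_event": 1.5,
    "indoor_edm": 5.9,
    "outdoor_edm": 3.0,
    "outdoor_music_d1d2": 3.0,
    "outdoor_music_d3plus": 3.0,
}


def ppr_profile(category: str, n_days: int) -> str:
    """Ground-truth leaf label for an event."""
    if category == "outdoor_music":
        return "outdoor_music_d3plus" if n_days >= 3 else "outdoor_music_d1d2"
    return category


# per-category shape parameters: (attendance median, days choices, day probs,
# timing, age-class choices, age probs)
_CATEGORY_SHAPE = {
    "city_festival": (120_000, (2, 3), (0.5, 0.5), "day_and_night",
                      ("mixed_family", "middle_adults"), (0.6, 0.4)),
    "indoor_edm": (30_000, (1, 2), (0.8, 0.2), "night",
                   ("young_adults",), (1.0,)),
    "indoor_dance": (15_000, (1, 2), (0.8, 0.2), "night",
                     ("young_adults",), (1.0,)),
    "outdoor_edm": (30_000, (1, 2), (0.6, 0.4), "day_and_night",
                    ("young_adults",), (1.0,)),
    "outdoor_music": (60_000, (1, 2, 3, 4), (0.3, 0.2, 0.25, 0.25), "day_and_night",
                      ("young_adults", "mixed_family", "children"), (0.7, 0.2, 0.1)),
    "sports_event": (25_000, (1,), (1.0,), "day",
                     ("middle_adults", "young_adults"), (0.6, 0.4)),
}

_AGE_MIXTURES = {
    # (component means, sds, weights); tuned so classify_age recovers the class
    "children": ((12.0,), (2.0,), (1.0,)),
    "young_adults": ((23.0,), (5.0,), (1.0,)),
    "middle_adults": ((40.0,), (10.0,), (1.0,)),
    "mixed_family": ((10.0, 38.0), (4.0, 10.0), (0.5, 0.5)),
}


@dataclass(frozen=True)
class GeneratorConfig:
    """Registry-generation parameters; defaults emulate the development set."""

    n_series: int = 28
    editions_per_series: int = 7
    start_year: int = 2009
    category_mix: tuple[float, ...] = (
        37 / 194, 19 / 194, 12 / 194, 21 / 194, 85 / 194, 20 / 194,
    )  # ordered as data.CATEGORIES
    true_effects: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TRUE_EFFECTS)
    )
    true_tthr_effects: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TTHR_EFFECTS)
    )
    temp_slope: float = 7.6  # PPR per deg C, acting on temp_which
    temp_pivot: float = 25.6  # deg C
    temp_reference_ppr: float = 183.0
    temp_which: str = "t_max"
    noise_sd: float = 40.0  # event-level PPR noise, per 10,000
    poisson_counts: bool = True
    constant_temperature: float | None = None  # pin t_max (oracle runs)
    missing_age_rate: float = 0.23
    missing_dismissal_rate: float = 0.10
    seed: int = 0

    def __post_init__(self):
        if abs(sum(self.category_mix) - 1.0) > 1e-9 or min(self.category_mix) < 0:
            raise ConfigError("category_mix must be a probability vector")
        for r in (self.missing_age_rate, self.missing_dismissal_rate):
            if not 0 <= r <= 1:
                raise ConfigError("missingness rates must be in [0, 1]")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")


@dataclass
class GroundTruth:
    """Recoverable generating quantities for every recovery test."""

    per_event: pd.DataFrame  # event_id, profile, base_ppr, expected_ppr, expected_tthr
    true_effects: dict[str, float]
    true_tthr_effects: dict[str, float]
    temp_slope: float
    temp_pivot: float
    temp_reference_ppr: float
    temp_which: str

    def partition_labels(self, events: pd.DataFrame) -> np.ndarray:
        """Generating-leaf label per event row: profiles that share a base
        PPR belong to the same leaf, so labels group by value."""
        return np.array(
            [
                f"ppr_{self.true_effects[ppr_profile(c, int(n))]:g}"
                for c, n in zip(events["category"], events["n_days"])
            ]
        )

    def tthr_partition_labels(self, events: pd.DataFrame) -> np.ndarray:
        """Generating TTHR-leaf label per event row (groups by TTHR value)."""
        return np.array(
            [
                f"tthr_{self.true_tthr_effects[ppr_profile(c, int(n))]:g}"
                for c, n in zip(events["category"], events["n_days"])
            ]
        )

    def base_ppr(self, events: pd.DataFrame) -> np.ndarray:
        return np.array(
            [
                self.true_effects[ppr_profile(c, int(n))]
                for c, n in zip(events["category"], events["n_days"])
            ]
        )


@dataclass
class SyntheticRegistry:
    events: pd.DataFrame
    encounters: pd.DataFrame
    temperatures: pd.DataFrame
    ground_truth: GroundTruth

    def write(self, directory: str | Path) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        ev = self.events.copy()
        ev["first_day"] = pd.to_datetime(ev["first_day"]).dt.strftime("%Y-%m-%d")
        ev.to_csv(d / "events.csv", index=False)
        enc = self.encounters.copy()
        enc["day"] = pd.to_datetime(enc["day"]).dt.strftime("%Y-%m-%d")
        enc.to_csv(d / "encounters.csv", index=False)
        tmp = self.temperatures.copy()
        tmp["day"] = pd.to_datetime(tmp["day"]).dt.strftime("%Y-%m-%d")
        tmp.to_csv(d / "temperatures.csv", index=False)


# ---------------------------------------------------------------------------
# generation


def _seasonal_t_max(day: pd.Timestamp, rng) -> float:
    doy = day.dayofyear
    return 12.0 + 11.0 * np.sin(2 * np.pi * (doy - 105) / 365.25) + rng.normal(0, 3.0)


def _draw_ages(rng, n: int, age_class: str) -> np.ndarray:
    means, sds, weights = _AGE_MIXTURES[age_class]
    comp = rng.choice(len(means), size=n, p=weights)
    ages = rng.normal(np.asarray(means)[comp], np.asarray(sds)[comp])
    return np.clip(np.round(ages), 0, 120)


def generate_registry(config: GeneratorConfig = GeneratorConfig()) -> SyntheticRegistry:
    """Generate (events, encounters, temperatures, ground truth)."""
    rng = np.random.default_rng(config.seed)
    events_rows, truth_rows, enc_frames = [], [], []
    temp_days: dict[pd.Timestamp, tuple[float, float]] = {}

    # stratified category allocation (largest remainder): the registry being
    # emulated has fixed per-category series counts, not a category lottery
    quota = np.asarray(config.category_mix) * config.n_series
    counts = np.floor(quota).astype(int)
    for i in np.argsort(-(quota - counts), kind="stable")[: config.n_series - counts.sum()]:
        counts[i] += 1
    series_categories = np.repeat(CATEGORIES, counts)
    rng.shuffle(series_categories)

    for si in range(config.n_series):
        category = series_categories[si]
        att_med, day_choices, day_p, timing, age_choices, age_p = _CATEGORY_SHAPE[category]
        indoor = category.startswith("indoor")
        base_att = float(np.exp(rng.normal(np.log(att_med), 0.5)))
        n_days = int(rng.choice(day_choices, p=np.asarray(day_p)))
        age_class = rng.choice(age_choices, p=np.asarray(age_p))
        bounded = bool(rng.random() < (0.95 if indoor else 0.75))
        camping = bool(category == "outdoor_music" and n_days >= 2 and rng.random() < 0.8)
        alcohol = "limited" if category == "sports_event" else (
            "none" if age_class == "children" else "unlimited"
        )
        hospital_km = float(np.exp(rng.normal(np.log(8.0), 0.7)))
        hospital_min = float(hospital_km * 1.5 + rng.normal(0, 2))
        if indoor:
            # November–February
            doy_start = int(rng.integers(305, 365))
        else:
            # June–September, leaving room for the last day
            doy_start = int(rng.integers(152, 273 - n_days))
        sold_out = bool(rng.random() < 0.15)

        for e in range(config.editions_per_series):
            year = config.start_year + e
            # development-set eligibility: at least 10,000 attendees per edition
            attendance = max(10_000.0, base_att * rng.uniform(0.85, 1.15))
            attendance = float(np.round(attendance, -2))
            first = pd.Timestamp(year=year, month=1, day=1) + pd.Timedelta(
                days=doy_start - 1
            )
            days = pd.date_range(first, periods=n_days, freq="D")
            for d in days:
                if d not in temp_days:
                    if config.constant_temperature is not None:
                        tmax = float(config.constant_temperature)
                        tav = tmax - 5.0
                    else:
                        tmax = float(_seasonal_t_max(d, rng))
                        tav = float(tmax - 5.0 + rng.normal(0, 1.0))
                    temp_days[d] = (tav, tmax)
            event_id = f"S{si:02d}Y{year}"
            profile = ppr_profile(category, n_days)
            base_ppr = float(config.true_effects[profile])
            outdoor_summer = not indoor and all(d.month in (6, 7, 8, 9) for d in days)
            if outdoor_summer:
                which_idx = 0 if config.temp_which == "t_av" else 1
                t_event = float(np.mean([temp_days[d][which_idx] for d in days]))
                expected = base_ppr + base_ppr / config.temp_reference_ppr * (
                    config.temp_slope * (t_event - config.temp_pivot)
                )
                expected = max(expected, 0.5)
            else:
                expected = base_ppr
            if config.noise_sd > 0:
                sigma = np.sqrt(np.log1p((config.noise_sd / expected) ** 2))
                # floor: even the quietest events see a couple of patients
                # per 10,000 (only binding deep in the lognormal tail)
                expected_noisy = max(
                    2.0, expected * float(np.exp(rng.normal(-0.5 * sigma**2, sigma)))
                )
            else:
                expected_noisy = expected
            mu_patients = attendance * expected_noisy / 10_000.0
            tthr_exp = float(config.true_tthr_effects[profile])
            mu_transfers = attendance * tthr_exp / 10_000.0
            if config.poisson_counts:
                n_patients = int(rng.poisson(mu_patients))
                n_transfers = int(min(n_patients, rng.poisson(mu_transfers)))
            else:
                n_patients = int(np.round(mu_patients))
                n_transfers = int(min(n_patients, np.round(mu_transfers)))

            events_rows.append(
                dict(
                    event_id=event_id,
                    series_name=f"series_{si:02d}",
                    year=year,
                    category=category,
                    attendance=attendance,
                    first_day=first,
                    n_days=n_days,
                    timing=timing,
                    indoor=indoor,
                    bounded=bounded,
                    camping=camping,
                    alcohol=alcohol,
                    hospital_distance_km=round(hospital_km, 1),
                    hospital_time_min=round(hospital_min, 1),
                    sold_out=sold_out,
                )
            )
            truth_rows.append(
                dict(
                    event_id=event_id,
                    profile=profile,
                    base_ppr=base_ppr,
                    expected_ppr=expected,
                    expected_ppr_noisy=expected_noisy,
                    expected_tthr=tthr_exp,
                )
            )
            if n_patients:
                day_idx = rng.integers(0, n_days, n_patients)
                ages = _draw_ages(rng, n_patients, age_class).astype(float)
                miss = rng.random(n_patients) < config.missing_age_rate
                if miss.all():
                    miss[0] = False
                ages[miss] = np.nan
                dismissal = np.empty(n_patients, dtype=object)
                transfer_idx = rng.choice(n_patients, size=n_transfers, replace=False)
                dismissal[:] = None
                dismissal[transfer_idx] = "hospital_by_ambulance"
                rest = np.setdiff1d(np.arange(n_patients), transfer_idx)
                u = rng.random(len(rest))
                dest = rng.choice(
                    ["back_to_event", "own_means", "other"], size=len(rest),
                    p=[0.96, 0.03, 0.01],
                )
                dest = np.where(u < config.missing_dismissal_rate, None, dest)
                dismissal[rest] = dest
                enc_frames.append(
                    pd.DataFrame(
                        {
                            "event_id": event_id,
                            "day": days[day_idx],
                            "age": ages,
                            "dismissal": dismissal,
                            "triage": rng.choice(
                                ["green", "yellow", "red"], size=n_patients,
                                p=[0.9, 0.08, 0.02],
                            ),
                        }
                    )
                )

    events = pd.DataFrame(events_rows)
    encounters = (
        pd.concat(enc_frames, ignore_index=True)
        if enc_frames
        else pd.DataFrame(columns=["event_id", "day", "age", "dismissal", "triage"])
    )
    temperatures = pd.DataFrame(
        {
            "day": sorted(temp_days),
            "t_av_c": [temp_days[d][0] for d in sorted(temp_days)],
            "t_max_c": [temp_days[d][1] for d in sorted(temp_days)],
        }
    )
    truth = GroundTruth(
        per_event=pd.DataFrame(truth_rows),
        true_effects=dict(config.true_effects),
        true_tthr_effects=dict(config.true_tthr_effects),
        temp_slope=config.temp_slope,
        temp_pivot=config.temp_pivot,
        temp_reference_ppr=config.temp_reference_ppr,
        temp_which=config.temp_which,
    )
    return SyntheticRegistry(events, encounters, temperatures, truth)


def generate_reference_daily(
    n_editions: int = 9,
    days_per_edition: int = 4,
    slope: float = 10.6,
    pivot: float = 20.4,
    reference_ppr: float = 183.0,
    noise_sd: float = 20.0,
    which: str = "t_av",
    temp_sd: float = 3.5,
    seed: int = 0,
) -> pd.DataFrame:
    """Day-level reference-event data: editions x days rows (default 36).

    ``ppr_day`` follows the linear law ``reference_ppr + slope * (t - pivot)``
    in the chosen temperature plus Gaussian noise; the other temperature
    column is generated as a correlated companion (t_max ≈ t_av + 5).
    """
    rng = np.random.default_rng(seed)
    rows = []
    for ed in range(n_editions):
        for di in range(days_per_edition):
            t = float(rng.normal(pivot, temp_sd))
            if which == "t_av":
                t_av, t_max = t, t + 5.0 + float(rng.normal(0, 1.0))
            else:
                t_av, t_max = t - 5.0 + float(rng.normal(0, 1.0)), t
            rows.append(
                dict(
                    edition_year=2009 + ed,
                    day_index=di + 1,
                    attendance_day=float(np.round(85_000 + rng.normal(0, 3000))),
                    t_av=t_av,
                    t_max=t_max,
                    ppr_day=reference_ppr + slope * (t - pivot) + float(rng.normal(0, noise_sd)),
                )
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# deterministic corruption schemes (exercise imputation and exclusion paths)

SCHEMES = ("attendance_gap", "sold_out_chain", "date_leakage")


def corrupt_for_robustness(
    registry: SyntheticRegistry, scheme: str
) -> tuple[SyntheticRegistry, dict]:
    """Return a corrupted copy of the registry plus a manifest of changes."""
    if scheme not in SCHEMES:
        raise ConfigError(f"unknown corruption scheme {scheme!r}")
    events = registry.events.copy()
    encounters = registry.encounters.copy()
    manifest: dict = {"scheme": scheme}

    by_series = events.groupby("series_name", sort=True)
    if scheme == "attendance_gap":
        for name, g in by_series:
            if len(g) >= 3:
                mid = g.sort_values("year").index[len(g) // 2]
                events.loc[mid, "attendance"] = np.nan
                manifest["event_id"] = events.loc[mid, "event_id"]
                break
    elif scheme == "sold_out_chain":
        for name, g in by_series:
            if len(g) >= 3:
                g = g.sort_values("year")
                events.loc[g.index, "sold_out"] = True
                events.loc[g.index[1:], "attendance"] = np.nan
                manifest["event_ids"] = list(g["event_id"].iloc[1:])
                manifest["copied_from"] = g["event_id"].iloc[0]
                break
    else:  # date_leakage
        ev = events.iloc[0]
        first = pd.Timestamp(ev["first_day"])
        last = first + pd.Timedelta(days=int(ev["n_days"]) - 1)
        extra = pd.DataFrame(
            {
                "event_id": ev["event_id"],
                "day": [first - pd.Timedelta(days=1)] * 3 + [last + pd.Timedelta(days=1)] * 2,
                "age": [25.0] * 5,
                "dismissal": ["back_to_event"] * 5,
                "triage": ["green"] * 5,
            }
        )
        encounters = pd.concat([encounters, extra], ignore_index=True)
        manifest.update(event_id=ev["event_id"], n_added=5)

    return (
        SyntheticRegistry(events, encounters, registry.temperatures.copy(), registry.ground_truth),
        manifest,
    )
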