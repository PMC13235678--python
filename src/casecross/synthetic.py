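"""Seeded synthetic event, weather, and tract data with known ground truth.

The generator emulates the structure of the three study inputs — point-located
fatal-encounter records, daily gridded weather (4-km-style cells), and census
tract tables with extreme-group counts — with a generative model whose
parameters the downstream analysis is supposed to recover:

* weather: per-cell mean + summer-peaking sinusoid + Gaussian day-to-day
  noise for daily maximum temperature; daily mean a fixed 8 degC below the
  maximum; rainfall zero with some probability, otherwise exponential;
* events: one Bernoulli draw per cell-day with
  logit p = logit(baseline_rate) + beta_temp * (tmax - 23.5) + gamma_holiday * holiday,
  so each case day is unambiguous for matched-stratum construction;
* tracts: extreme-group counts built to span the full ICE range, so the
  national terciles are all populated.

Every cell is fixed to one tract (and one census region) at generation,
mirroring the spatial join of encounters to tracts.
"""

from __future__ import annotations

import datetime as dt
import json
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from .holidays import us_federal_holidays
from .ice import DIMENSIONS

__all__ = ["SyntheticConfig", "GroundTruth", "generate_weather", "generate_events",
           "generate_tracts", "generate_all"]

REFERENT_C = 23.5          # temperature at which the event hazard equals baseline_rate
TMEAN_OFFSET_C = 8.0       # daily mean = daily max - 8 degC
SEASONAL_PEAK_DOY = 196    # July 15: summer peak of the seasonal cycle
REGIONS = ("Northeast", "Midwest", "South", "West")
SEASONS = {12: "Winter", 1: "Winter", 2: "Winter", 3: "Spring", 4: "Spring", 5: "Spring",
           6: "Summer", 7: "Summer", 8: "Summer", 9: "Fall", 10: "Fall", 11: "Fall"}


@dataclass(frozen=True)
class SyntheticConfig:
    """Ground-truth parameters and sizes for one synthetic dataset.

    beta_temp is the log-odds change per degC of daily max temperature;
    gamma_holiday the log-odds holiday effect; baseline_rate the event
    probability per cell-day at the referent temperature on a non-holiday.
    """

    n_cells: int = 40
    n_tracts: int = 120
    date_start: dt.date = dt.date(2021, 1, 1)
    date_end: dt.date = dt.date(2021, 12, 31)
    beta_temp: float = 0.006
    gamma_holiday: float = 0.10
    baseline_rate: float = 0.05
    seasonal_amplitude: float = 12.0
    noise_sd: float = 3.0
    precip_zero_prob: float = 0.6
    precip_wet_mean_mm: float = 4.0
    seed: int = 0

    def __post_init__(self):
        if self.n_cells < 1 or self.n_tracts < 1:
            raise ValueError("n_cells and n_tracts must be >= 1")
        if self.date_start >= self.date_end:
            raise ValueError("date_start must precede date_end")
        if not (0 < self.baseline_rate < 1):
            raise ValueError("baseline_rate must lie in (0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not (0 <= self.precip_zero_prob <= 1):
            raise ValueError("precip_zero_prob must lie in [0, 1]")

    @property
    def dates(self) -> pd.DatetimeIndex:
        return pd.date_range(self.date_start, self.date_end, freq="D")


@dataclass(frozen=True)
class GroundTruth:
    """The generative parameters a correct analysis should recover."""

    beta_temp: float
    gamma_holiday: float
    cell_baseline_logodds: dict
    seed: int

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)


def _cells_frame(config: SyntheticConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Cell centers on a rough CONUS-interior grid, each fixed to one tract/region."""
    n = config.n_cells
    side = int(np.ceil(np.sqrt(n)))
    idx = np.arange(n)
    cells = pd.DataFrame(
        {
            "cell_id": [f"C{i:04d}" for i in idx],
            "lon": -110.0 + 0.5 * (idx % side),
            "lat": 32.0 + 0.5 * (idx // side),
            "tract_id": [f"T{t:04d}" for t in rng.integers(0, config.n_tracts, size=n)],
            "region": rng.choice(REGIONS, size=n),
            "mean_tmax_c": rng.uniform(8.0, 24.0, size=n),
        }
    )
    return cells


def generate_weather(config: SyntheticConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Daily weather series for every cell over the configured date range.

    Returns ``(weather, cells)``: ``weather`` has one row per cell-day with
    ``cell_id, date, tmax_c, tmean_c, precip_mm``; ``cells`` carries the cell
    centers and their fixed tract/region assignment.  Requires a range of at
    least 60 days (shorter ranges cannot support month-stratified matching).
    """
    dates = config.dates
    if len(dates) < 60:
        raise ValueError("date range must span at least 60 days for month-stratified matching")
    rng = np.random.default_rng([config.seed, 1])
    cells = _cells_frame(config, rng)
    doy = dates.dayofyear.to_numpy()
    seasonal = config.seasonal_amplitude * np.cos(2 * np.pi * (doy - SEASONAL_PEAK_DOY) / 365.25)
    n_c, n_d = len(cells), len(dates)
    tmax = (
        cells["mean_tmax_c"].to_numpy()[:, None]
        + seasonal[None, :]
        + rng.normal(0.0, config.noise_sd, size=(n_c, n_d))
    )
    dry = rng.random(size=(n_c, n_d)) < config.precip_zero_prob
    precip = np.where(dry, 0.0, rng.exponential(config.precip_wet_mean_mm, size=(n_c, n_d)))
    weather = pd.DataFrame(
        {
            "cell_id": np.repeat(cells["cell_id"].to_numpy(), n_d),
            "date": np.tile(dates.to_numpy(), n_c),
            "tmax_c": tmax.ravel(),
            "tmean_c": tmax.ravel() - TMEAN_OFFSET_C,
            "precip_mm": precip.ravel(),
        }
    )
    return weather, cells.drop(columns="mean_tmax_c")


def generate_events(
    config: SyntheticConfig, weather: pd.DataFrame, cells: pd.DataFrame
) -> tuple[pd.DataFrame, GroundTruth]:
    """Bernoulli event draw per cell-day under the log-linear temperature model.

    Each event becomes a record at its generating cell's center, carrying the
    cell's fixed tract and region, plus the meteorological season of its date.
    """
    dates = config.dates
    covered = weather.groupby("cell_id")["date"].agg(["min", "max"])
    if (pd.to_datetime(covered["min"]) > dates[0]).any() or (
        pd.to_datetime(covered["max"]) < dates[-1]
    ).any():
        raise ValueError("weather does not cover the configured date range for every cell")
    rng = np.random.default_rng([config.seed, 2])
    cal = us_federal_holidays(range(config.date_start.year, config.date_end.year + 1))
    w = weather.copy()
    w["date"] = pd.to_datetime(w["date"])
    w = w[(w["date"] >= dates[0]) & (w["date"] <= dates[-1])]
    hol = w["date"].dt.date.map(lambda d: d in cal.dates).to_numpy()
    base = np.log(config.baseline_rate / (1.0 - config.baseline_rate))
    logit = base + config.beta_temp * (w["tmax_c"].to_numpy() - REFERENT_C)
    logit = logit + config.gamma_holiday * hol
    p = 1.0 / (1.0 + np.exp(-logit))
    hit = rng.random(len(w)) < p
    ev = w.loc[hit, ["cell_id", "date"]].merge(cells, on="cell_id", how="left")
    ev = ev.sort_values(["date", "cell_id"], kind="stable").reset_index(drop=True)
    events = pd.DataFrame(
        {
            "event_id": [f"E{i:06d}" for i in range(len(ev))],
            "date": ev["date"],
            "lon": ev["lon"],
            "lat": ev["lat"],
            "cell_id": ev["cell_id"],
            "tract_id": ev["tract_id"],
            "region": ev["region"],
            "season": ev["date"].dt.month.map(SEASONS),
        }
    )
    truth = GroundTruth(
        beta_temp=config.beta_temp,
        gamma_holiday=config.gamma_holiday,
        cell_baseline_logodds={c: base for c in cells["cell_id"]},
        seed=config.seed,
    )
    return events, truth


def generate_tracts(config: SyntheticConfig) -> pd.DataFrame:
    """Tract table with extreme-group counts spanning the full ICE range.

    For each tract and dimension a target ICE in (-0.85, 0.85) and a total
    extreme-group share are drawn, then converted to privileged/deprived
    counts; by construction privileged + deprived <= total population.
    """
    rng = np.random.default_rng([config.seed, 3])
    n = config.n_tracts
    pop = rng.integers(1200, 8000, size=n)
    out = {"tract_id": [f"T{i:04d}" for i in range(n)], "pop_total": pop}
    for dim in DIMENSIONS:
        target = rng.uniform(-0.85, 0.85, size=n)
        share = np.abs(target) + rng.uniform(0.05, 0.95, size=n) * (1.0 - np.abs(target))
        priv = np.floor(pop * (share + target) / 2.0).astype(int)
        depr = np.floor(pop * (share - target) / 2.0).astype(int)
        out[f"{dim}_priv"] = np.clip(priv, 0, pop)
        out[f"{dim}_depr"] = np.clip(depr, 0, pop - np.clip(priv, 0, pop))
        assert np.all(out[f"{dim}_priv"] + out[f"{dim}_depr"] <= pop)
    return pd.DataFrame(out)


def generate_all(config: SyntheticConfig) -> dict:
    """Generate the full dataset bundle: weather, cells, events, tracts, truth."""
    weather, cells = generate_weather(config)
    events, truth = generate_events(config, weather, cells)
    tracts = generate_tracts(config)
    return {
        "weather": weather,
        "cells": cells,
        "events": events,
        "tracts": tracts,
        "truth": truth,
    }
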