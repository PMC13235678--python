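"""End-to-end workflow: generate/load -> match -> link -> fit -> effects -> stratify.

One :class:`RunConfig` drives the whole analysis.  Inputs are either three
CSV paths (events, weather, tracts) or an inline synthetic-data block —
exactly one of the two.  Every stage writes its interface file into the
output directory and the run closes with ``run_report.json`` (stage timings,
record counts in/out, the AIC-selected exposure parameterization, warnings),
so a run is reproducible from its report plus the seed.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import clr, effects, ice, linkage, synthetic
from .crossover import build_strata
from .holidays import load_holidays, us_federal_holidays

__all__ = ["RunConfig", "run", "descriptives"]

logger = logging.getLogger(__name__)

DESCRIPTIVE_ATTRIBUTES = ("gender", "age", "race", "cause", "region", "season")


@dataclass
class RunConfig:
    """Configuration for one pipeline run.

    Exactly one of ``events/weather/tracts`` paths or ``synthetic`` must be
    supplied.  ``referent`` defaults to 23.5 degC for daily maximum
    temperature and 17.1 degC for daily mean temperature.
    """

    outdir: str = "casecross_run"
    seed: int = 0
    events: str | None = None
    weather: str | None = None
    tracts: str | None = None
    synthetic: dict | None = None
    exposure: str = "dtmax"
    forms: tuple = ("linear", "spline2", "spline3", "spline4")
    covariates: tuple = ("holiday",)
    referent: float | None = None
    probs: tuple = effects.DEFAULT_PROBS
    holidays_path: str | None = None
    precip_mean_mm: float = linkage.DEFAULT_PRECIP_MEAN_MM
    stratify_by: tuple = ice.DIMENSIONS
    curve_points: int = 200
    log_level: str = "INFO"

    def __post_init__(self):
        paths = [self.events, self.weather, self.tracts]
        have_paths = any(p is not None for p in paths)
        if have_paths and self.synthetic is not None:
            raise ValueError("supply either input CSV paths or a synthetic block, not both")
        if not have_paths and self.synthetic is None:
            raise ValueError("one of input CSV paths or a synthetic block is required")
        if have_paths and not all(p is not None for p in paths):
            raise ValueError("events, weather, and tracts paths must all be given")
        if self.referent is None:
            self.referent = 23.5 if self.exposure == "dtmax" else 17.1
        self.forms = tuple(self.forms)
        self.covariates = tuple(self.covariates)
        self.stratify_by = tuple(self.stratify_by)
        self.probs = tuple(self.probs)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update(overrides)
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    def model_specs(self) -> list[clr.ModelSpec]:
        specs = []
        for form in self.forms:
            if form == "linear":
                specs.append(
                    clr.ModelSpec(
                        exposure=self.exposure, form="linear",
                        covariates=self.covariates, referent=self.referent,
                    )
                )
            elif form.startswith("spline"):
                specs.append(
                    clr.ModelSpec(
                        exposure=self.exposure, form="spline", df=int(form[len("spline"):]),
                        covariates=self.covariates, referent=self.referent,
                    )
                )
            else:
                raise ValueError(f"unknown exposure form {form!r}")
        return specs


def descriptives(events: pd.DataFrame, attributes=DESCRIPTIVE_ATTRIBUTES) -> pd.DataFrame:
    """Frequency table of victim/event attributes: counts and percentages.

    Every event counts once per attribute (missing values tallied as
    "Unknown"); percentages use the full event count as denominator and are
    rounded to one decimal.
    """
    n = len(events)
    rows = []
    for attr in attributes:
        col = events[attr] if attr in events.columns else pd.Series(pd.NA, index=events.index)
        col = col.fillna("Unknown").replace("", "Unknown")
        counts = col.value_counts()
        for level, count in counts.items():
            rows.append(
                {
                    "attribute": attr,
                    "level": level,
                    "count": int(count),
                    "percent": round(100.0 * count / n, 1) if n else 0.0,
                }
            )
    return pd.DataFrame(rows)


def _load_inputs(config: RunConfig, outdir: Path):
    if config.synthetic is not None:
        syn = dict(config.synthetic)
        syn.setdefault("seed", config.seed)
        for key in ("date_start", "date_end"):
            if key in syn and isinstance(syn[key], str):
                syn[key] = dt.date.fromisoformat(syn[key])
        scfg = synthetic.SyntheticConfig(**syn)
        bundle = synthetic.generate_all(scfg)
        bundle["events"].to_csv(outdir / "events.csv", index=False)
        bundle["weather"].to_csv(outdir / "weather.csv", index=False)
        bundle["tracts"].to_csv(outdir / "tracts.csv", index=False)
        bundle["truth"].to_json(outdir / "truth.json")
        return bundle["events"], bundle["weather"], bundle["tracts"], bundle["cells"]
    # round_trip keeps exposure values bit-exact through the CSV interface
    events = pd.read_csv(config.events, parse_dates=["date"], float_precision="round_trip")
    weather = pd.read_csv(config.weather, parse_dates=["date"], float_precision="round_trip")
    tracts = pd.read_csv(config.tracts)
    cells = None
    if "cell_id" not in events.columns or events["cell_id"].isna().any():
        centers = weather.groupby("cell_id").first().reset_index()
        if not {"lon", "lat"} <= set(centers.columns):
            raise ValueError("events lack cell_id and weather carries no cell lon/lat to resolve it")
        cells = centers[["cell_id", "lon", "lat"]]
        events = events.copy()
        events["cell_id"] = [
            linkage.nearest_cell(lo, la, cells) for lo, la in zip(events["lon"], events["lat"])
        ]
    return events, weather, tracts, cells


def run(config: RunConfig) -> dict:
    """Execute the full workflow; returns (and writes) the run report."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": config.to_dict(), "seed": config.seed, "stages": {}, "warnings": []}

    def stage(name):
        t0 = time.perf_counter()
        report["stages"][name] = {"seconds": None}
        return t0

    def close(name, t0, **counts):
        report["stages"][name]["seconds"] = round(time.perf_counter() - t0, 3)
        report["stages"][name].update(counts)

    t0 = stage("inputs")
    events, weather, tracts, cells = _load_inputs(config, outdir)
    close("inputs", t0, n_events=len(events), n_cell_days=len(weather), n_tracts=len(tracts))

    t0 = stage("descriptives")
    desc = descriptives(events)
    desc.to_csv(outdir / "descriptives.csv", index=False)
    close("descriptives", t0, n_rows=len(desc))

    t0 = stage("match")
    strata = build_strata(events)
    strata.to_csv(outdir / "strata.csv", index=False)
    n_strata = strata["stratum_id"].nunique()
    close("match", t0, n_strata=n_strata, n_stratum_days=len(strata))

    t0 = stage("link")
    years = range(pd.to_datetime(strata["date"]).dt.year.min(),
                  pd.to_datetime(strata["date"]).dt.year.max() + 1)
    calendar = (
        load_holidays(config.holidays_path, years=years)
        if config.holidays_path
        else us_federal_holidays(years)
    )
    linked = linkage.link(strata, weather, calendar, mean_mm=config.precip_mean_mm)
    linked.to_csv(outdir / "linked.csv", index=False)
    n_linked_strata = linked["stratum_id"].nunique()
    dropped = n_strata - n_linked_strata
    if dropped:
        report["warnings"].append(f"{dropped} strata dropped for missing weather")
    close("link", t0, n_strata=n_linked_strata, n_dropped_missing_weather=dropped)

    t0 = stage("fit")
    best_spec, candidates = clr.select_parameterization(linked, config.model_specs())
    fit_res, design = clr.fit_model(linked, best_spec)
    selection = pd.DataFrame(
        [
            {
                "model": label,
                "aic": res.aic if isinstance(res, clr.FitResult) else np.nan,
                "loglik": res.loglik if isinstance(res, clr.FitResult) else np.nan,
                "converged": res.converged if isinstance(res, clr.FitResult) else False,
                "error": "" if isinstance(res, clr.FitResult) else str(res),
            }
            for label, res in candidates.items()
        ]
    )
    selection.to_csv(outdir / "model_selection.csv", index=False)
    with open(outdir / "fit.json", "w") as fh:
        json.dump(fit_res.to_dict(), fh, indent=2)
    report["selected_parameterization"] = best_spec.label()
    close("fit", t0, n_strata=fit_res.n_strata, selected=best_spec.label(),
          aic=fit_res.aic, converged=fit_res.converged)

    t0 = stage("effects")
    case_days = linked.loc[linked["role"] == "case", "dtmax_c" if config.exposure == "dtmax" else "dtmean_c"]
    pct = effects.exposure_percentiles(case_days, probs=config.probs, min_n=min(100, len(case_days)))
    ort = effects.or_table(fit_res, design, pct)
    ort.to_csv(outdir / "or_table.csv", index=False)
    curve = effects.response_curve(
        fit_res, design, float(case_days.min()), float(case_days.max()), config.curve_points
    )
    curve.to_csv(outdir / "curve.csv", index=False)
    close("effects", t0, n_percentiles=len(ort))

    t0 = stage("stratify")
    ice_table = ice.compute_ice_table(tracts)
    ice_cols = ["tract_id"] + [c for c in ice_table.columns if c.startswith(("ice_", "tercile_"))]
    ice_table[ice_cols].to_csv(outdir / "ice.csv", index=False)
    summaries, strat_rows, q_rows = [], [], []
    case_tract = events.set_index("event_id")["tract_id"]
    t_extreme = {"p99": float(pct.loc[0.99]), "p05": float(pct.loc[0.05])} \
        if {0.99, 0.05} <= set(pct.index) else {}
    for dim in config.stratify_by:
        summaries.append(ice.tercile_rates(events, ice_table, dim))
        tract_terc = ice_table.set_index("tract_id")[f"tercile_{dim}"]
        labels = case_tract.map(tract_terc)  # stratum_id == event_id
        fits = effects.stratified_fits(linked, labels, best_spec)
        for contrast, t_c in t_extreme.items():
            ests, ses, labs = [], [], []
            for label, (res, des) in sorted(fits.items()):
                if not isinstance(res, clr.FitResult) or not res.converged:
                    continue
                row = effects.or_at(res, des, t_c)
                strat_rows.append(
                    {
                        "dimension": dim, "tercile": label, "contrast": contrast,
                        "temp_c": t_c, "or": row.or_, "ci_low": row.ci_low,
                        "ci_high": row.ci_high, "n_strata": res.n_strata,
                    }
                )
                ests.append(row.log_or)
                ses.append(row.se)
                labs.append(label)
            if len(ests) >= 2:
                qt = effects.cochran_q(ests, ses)
                q_rows.append(
                    {
                        "dimension": dim, "contrast": contrast, "q": qt.q,
                        "df": qt.df, "p_value": qt.p_value, "strata": ";".join(map(str, labs)),
                    }
                )
    pd.concat(summaries, ignore_index=True).to_csv(outdir / "tercile_summary.csv", index=False)
    strat = pd.DataFrame(strat_rows).drop_duplicates(subset=["dimension", "tercile", "contrast"])
    strat.to_csv(outdir / "stratified.csv", index=False)
    pd.DataFrame(q_rows).to_csv(outdir / "qtests.csv", index=False)
    close("stratify", t0, n_dimensions=len(config.stratify_by), n_qtests=len(q_rows))

    report["n_events"] = int(len(events))
    report["n_strata"] = int(n_strata)
    report["n_strata_fitted"] = int(fit_res.n_strata)
    with open(outdir / "run_report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    return report
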