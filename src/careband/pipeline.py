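"""End-to-end pipeline: simulate → curate → fit → project → report.

Each stage reads and writes plain files (CSV/JSON/YAML) so stages can be
run and audited independently; a manifest records the configuration echo
and SHA-256 of every artifact.  Reruns with an identical configuration
reproduce identical numeric outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd

from . import bands, curation, gam
from .months import as_month, month_range
from .scenarios import demo_scenario
from .synth import (
    FACTORS,
    ScenarioConfig,
    generate_events,
    generate_population,
    read_events,
    read_persons,
    save_scenario,
    write_events,
    write_persons,
)

log = logging.getLogger("careband")

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """Raised with the failing stage name when a pipeline stage aborts."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


_STRATIFY_MAP = {
    "age": ("age_band",),
    "sex": ("sex",),
    "ethnicity": ("ethnicity",),
    "imd": ("imd_quintile",),
    "none": (),
}


@dataclass
class PipelineConfig:
    """Configuration of a full observed-vs-expected pipeline run."""

    out_dir: str = "careband_out"
    scenario: Optional[ScenarioConfig] = None
    factors: Sequence[str] = ()
    stratify: str = "none"  # one of age / sex / ethnicity / imd / none
    fit_start: str = "2018-11"
    fit_end: str = "2020-02"
    project_start: str = "2020-03"
    project_end: str = "2024-03"
    spline_k: int = 6
    lambda_grid: Sequence[float] = tuple(gam.DEFAULT_LAMBDA_GRID)
    periods: Sequence[bands.SummaryPeriod] = field(
        default_factory=lambda: list(bands.DEFAULT_PERIODS)
    )
    seed: int = 0
    round_disclosure: bool = False

    def validate(self) -> None:
        if self.stratify not in _STRATIFY_MAP:
            raise PipelineError(
                "config", f"stratify must be one of {sorted(_STRATIFY_MAP)}"
            )
        if as_month(self.fit_end) >= as_month(self.project_start):
            raise PipelineError("config", "fit window must precede projection window")
        lo, hi = as_month(self.project_start), as_month(self.project_end)
        for p in self.periods:
            if as_month(p.start) < lo or as_month(p.end) > hi:
                raise PipelineError(
                    "config",
                    f"period {p.label!r} lies outside the projection window",
                )
        for f in self.factors:
            if f not in FACTORS:
                raise PipelineError("config", f"unknown factor {f!r}")

    @property
    def strata_columns(self) -> Tuple[str, ...]:
        return _STRATIFY_MAP[self.stratify]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage(manifest: dict, name: str, outputs: Dict[str, Path], t0: float) -> None:
    manifest["stages"][name] = {
        "outputs": {k: str(p) for k, p in outputs.items()},
        "sha256": {k: _sha256(p) for k, p in outputs.items()},
        "seconds": round(time.perf_counter() - t0, 3),
    }
    log.info("stage %s done in %.2fs", name, time.perf_counter() - t0)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and return the artifact manifest (also written)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scenario = config.scenario or demo_scenario(seed=config.seed)
    if config.factors:
        missing = [f for f in config.factors if f not in scenario.baseline_log_rate]
        if missing:
            raise PipelineError("config", f"scenario lacks factor(s) {missing}")
    factors = list(config.factors) or list(scenario.baseline_log_rate)

    manifest: dict = {
        "config": {
            **{
                k: v
                for k, v in dataclasses.asdict(config).items()
                if k not in ("scenario", "periods", "lambda_grid")
            },
            "lambda_grid": list(config.lambda_grid),
            "periods": [dataclasses.asdict(p) for p in config.periods],
        },
        "stages": {},
    }

    # simulate ----------------------------------------------------------
    t0 = time.perf_counter()
    try:
        persons = generate_population(scenario)
        events = generate_events(persons, scenario)
        p_path, e_path, s_path = (
            out / "persons.csv",
            out / "events.csv",
            out / "scenario.yaml",
        )
        write_persons(persons, p_path)
        write_events(events, e_path)
        save_scenario(scenario, s_path)
    except Exception as exc:
        raise PipelineError("simulate", str(exc)) from exc
    _stage(manifest, "simulate", {"persons": p_path, "events": e_path,
                                  "scenario": s_path}, t0)

    # curate ------------------------------------------------------------
    t0 = time.perf_counter()
    try:
        eligible, tally = curation.apply_exclusions(persons)
        curated = curation.drop_valueless(curation.dedup_events(events))
        rates = curation.monthly_rates(
            curated,
            eligible,
            scenario.start_month,
            scenario.end_month,
            stratify=config.strata_columns,
        )
        rates = rates[rates["factor"].isin(factors)]
        tally_path = out / "exclusions.json"
        tally.to_json(tally_path)
        rates_path = out / "monthly_rates.csv"
        rates_out = rates.copy()
        if config.round_disclosure:
            rates_out["count"] = curation.disclosure_round(rates_out["count"])
            rates_out["denominator"] = curation.disclosure_round(
                rates_out["denominator"]
            )
        rates_out.to_csv(rates_path, index=False)
    except Exception as exc:
        raise PipelineError("curate", str(exc)) from exc
    _stage(manifest, "curate", {"tally": tally_path, "rates": rates_path}, t0)

    # fit ---------------------------------------------------------------
    t0 = time.perf_counter()
    models = {}
    try:
        for f in factors:
            model = gam.fit_trend_model(
                rates,
                fit_start=config.fit_start,
                fit_end=config.fit_end,
                spec=gam.CyclicBasisSpec(k=config.spline_k),
                stratify=config.strata_columns,
                lambda_grid=config.lambda_grid,
                factor=f,
            )
            models[f] = model
            model.save(out / f"model_{f}.json")
        model_paths = {f: out / f"model_{f}.json" for f in factors}
    except Exception as exc:
        raise PipelineError("fit", str(exc)) from exc
    _stage(manifest, "fit", model_paths, t0)

    # project -----------------------------------------------------------
    t0 = time.perf_counter()
    try:
        proj_months = month_range(config.project_start, config.project_end)
        band_frames = []
        for f, model in models.items():
            band = bands.expectation_band(model, proj_months)
            band.insert(0, "factor", f)
            band_frames.append(band)
        band_df = pd.concat(band_frames, ignore_index=True)
        band_path = out / "expectation_bands.csv"
        band_df.to_csv(band_path, index=False)
    except Exception as exc:
        raise PipelineError("project", str(exc)) from exc
    _stage(manifest, "project", {"bands": band_path}, t0)

    # report ------------------------------------------------------------
    t0 = time.perf_counter()
    try:
        keys = ["factor", *config.strata_columns, "month"]
        merged = band_df.merge(
            rates[keys + ["rate"]].rename(columns={"rate": "observed"}), on=keys
        )
        monthly = merged.copy()
        dev = bands.deviation(monthly["observed"], monthly["L"], monthly["U"])
        monthly = pd.concat(
            [monthly, dev.drop(columns=["observed"])], axis=1
        )
        monthly_path = out / "monthly_deviations.csv"
        monthly.to_csv(monthly_path, index=False)

        period_rows = []
        for p in config.periods:
            summary = bands.period_summary(
                monthly, p, by=["factor", *config.strata_columns]
            )
            period_rows.append(summary)
        period_df = pd.concat(period_rows, ignore_index=True)
        period_path = out / "period_deviations.csv"
        period_df.to_csv(period_path, index=False)

        try:
            from .plotting import plot_observed_vs_band

            fig_path = out / "observed_vs_band.png"
            plot_observed_vs_band(monthly, fig_path)
            figures = {"figure": fig_path}
        except Exception:  # plotting is best-effort
            figures = {}
    except Exception as exc:
        raise PipelineError("report", str(exc)) from exc
    _stage(
        manifest,
        "report",
        {"monthly": monthly_path, "periods": period_path, **figures},
        t0,
    )

    manifest_path = out / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
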