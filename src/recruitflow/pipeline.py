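"""End-to-end orchestration: from the four inputs (real CSVs or a synthetic
scenario) to the full report bundle.

Stages, in order: input validation, funnel/attrition report, recruitment
source and demographic composition tables, per-city model fit with
effectiveness and time-efficiency tables, Kruskal-Wallis/Dunn comparison of
questionnaires per participant, census representativeness report, and a
machine-readable run manifest (config, seed, package versions, input
checksums, per-stage wall time).  Model non-convergence or missing inputs
for a stage are reported and the pipeline continues with the remaining
stages.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Optional

import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

from . import io as rio
from .metrics import (
    demographics_table,
    funnel_by_city,
    participants_frame,
    source_table,
    time_efficiency,
    withdrawal_rate,
)
from .model import FitOptions, apply_peak_boost, category_effectiveness, fit_model
from .stats import GroupedValues, census_comparison, dunn_posthoc, kruskal_wallis
from .synthetic import ScenarioConfig, generate_dataset
from .types import ConfigurationError

__all__ = ["PipelineConfig", "ReportBundle", "run_pipeline"]

log = logging.getLogger("recruitflow")


class PipelineConfig(BaseModel):
    """Exactly one of {the four input CSV paths, a synthetic scenario}."""

    model_config = ConfigDict(arbitrary_types_allowed=True)

    activities_csv: Optional[str] = None
    registrations_csv: Optional[str] = None
    participants_csv: Optional[str] = None
    census_csv: Optional[str] = None
    scenario: Optional[ScenarioConfig] = None

    seed: int = 0
    boost_threshold: float = 4.0
    apply_boost: bool = True
    alpha: float = Field(default=0.05, gt=0, lt=1)
    adjust: str = "holm"
    minutes_per_post: float = 5.0
    epoch: str = rio.DEFAULT_EPOCH
    output_dir: str = "recruitflow_output"

    @model_validator(mode="after")
    def _one_input_mode(self) -> "PipelineConfig":
        real = any(
            p is not None
            for p in (
                self.activities_csv,
                self.registrations_csv,
                self.participants_csv,
                self.census_csv,
            )
        )
        if real and self.scenario is not None:
            raise ValueError("supply either input CSV paths or a scenario, not both")
        if not real and self.scenario is None:
            raise ValueError("supply input CSV paths or a synthetic scenario")
        return self


class ReportBundle:
    """Paths and in-memory tables produced by one pipeline run."""

    def __init__(self, output_dir: Path, manifest: dict, tables: dict):
        self.output_dir = output_dir
        self.manifest = manifest
        self.tables = tables

    def path(self, name: str) -> Path:
        return self.output_dir / name


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """Run every stage the supplied inputs allow and write the bundle."""
    t0 = time.perf_counter()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "config": json.loads(config.model_dump_json()),
        "versions": _versions(),
        "inputs": {},
        "stages": {},
        "outputs": [],
        "notices": [],
    }
    tables: dict = {}

    def stage(name):
        class _Timer:
            def __enter__(self):
                self.t = time.perf_counter()
                log.info("stage %s: start", name)
                return self

            def __exit__(self, *exc):
                manifest["stages"][name] = round(time.perf_counter() - self.t, 4)
                log.info("stage %s: %.3fs", name, manifest["stages"][name])
                return False

        return _Timer()

    def emit(name: str, df: pd.DataFrame) -> None:
        path = outdir / name
        df.to_csv(path, index=False)
        manifest["outputs"].append(name)
        tables[name] = df

    # ---- load or generate inputs
    with stage("inputs"):
        if config.scenario is not None:
            scenario = config.scenario.model_copy(update={"seed": config.seed})
            ds = generate_dataset(scenario)
            activities, registrations = ds.activities, ds.registrations
            participants, census = ds.participants, ds.census
            manifest["inputs"]["mode"] = "synthetic"
        else:
            manifest["inputs"]["mode"] = "files"
            report = rio.validate_inputs(
                activities=config.activities_csv,
                registrations=config.registrations_csv,
                participants=config.participants_csv,
                census=config.census_csv,
            )
            if not report.clean:
                lines = [
                    f"{d.file}:{d.line}:{d.column}: [{d.rule}] {d.message}"
                    for d in report.diagnostics
                ]
                raise ConfigurationError(
                    "input validation failed:\n" + "\n".join(lines)
                )
            activities = (
                rio.read_activities(config.activities_csv, config.epoch)
                if config.activities_csv
                else []
            )
            registrations = (
                rio.read_registrations(config.registrations_csv, config.epoch)
                if config.registrations_csv
                else []
            )
            participants = (
                rio.read_participants(config.participants_csv, config.epoch)
                if config.participants_csv
                else []
            )
            census = rio.read_census(config.census_csv) if config.census_csv else []
            for key in ("activities_csv", "registrations_csv",
                        "participants_csv", "census_csv"):
                p = getattr(config, key)
                if p:
                    manifest["inputs"][key] = {"path": p, "sha256": _sha256(p)}

    pf = participants_frame(participants) if participants else pd.DataFrame()

    # ---- funnel / attrition / withdrawal
    if participants:
        with stage("funnel"):
            emit("funnel_attrition.csv", funnel_by_city(participants))
            wd = withdrawal_rate(participants, by="city")
            overall = withdrawal_rate(participants)
            emit(
                "withdrawal.csv",
                pd.concat([wd, overall]).rename_axis("group").reset_index(),
            )
    else:
        manifest["notices"].append("no participants: funnel stage skipped")

    # ---- composition tables
    if participants:
        with stage("tables"):
            emit("source_overall.csv", source_table(participants, by="overall"))
            emit("source_by_city.csv", source_table(participants, by="city"))
            emit("demographics.csv", demographics_table(participants))

    # ---- attribution model, per city
    if activities and registrations:
        with stage("model"):
            fit_rows, eff_frames = [], []
            for series in registrations:
                city_acts = [a for a in activities if a.city == series.city]
                if not city_acts:
                    manifest["notices"].append(
                        f"no activities for city {series.city!r}: fit skipped"
                    )
                    continue
                fit = fit_model(
                    city_acts, series, FitOptions(seed=config.seed)
                )
                if config.apply_boost:
                    boosted = apply_peak_boost(
                        city_acts, series, fit, config.boost_threshold
                    )
                    if any(b.boost != a.boost for a, b in zip(city_acts, boosted)):
                        fit = fit_model(
                            boosted, series, FitOptions(seed=config.seed)
                        )
                        city_acts = boosted
                if not fit.converged:
                    manifest["notices"].append(
                        f"fit for {series.city!r} did not converge"
                    )
                eff = category_effectiveness(fit)
                eff.insert(0, "city", series.city)
                te = time_efficiency(
                    fit.per_category_predicted,
                    city_acts,
                    minutes_per_post=config.minutes_per_post,
                )
                eff["participants_per_hour"] = eff["category"].map(te)
                eff_frames.append(eff)
                fit_rows.append(
                    {
                        "city": series.city,
                        "mu": fit.params.mu,
                        "sigma": fit.params.sigma,
                        "residual_se": fit.residual_se,
                        "df": fit.df,
                        "pseudo_r2": fit.pseudo_r2,
                        "converged": fit.converged,
                    }
                )
            if fit_rows:
                emit("model_fit.csv", pd.DataFrame(fit_rows))
                emit("effectiveness.csv", pd.concat(eff_frames, ignore_index=True))
    else:
        manifest["notices"].append(
            "activities or registrations missing: model stage skipped"
        )

    # ---- questionnaires-per-participant comparisons
    if participants and pf["city"].nunique() >= 2:
        with stage("inference"):
            starters = pf[pf["baseline_started"]]
            rows = []
            for dim in ("city", "age_class", "employment", "source"):
                sub = starters[starters[dim] != "unreported"]
                if sub[dim].nunique() < 2:
                    continue
                gv = GroupedValues.from_frame(sub, "n_questionnaires", dim)
                kw = kruskal_wallis(gv)
                dunn = dunn_posthoc(gv, adjust=config.adjust, alpha=config.alpha)
                for grp, g in sub.groupby(dim):
                    vals = g["n_questionnaires"]
                    rows.append(
                        {
                            "characteristic": dim,
                            "group": grp,
                            "mean": vals.mean(),
                            "se": vals.std(ddof=1) / len(vals) ** 0.5
                            if len(vals) > 1
                            else float("nan"),
                            "letter": dunn.letters[str(grp)],
                            "kw_H": kw.H,
                            "kw_p": kw.p,
                        }
                    )
            if rows:
                emit("questionnaire_comparisons.csv", pd.DataFrame(rows))

    # ---- representativeness vs census
    if participants and census:
        with stage("census"):
            rows = []
            for cm in census:
                sub = pf[pf["city"] == cm.city]
                if sub.empty:
                    continue
                for margin, col in (("gender", "gender"), ("age", "age_class")):
                    counts = (
                        sub[sub[col] != "unreported"][col].value_counts().to_dict()
                    )
                    counts = {
                        k: v for k, v in counts.items()
                        if k in cm.margin_shares(margin)
                    }
                    if not counts:
                        continue
                    res = census_comparison(counts, cm, margin)
                    rows.append(
                        {
                            "city": cm.city,
                            "margin": margin,
                            "chi2": res.chi2,
                            "df": res.df,
                            "p": res.p,
                            "cohens_w": res.effect_size,
                            "n": res.n,
                            "representative": res.p > config.alpha,
                        }
                    )
            if rows:
                emit("census_comparison.csv", pd.DataFrame(rows))

    manifest["wall_time_s"] = round(time.perf_counter() - t0, 4)
    manifest["output_sizes"] = {
        name: (outdir / name).stat().st_size for name in manifest["outputs"]
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return ReportBundle(outdir, manifest, tables)


def _versions() -> dict:
    import numpy, pandas, scipy  # noqa: PLC0415

    from . import __version__

    return {
        "recruitflow": __version__,
        "numpy": numpy.__version__,
        "scipy": scipy.__version__,
        "pandas": pandas.__version__,
    }
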