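"""Pipeline orchestration: simulate -> cohort -> classifiers -> estimates ->
trends -> treatment standardization -> mediation, with per-stage seeds,
row-count accounting and a reproducible archived configuration.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import classifiers, cohort as cohort_mod, mediation, survey, synthetic, trends
from .errors import ConfigError, EgsDisparityError

logger = logging.getLogger(__name__)

ESTIMATE_METRICS = {
    "any_surgery": "any_surgery",
    "los_days": "los_days",
    "died": "died",
    "time_to_surgery": "time_to_surgery",
}


@dataclass
class RunConfig:
    """Full configuration of one reproducible pipeline run."""

    outdir: str
    seed: int = 0
    simulate: dict | None = None  # GeneratorConfig overrides, or None
    input_dir: str | None = None  # existing dataset directory
    diagnoses: list = field(default_factory=lambda: ["cholecystitis"])
    codemap_path: str | None = None
    hospital_aggregates: bool = True
    run_trends: bool = True
    run_mediation: bool = True
    mediation_outcomes: list = field(default_factory=lambda: ["los", "mortality"])
    sensitivity: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))


def _stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31 derived from the global one."""
    import zlib

    ss = np.random.SeedSequence([seed, zlib.crc32(stage.encode())])
    return int(ss.generate_state(1)[0] % (2**31))


def prepare_mediation_frame(
    cohort: pd.DataFrame,
    hospitals: pd.DataFrame,
    design: survey.SurveyDesign,
    codemap: cohort_mod.CodeMap,
    hospital_aggregates: bool = True,
):
    """Attach the empirically derived covariates the mediation models need.

    Adds: diagnosis severity subgroup, crude comorbidity score, hospital
    attributes (prefixed ``hosp_``), hospital aggregates (operative rate and
    mean LOS; zeroed contextual placeholders when hospital statistics are
    disabled, mirroring years where hospital identifiers are uninformative),
    and ``time_to_surgery_filled`` (0 for non-operated stays, whose surgery
    indicator carries the information).
    """
    out = cohort.copy()
    dxmap = classifiers.fit_dx_subgroups(out, design, allow_single_group=True)
    out["dx_subgroup"] = dxmap.assign(out)
    cm_cols = {name: cols[0] for name, cols in codemap.comorbidities.items()}
    score = classifiers.fit_comorbidity_score(out, design, cm_cols)
    out["comorb_score"] = score.score(out)
    hosp = hospitals.rename(columns={
        "size": "hosp_size", "ownership": "hosp_ownership",
        "region": "hosp_region", "type": "hosp_type",
    })
    keep = ["hospital_id", "hosp_size", "hosp_ownership", "hosp_region", "hosp_type"]
    out = out.merge(hosp[[c for c in keep if c in hosp.columns]],
                    on="hospital_id", how="left")
    if hospital_aggregates:
        agg = classifiers.compute_hospital_aggregates(out, design)
        out = classifiers.join_hospital_aggregates(out, agg, design)
    else:
        out["hosp_operative_rate"] = 0.0
        out["hosp_mean_los"] = 0.0
    out["time_to_surgery_filled"] = out["time_to_surgery"].fillna(0.0)
    return out, dxmap, score


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full pipeline and write a report bundle to ``outdir``.

    Returns a summary dict (also written as ``summary.json``).  Any stage
    failure aborts with the stage named; partial outputs stay on disk.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "run_config.yaml")
    run_log: dict = {"seed": config.seed, "stages": {}}
    summary: dict = {"diagnoses": {}}

    # --- stage: data -----------------------------------------------------
    stage = "simulate" if config.input_dir is None else "load"
    try:
        if config.input_dir is None:
            overrides = dict(config.simulate or {})
            overrides.setdefault("seed", _stage_seed(config.seed, "simulate"))
            gen_cfg = synthetic.GeneratorConfig(**overrides)
            discharges, hospitals, truth = synthetic.generate_dataset(gen_cfg)
            data_dir = outdir / "dataset"
            data_dir.mkdir(exist_ok=True)
            synthetic.write_dataset(discharges, hospitals, truth, data_dir)
        else:
            if not Path(config.input_dir).exists():
                raise ConfigError(f"input_dir does not exist: {config.input_dir}")
            discharges, hospitals, truth = synthetic.read_dataset(config.input_dir)
    except EgsDisparityError:
        run_log["failed_stage"] = stage
        (outdir / "run_log.json").write_text(json.dumps(run_log, indent=2))
        raise
    run_log["stages"][stage] = {"n_discharges": len(discharges),
                                "n_hospitals": len(hospitals)}

    codemaps = cohort_mod.load_codemaps(config.codemap_path)
    design = survey.SurveyDesign(weight="discwt")
    trend_design = survey.SurveyDesign(weight="trendwt")

    for dx in config.diagnoses:
        if dx not in codemaps:
            raise ConfigError(f"no codemap for diagnosis {dx!r}")
        dx_dir = outdir / dx
        dx_dir.mkdir(exist_ok=True)
        dx_summary: dict = {}
        acc: dict = {}
        co = cohort_mod.build_cohort(discharges, codemaps[dx], log=acc)
        run_log["stages"][f"cohort[{dx}]"] = acc
        co, dxmap, score = prepare_mediation_frame(
            co, hospitals, design, codemaps[dx],
            hospital_aggregates=config.hospital_aggregates,
        )
        co.to_csv(dx_dir / "cohort.csv", index=False, float_format="%.10g")
        dxmap.to_yaml(dx_dir / "dx_subgroups.yaml")
        score.to_yaml(dx_dir / "comorbidity_score.yaml")

        # Table-2-style age-adjusted estimates
        standard = survey.AgeStandard.from_cohort(co, design)
        rows = []
        for label, column in ESTIMATE_METRICS.items():
            try:
                cmp_ = survey.compare_groups(co, column, design, standard)
            except EgsDisparityError as exc:
                logger.warning("estimate %s skipped for %s: %s", label, dx, exc)
                continue
            rows.append({
                "diagnosis": dx, "variable": label,
                "black": cmp_.estimate_a.value, "black_se": cmp_.estimate_a.se,
                "white": cmp_.estimate_b.value, "white_se": cmp_.estimate_b.se,
                "difference": cmp_.difference.value,
                "difference_se": cmp_.difference.se, "p_value": cmp_.p_value,
            })
            dx_summary[f"{label}_disparity"] = cmp_.difference.value
        pd.DataFrame(rows).to_csv(dx_dir / "estimates.csv", index=False,
                                  float_format="%.10g")

        # treatment standardization of LOS among operated stays
        operated = co.loc[co["any_surgery"] == 1].copy()
        if len(operated):
            operated["tts_band"] = np.minimum(
                operated["time_to_surgery"].fillna(0), 7
            ).astype(int)
            std_result = survey.standardize_for_treatment(
                operated, design, ["tts_band", "surgery_category"],
                outcome="los_days",
            )
            pd.DataFrame([{
                "diagnosis": dx,
                "unadjusted": std_result.unadjusted.value,
                "unadjusted_se": std_result.unadjusted.se,
                "adjusted": std_result.adjusted.value,
                "adjusted_se": std_result.adjusted.se,
                "percent_change": std_result.percent_change,
            }]).to_csv(dx_dir / "los_standardization.csv", index=False,
                       float_format="%.10g")
            dx_summary["los_percent_explained_by_treatment"] = std_result.percent_change

        if config.run_trends and co["year"].nunique() >= 3:
            try:
                series = trends.build_series(co, trend_design, "any_surgery")
                fit = trends.fit_trend(series)
                series.table.to_csv(dx_dir / "trend_series.csv", index=False,
                                    float_format="%.10g")
                pd.DataFrame([dataclasses.asdict(fit)]).to_csv(
                    dx_dir / "trend_summary.csv", index=False,
                    float_format="%.10g")
                dx_summary["trend_slope_per_year"] = fit.slope
                dx_summary["years_to_closure"] = fit.years_to_closure
            except EgsDisparityError as exc:
                logger.warning("trend stage skipped for %s: %s", dx, exc)

        if config.run_mediation:
            groups = mediation.FactorGroups()
            med_out = {}
            for oname in config.mediation_outcomes:
                try:
                    dec = mediation.decompose(co, oname, groups, design)
                except EgsDisparityError as exc:
                    logger.warning("mediation %s skipped for %s: %s", oname, dx, exc)
                    continue
                med_out[oname] = dec.to_dict()
                if config.sensitivity:
                    sens = mediation.sensitivity_suite(co, oname, groups, design)
                    med_out[oname]["sensitivity"] = {
                        k: v.to_dict() for k, v in sens.items()
                    }
            (dx_dir / "mediation.json").write_text(json.dumps(med_out, indent=2))
            summary_rows = []
            for oname, dec in med_out.items():
                for comp, val in (("total", dec["total"]),
                                  ("direct", dec["direct"]),
                                  *[(f"unique_{g}", v) for g, v in dec["unique"].items()],
                                  ("overlap", dec["overlap"])):
                    summary_rows.append({
                        "diagnosis": dx, "outcome": oname, "component": comp,
                        "link_scale": val,
                        "ratio_scale": dec["ratio_scale"].get(comp),
                    })
            pd.DataFrame(summary_rows).to_csv(
                dx_dir / "mediation_summary.csv", index=False,
                float_format="%.10g")
            dx_summary["mediation"] = {
                k: {kk: v[kk] for kk in ("total", "direct", "overlap", "unique")}
                for k, v in med_out.items()
            }
        summary["diagnoses"][dx] = dx_summary

    (outdir / "run_log.json").write_text(json.dumps(run_log, indent=2))
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2))
    return summary
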