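"""End-to-end orchestration: minutes -> sleep timing -> hourly features ->
outcomes/covariates -> exclusion cascade -> survey-weighted window scans.

`run` is the single entry point used by the CLI, the analysis drivers and the
tests. It accepts either file inputs (the documented CSV dialects) or a
simulation configuration, executes every stage in order while logging
participant counts, and writes the full set of result tables plus a JSON run
manifest into the output directory.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .errors import ConfigError, UsageError
from . import ingest_qc, sleep_timing, hourly_features, outcomes_covariates as oc
from .association_models import SurveyDesign, run_window_scan, run_subgroups_and_sensitivity, table2_layout
from .synthetic_data import SimConfig, simulate_cohort


@dataclass
class RunConfig:
    """One pipeline run: exactly one input source, one analysis."""

    sim: SimConfig | None = None
    minutes_path: str | None = None
    participants_path: str | None = None
    dialect: str = "csv"
    analysis: str = "diabetes"
    framings: tuple[str, ...] = ("relative", "clock")
    include_bmi: bool = True
    variance: str = "taylor"
    subgroups: bool = False
    sensitivity: bool = False
    out_dir: str = "results/run"
    seed: int = 0

    def validate(self) -> None:
        has_files = self.minutes_path is not None and self.participants_path is not None
        if (self.sim is None) == (not has_files):
            raise ConfigError("exactly one input source required (sim config or file paths)")
        if self.analysis not in ingest_qc.ANALYSES:
            raise UsageError(f"unknown analysis {self.analysis!r}")
        for f in self.framings:
            if f not in ("relative", "clock"):
                raise UsageError(f"unknown framing {f!r}")


OUTCOME_COLUMN = {
    "diabetes": "diabetes",
    "fasting_glucose": "log_fasting_glucose",
    "fasting_insulin": "log_fasting_insulin",
    "homa_ir": "log_homa_ir",
    "ogtt": "log_ogtt_2h_glucose",
}


def _log(handle, stage: str, **fields) -> None:
    handle.write(json.dumps({"stage": stage, **fields}) + "\n")
    handle.flush()


def prepare_participants(participants: pd.DataFrame, include_bmi: bool = True) -> pd.DataFrame:
    """Derive outcomes and encode covariates on the raw participant table."""
    p = participants.copy()
    p["diabetes"] = oc.derive_diabetes(p["hba1c"], p["diabetes_selfreport"]).astype(object)
    if "fasting_insulin" in p.columns and "survey_cycle" in p.columns:
        p["fasting_insulin"] = oc.harmonize_insulin(p["fasting_insulin"].to_numpy(), p["survey_cycle"].to_numpy())
    if {"fasting_glucose", "fasting_insulin"}.issubset(p.columns):
        g = p["fasting_glucose"].to_numpy(dtype=float)
        i = p["fasting_insulin"].to_numpy(dtype=float)
        homa = np.full(len(p), np.nan)
        ok = np.isfinite(g) & np.isfinite(i)
        homa[ok] = g[ok] * i[ok] / oc.HOMA_IR_DENOMINATOR
        p["homa_ir"] = homa
    p = oc.transform_outcomes(p)
    p = oc.encode_covariates(p, include_bmi=include_bmi)
    return p


def outcome_availability(p: pd.DataFrame, analysis: str) -> pd.Series:
    """Availability (and OGTT eligibility) of the analysis outcome."""
    col = OUTCOME_COLUMN[analysis]
    avail = p[col].notna() if col in p.columns else pd.Series(False, index=p.index)
    if "fasting_subsample" in p.columns and analysis != "diabetes":
        avail &= p["fasting_subsample"].fillna(False).astype(bool)
    if analysis == "ogtt" and "ogtt_eligible" in p.columns:
        avail &= p["ogtt_eligible"].fillna(False).astype(bool)
    avail.index = p["participant_id"]
    return avail


def run(config: RunConfig) -> Path:
    """Execute the full pipeline; returns the output directory."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log = open(out / "log.jsonl", "w")

    truth = None
    if config.sim is not None:
        sim_cfg = dataclasses.replace(config.sim, seed=config.seed)
        minutes, participants, truth = simulate_cohort(sim_cfg)
        _log(log, "simulate", n_participants=int(participants.shape[0]), n_minutes=int(minutes.shape[0]))
    else:
        minutes, report = ingest_qc.read_minute_records(config.minutes_path, config.dialect)
        participants = ingest_qc.read_participants(config.participants_path)
        _log(log, "ingest", n_rows=report.n_rows, n_participants=report.n_participants,
             n_unknown_wear=report.n_unknown_wear)

    minutes = ingest_qc.flag_valid_minutes(minutes)
    day_validity = ingest_qc.summarize_day_validity(minutes)
    _log(log, "day_validity", n_valid_days=int(day_validity["is_valid_day"].sum()))

    nights = sleep_timing.nightly_sleep_windows(minutes)
    sleep_summary = sleep_timing.summarize_sleep(nights)
    sleep_timing.write_sleep_tables(nights, sleep_summary, out / "sleep_nights.tsv", out / "sleep_summary.tsv")
    _log(log, "sleep_timing", n_nights=int(len(nights)), n_with_summary=int(len(sleep_summary)))

    mid_clock = pd.Series(
        sleep_timing.axis_to_clock_minutes(sleep_summary["overall_midpoint"]),
        index=sleep_summary["participant_id"],
    )
    clock_means = hourly_features.hourly_means_clock(minutes, day_validity)
    rel_means = hourly_features.hourly_means_relative(minutes, day_validity, mid_clock)
    total = hourly_features.total_activity(minutes, day_validity)
    sleep_dur = hourly_features.sleep_duration(minutes, day_validity)
    features = hourly_features.feature_matrix(clock_means, rel_means, total, sleep_dur)
    hourly_features.write_feature_matrix(features, out / "features.tsv")
    _log(log, "features", n_participants=int(len(features)))

    p = prepare_participants(participants, include_bmi=config.include_bmi)
    avail = outcome_availability(p, config.analysis)
    rel_profile = features[["participant_id"] + [f"rel_h{k:02d}" for k in range(1, 25)]]
    cohort, audit = ingest_qc.apply_exclusion_cascade(p, day_validity, rel_profile, avail, config.analysis)
    ingest_qc.write_audit(audit, out / "audit.tsv")
    counts = audit["exclusion_reason"].value_counts().to_dict()
    _log(log, "cascade", n_input=int(len(audit)), n_included=int(audit["included"].sum()), reasons=counts)

    ids = cohort["participant_id"]
    feat = features.set_index("participant_id").loc[ids]
    pc = cohort.set_index("participant_id")

    model_frame = pc[[c for c in oc.model_covariate_columns(pc, config.include_bmi)
                      if c not in ("sleep_duration_cat", "sleep_midpoint_cont", "total_pa")]].copy()
    model_frame["sleep_duration_cat"] = pd.Categorical(
        feat["sleep_duration_cat"], categories=oc.SLEEP_DURATION_LEVELS
    )
    summary_idx = sleep_summary.set_index("participant_id")["overall_midpoint"].reindex(ids)
    model_frame["sleep_midpoint_cont"] = summary_idx.to_numpy()
    model_frame["total_pa"] = feat["total_mims_per_day"]

    weight_col = f"weight_{config.analysis}" if f"weight_{config.analysis}" in pc.columns else "weight"
    design = SurveyDesign(
        weights=pc[weight_col].astype(float),
        stratum=pc["stratum"] if "stratum" in pc.columns else None,
        psu=pc["psu"] if "psu" in pc.columns else None,
    )

    if config.analysis == "diabetes":
        y = pc["diabetes"].astype(float)
        family = "logistic"
    else:
        y = pc[OUTCOME_COLUMN[config.analysis]].astype(float)
        family = "linear"

    for framing in config.framings:
        grid = run_window_scan(feat, y, model_frame, design, framing, family, config.variance)
        grid.to_csv(out / f"scan_{framing}.tsv", sep="\t", index=False)
        table2_layout(grid, logistic=(family == "logistic")).to_csv(
            out / f"table_{framing}.tsv", sep="\t", index=False
        )
        curve = grid[grid["quintile"] == 5][["window_index", "estimate", "ci_low", "ci_high", "status"]]
        curve.to_csv(out / f"curve_{framing}.tsv", sep="\t", index=False)
        _log(log, "scan", framing=framing, n_ok=int((grid["status"] == "ok").sum()))

    if config.subgroups or config.sensitivity:
        strata = pd.DataFrame(index=pc.index)
        strata["gender"] = pc["gender"]
        strata["age"] = pc["age"]
        if "race_ethnicity" in pc.columns:
            strata["race_ethnicity"] = pc["race_ethnicity"]
        wk = sleep_summary.set_index("participant_id")["weekend_midpoint"].reindex(ids)
        strata["weekend_midpoint"] = wk.to_numpy()
        extra = run_subgroups_and_sensitivity(
            feat, y, model_frame, design, strata, feat["sleep_duration_h"],
            framing=config.framings[0], family=family, variance=config.variance,
        )
        if config.subgroups and "subgroups" in extra:
            extra["subgroups"].to_csv(out / "subgroups.tsv", sep="\t", index=False)
            _log(log, "subgroups", n_rows=int(len(extra["subgroups"])))
        if config.sensitivity:
            extra["sensitivity"].to_csv(out / "sensitivity.tsv", sep="\t", index=False)
            _log(log, "sensitivity", n_rows=int(len(extra["sensitivity"])))

    if truth is not None:
        truth.to_csv(out / "sim_truth.tsv", sep="\t", index=False)

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "analysis": config.analysis,
        "config": _config_dict(config),
        "config_hash": _config_hash(config),
        "counts": {
            "input_participants": int(len(audit)),
            "included": int(audit["included"].sum()),
            "excluded_by_reason": counts,
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    log.close()
    return out


def _config_dict(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    return d


def _config_hash(config: RunConfig) -> str:
    payload = json.dumps(_config_dict(config), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]
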