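"""Ingest minute-level actigraphy and participant tables; apply validity rules
and the study exclusion cascade.

The minute-level layout mirrors the public NHANES minute summary files: one row
per participant-minute carrying a MIMS (monitor-independent movement summary)
value and an upstream wear classification (wake wear / sleep wear / non-wear).
A *valid minute* is one labelled wake or sleep wear and not quality-flagged; a
*valid day* is a midnight-to-midnight calendar day with at least 20 h (1200
minutes) of valid data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataError, FormatError, UsageError

WAKE_WEAR = "wake_wear"
SLEEP_WEAR = "sleep_wear"
NON_WEAR = "non_wear"
UNKNOWN = "unknown"

WEAR_CLASSES = (WAKE_WEAR, SLEEP_WEAR, NON_WEAR, UNKNOWN)

#: Accepted spellings for wear-class codes in input files. Numeric codes follow
#: the NHANES minute-summary convention (1 wake, 2 sleep, 3 non-wear).
WEAR_CODE_MAP = {
    "wake": WAKE_WEAR,
    "wake_wear": WAKE_WEAR,
    "1": WAKE_WEAR,
    "sleep": SLEEP_WEAR,
    "sleep_wear": SLEEP_WEAR,
    "2": SLEEP_WEAR,
    "nonwear": NON_WEAR,
    "non_wear": NON_WEAR,
    "non-wear": NON_WEAR,
    "3": NON_WEAR,
    "unknown": UNKNOWN,
}

MINUTE_COLUMNS = ["participant_id", "timestamp", "mims", "wear_class", "quality_flag"]

#: Minimum count of valid minutes for a valid day (20 h).
VALID_DAY_MINUTES = 1200

#: Exclusion reasons in precedence order; an excluded participant gets the
#: first reason that applies.
EXCLUSION_ORDER = [
    "age_le_20",
    "pregnant",
    "lt_4_valid_days",
    "missing_hourly_window",
    "unknown_diabetes",
    "missing_outcome",
    "on_diabetes_medication",
]

ANALYSES = ("diabetes", "fasting_glucose", "fasting_insulin", "homa_ir", "ogtt")

#: Analyses run on the morning-exam biomarker subsample, which add the
#: missing-outcome and diabetes-medication exclusions on top of the main cascade.
BIOMARKER_ANALYSES = ("fasting_glucose", "fasting_insulin", "homa_ir", "ogtt")


@dataclass
class LoadReport:
    """Summary of one minute-file load."""

    n_rows: int
    n_participants: int
    n_unknown_wear: int


def read_minute_records(path, dialect: str = "csv") -> tuple[pd.DataFrame, LoadReport]:
    """Read a minute-level file into the normalised minute table.

    Parameters
    ----------
    path
        CSV (canonical) or SAS-transport file with columns ``participant_id``,
        ``timestamp`` (ISO-8601, minute resolution), ``mims``, ``wear_class``,
        ``quality_flag``.
    dialect
        ``"csv"`` or ``"xpt"``.

    Returns
    -------
    (minutes, report)
        ``minutes`` sorted by (participant_id, timestamp) with wear codes
        normalised to :data:`WEAR_CLASSES`; unrecognised codes map to
        ``unknown`` and are counted in ``report``.
    """
    if dialect == "csv":
        df = pd.read_csv(path, dtype={"participant_id": str})
    elif dialect == "xpt":
        df = pd.read_sas(path, format="xport")
        df["participant_id"] = df["participant_id"].astype(str)
    else:
        raise UsageError(f"unknown dialect {dialect!r}; expected 'csv' or 'xpt'")

    for col in MINUTE_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"minute file missing required column {col!r}")

    df = df.loc[:, MINUTE_COLUMNS].copy()
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    codes = df["wear_class"].astype(str).str.strip().str.lower()
    mapped = codes.map(WEAR_CODE_MAP)
    n_unknown = int(mapped.isna().sum() + (mapped == UNKNOWN).sum())
    df["wear_class"] = mapped.fillna(UNKNOWN)
    df["quality_flag"] = df["quality_flag"].astype(bool)
    df["mims"] = pd.to_numeric(df["mims"])

    df = df.sort_values(["participant_id", "timestamp"], kind="mergesort")
    df = df.reset_index(drop=True)
    # strict monotonicity within participant: duplicated minutes are a data error
    dup = df.duplicated(subset=["participant_id", "timestamp"])
    if dup.any():
        pid = df.loc[dup.idxmax(), "participant_id"]
        raise DataError(f"non-monotone timestamps for participant {pid!r}")

    worn = df["wear_class"].isin([WAKE_WEAR, SLEEP_WEAR])
    bad = worn & (~np.isfinite(df["mims"]) | (df["mims"] < 0))
    if bad.any():
        raise DataError("negative or non-finite MIMS on a worn minute")

    report = LoadReport(
        n_rows=len(df),
        n_participants=df["participant_id"].nunique(),
        n_unknown_wear=n_unknown,
    )
    return df, report


def read_participants(path) -> pd.DataFrame:
    """Read the participant-level table (one row per participant)."""
    df = pd.read_csv(path, dtype={"participant_id": str})
    if "participant_id" not in df.columns:
        raise FormatError("participant file missing required column 'participant_id'")
    if df["participant_id"].duplicated().any():
        raise DataError("duplicated participant_id in participant table")
    return df


def flag_valid_minutes(minutes: pd.DataFrame) -> pd.DataFrame:
    """Add ``is_valid``: worn (wake or sleep wear) and not quality-flagged.

    Non-wear, unknown and quality-flagged minutes are invalid; their MIMS
    values never enter any downstream mean.
    """
    out = minutes.copy()
    worn = out["wear_class"].isin([WAKE_WEAR, SLEEP_WEAR])
    out["is_valid"] = worn & ~out["quality_flag"].astype(bool)
    return out


def summarize_day_validity(minutes: pd.DataFrame) -> pd.DataFrame:
    """One row per participant-day with the valid-minute count and day validity.

    Days are midnight-to-midnight on the local clock. ``is_valid_day`` is true
    iff the day has at least :data:`VALID_DAY_MINUTES` valid minutes.
    """
    if "is_valid" not in minutes.columns:
        raise UsageError("minutes must be flagged by flag_valid_minutes first")
    day = minutes["timestamp"].dt.normalize()
    g = minutes.assign(date=day).groupby(["participant_id", "date"], observed=True)
    out = g["is_valid"].sum().astype(int).rename("valid_minutes").reset_index()
    out["is_valid_day"] = out["valid_minutes"] >= VALID_DAY_MINUTES
    return out


def count_valid_days(day_validity: pd.DataFrame) -> pd.Series:
    """Valid-day count per participant (0 for participants with no valid day)."""
    return day_validity.groupby("participant_id", observed=True)["is_valid_day"].sum().astype(int)


def apply_exclusion_cascade(
    participants: pd.DataFrame,
    day_validity: pd.DataFrame,
    hourly_profiles: pd.DataFrame,
    outcome_availability: pd.Series | None,
    analysis: str = "diabetes",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the study exclusion cascade and return (cohort, audit).

    The cascade runs in a fixed precedence order: age at or below 20 years;
    pregnancy; fewer than 4 valid actigraphy days; any missing hourly activity
    window; unknown diabetes status; and, for the biomarker analyses only,
    missing outcome and current diabetes medication. A participant meeting
    several criteria is recorded once, under the first triggered reason.

    Parameters
    ----------
    participants
        One row per participant; must carry ``age``, ``pregnant``,
        ``diabetes`` (boolean, NaN = unknown) and, for biomarker analyses,
        ``diabetes_medication``.
    day_validity
        Output of :func:`summarize_day_validity`.
    hourly_profiles
        Wide per-participant frame whose non-id columns are the 24 hourly-mean
        columns of the analysis framing; NaN marks a missing window.
        Participants absent from the frame count as missing all windows.
    outcome_availability
        Boolean Series indexed by participant_id: outcome measured (and, for
        the OGTT, protocol-eligible). Ignored for the diabetes analysis.
    analysis
        One of ``diabetes``, ``fasting_glucose``, ``fasting_insulin``,
        ``homa_ir``, ``ogtt``.
    """
    if analysis not in ANALYSES:
        raise UsageError(f"unknown analysis {analysis!r}; expected one of {ANALYSES}")

    p = participants.set_index("participant_id")
    n_days = count_valid_days(day_validity).reindex(p.index).fillna(0).astype(int)

    prof = hourly_profiles.set_index("participant_id")
    value_cols = [c for c in prof.columns if c != "participant_id"]
    has_all = (~prof[value_cols].isna().any(axis=1)).reindex(p.index).fillna(False)

    diabetes = p["diabetes"] if "diabetes" in p.columns else pd.Series(np.nan, index=p.index)

    checks = {
        "age_le_20": p["age"] <= 20,
        "pregnant": p.get("pregnant", pd.Series(False, index=p.index)).fillna(False).astype(bool),
        "lt_4_valid_days": n_days < 4,
        "missing_hourly_window": ~has_all,
        "unknown_diabetes": diabetes.isna(),
    }
    if analysis in BIOMARKER_ANALYSES:
        if outcome_availability is None:
            avail = pd.Series(False, index=p.index)
        else:
            avail = outcome_availability.reindex(p.index).fillna(False).astype(bool)
        med = p.get("diabetes_medication", pd.Series(False, index=p.index))
        checks["missing_outcome"] = ~avail
        checks["on_diabetes_medication"] = med.fillna(False).astype(bool)

    reason = pd.Series("none", index=p.index, dtype=object)
    for name in EXCLUSION_ORDER:
        if name not in checks:
            continue
        hit = checks[name].astype(bool) & (reason == "none")
        reason[hit] = name

    audit = pd.DataFrame(
        {
            "participant_id": p.index,
            "included": (reason == "none").to_numpy(),
            "exclusion_reason": reason.to_numpy(),
            "n_valid_days": n_days.to_numpy(),
        }
    )
    cohort = participants[participants["participant_id"].isin(audit.loc[audit["included"], "participant_id"])]
    return cohort.reset_index(drop=True), audit


def write_audit(audit: pd.DataFrame, path) -> None:
    audit.to_csv(path, sep="\t", index=False)
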