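"""Hourly activity exposures: clock-time and sleep-midpoint-relative hourly
mean MIMS, total daily activity, sleep duration, and quintile coding.

Hourly windows are half-open and labelled by their ending hour: clock window 1
is (00:00, 01:00] (i.e. minutes stamped 00:01-01:00) and relative window k is
(midpoint + (k-1) h, midpoint + k h], anchored at the participant's overall
average sleep midpoint replicated on every calendar day. Means pool valid
minutes across valid days (minute-weighted); a window is missing iff no valid
minute falls in it over the whole recording.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import DataError, UsageError
from .ingest_qc import SLEEP_WEAR

CLOCK_PREFIX = "clock_h"
REL_PREFIX = "rel_h"


def _clock_window(minute_of_day: np.ndarray) -> np.ndarray:
    """Window 1..24 for integer minutes after midnight; minute 00:00 -> 24."""
    return ((minute_of_day - 1) % 1440) // 60 + 1


def _relative_window(minute_of_day: np.ndarray, midpoint_clock_min: np.ndarray) -> np.ndarray:
    """Window 1..24 by minutes elapsed since the (possibly fractional) midpoint.

    Half-open interval arithmetic: a minute exactly at the midpoint closes
    window 24; a minute in (midpoint, midpoint + 60] falls in window 1.
    """
    delta = np.mod(minute_of_day - midpoint_clock_min, 1440.0)
    delta = np.where(delta == 0.0, 1440.0, delta)
    return np.ceil(delta / 60.0).astype(int)


def _valid_on_valid_days(minutes: pd.DataFrame, day_validity: pd.DataFrame) -> pd.DataFrame:
    if "is_valid" not in minutes.columns:
        raise UsageError("minutes must be flagged by flag_valid_minutes first")
    ok_days = day_validity.loc[day_validity["is_valid_day"], ["participant_id", "date"]]
    sub = minutes.assign(date=minutes["timestamp"].dt.normalize())
    sub = sub.merge(ok_days, on=["participant_id", "date"], how="inner")
    return sub[sub["is_valid"]]


def _pivot_means(sub: pd.DataFrame, window: np.ndarray, prefix: str, participants) -> pd.DataFrame:
    means = sub.assign(window=window).groupby(["participant_id", "window"], observed=True)["mims"].mean()
    wide = means.unstack("window")
    wide = wide.reindex(index=participants, columns=range(1, 25))
    wide.columns = [f"{prefix}{k:02d}" for k in range(1, 25)]
    return wide.reset_index().rename(columns={"index": "participant_id"})


def hourly_means_clock(minutes: pd.DataFrame, day_validity: pd.DataFrame) -> pd.DataFrame:
    """24 clock-anchored hourly mean MIMS per participant (NaN = missing window)."""
    participants = minutes["participant_id"].unique()
    sub = _valid_on_valid_days(minutes, day_validity)
    mod = (sub["timestamp"].dt.hour * 60 + sub["timestamp"].dt.minute).to_numpy()
    return _pivot_means(sub, _clock_window(mod), CLOCK_PREFIX, participants)


def hourly_means_relative(
    minutes: pd.DataFrame, day_validity: pd.DataFrame, midpoint_clock_min: pd.Series
) -> pd.DataFrame:
    """24 sleep-midpoint-relative hourly mean MIMS per participant.

    ``midpoint_clock_min`` maps participant_id to the overall sleep midpoint
    in (possibly fractional) minutes after midnight; participants with a
    missing midpoint get all 24 windows missing.
    """
    participants = minutes["participant_id"].unique()
    sub = _valid_on_valid_days(minutes, day_validity)
    mid = sub["participant_id"].map(midpoint_clock_min).to_numpy(dtype=float)
    has_mid = np.isfinite(mid)
    sub = sub[has_mid]
    mid = mid[has_mid]
    mod = (sub["timestamp"].dt.hour * 60 + sub["timestamp"].dt.minute).to_numpy()
    return _pivot_means(sub, _relative_window(mod, mid), REL_PREFIX, participants)


def total_activity(minutes: pd.DataFrame, day_validity: pd.DataFrame) -> pd.Series:
    """Average of the daily sum of per-minute MIMS over valid days (MIMS/day)."""
    sub = _valid_on_valid_days(minutes, day_validity)
    daily = sub.groupby(["participant_id", "date"], observed=True)["mims"].sum()
    out = daily.groupby("participant_id", observed=True).mean().rename("total_mims_per_day")
    return out.reindex(minutes["participant_id"].unique())


def sleep_duration(minutes: pd.DataFrame, day_validity: pd.DataFrame) -> pd.DataFrame:
    """Mean daily sleep-wear hours over valid days, with the <7 / 7-9 / >9 bands.

    The middle band is closed on both ends (7 <= h <= 9).
    """
    sub = _valid_on_valid_days(minutes, day_validity)
    sleep_min = (
        sub.assign(is_sleep=sub["wear_class"] == SLEEP_WEAR)
        .groupby(["participant_id", "date"], observed=True)["is_sleep"]
        .sum()
    )
    hours = (sleep_min.groupby("participant_id", observed=True).mean() / 60.0).rename("sleep_duration_h")
    out = hours.reindex(minutes["participant_id"].unique()).to_frame()
    out["sleep_duration_cat"] = sleep_duration_category(out["sleep_duration_h"])
    out.index.name = "participant_id"
    return out.reset_index()


def sleep_duration_category(hours) -> pd.Series:
    h = pd.Series(hours, dtype=float)
    cat = pd.Series(pd.NA, index=h.index, dtype=object)
    cat[h < 7] = "lt_7"
    cat[(h >= 7) & (h <= 9)] = "7_to_9"
    cat[h > 9] = "gt_9"
    return cat


def assign_quintiles(values: pd.Series) -> pd.Series:
    """Quintile 1 (lowest) .. 5 by the 20/40/60/80th percentiles of the sample.

    Cut-points are unweighted percentiles of the non-missing values; ties share
    the quintile of their common value. Missing values get missing quintiles.
    Raises when fewer than 5 non-missing values are supplied.
    """
    v = pd.Series(values, dtype=float)
    obs = v.dropna()
    if len(obs) < 5:
        raise DataError("quintile assignment needs at least 5 non-missing values")
    cuts = np.percentile(obs.to_numpy(), [20, 40, 60, 80])
    arr = v.to_numpy()
    with np.errstate(invalid="ignore"):
        q = 1 + sum((arr > c).astype(float) for c in cuts)
    q = pd.Series(q, index=v.index)
    q[v.isna()] = np.nan
    return q


def feature_matrix(
    clock_means: pd.DataFrame,
    relative_means: pd.DataFrame,
    total_mims: pd.Series,
    sleep: pd.DataFrame,
) -> pd.DataFrame:
    """Assemble the per-participant feature matrix (one row per participant)."""
    out = clock_means.merge(relative_means, on="participant_id", how="outer")
    out = out.merge(total_mims.rename("total_mims_per_day"), left_on="participant_id", right_index=True, how="left")
    out = out.merge(sleep, on="participant_id", how="left")
    return out


def write_feature_matrix(features: pd.DataFrame, path) -> None:
    features.to_csv(path, sep="\t", index=False, float_format="%.6g")
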