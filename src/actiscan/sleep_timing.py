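"""Rolling-window sleep onset/offset detection and sleep-midpoint summaries.

Sleep is searched for between 20:00 and 10:00 the next morning (the *night
axis*: minute index 0 at 20:00 through 839 at 09:59), which deliberately
ignores severely misaligned schedules such as shift work. Onset is the first
sleep-wear minute inside the first forward-rolling 30-minute window that
contains at least 15 sleep-wear minutes; offset mirrors the rule backward from
10:00. A participant's overall sleep midpoint is the midpoint between the
averaged onset and offset across nights; the weekend midpoint (Friday and
Saturday nights) proxies chronotype.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .ingest_qc import SLEEP_WEAR

#: Night axis: minutes since 20:00; index 839 is 09:59 the next day.
NIGHT_LEN = 840
NIGHT_START_MINUTE = 20 * 60  # minutes after midnight

ROLL_WINDOW = 30
ROLL_THRESHOLD = 15


def detect_onset(is_sleep: np.ndarray) -> int | None:
    """First sleep minute within the first qualifying forward 30-min window.

    ``is_sleep`` is a boolean array over the night axis (length 840); minutes
    missing from the record must be filled as False. Windows ``[s, s+29]``
    advance one minute at a time from 20:00; the first containing
    >= 15 sleep-wear minutes selects the onset. Returns None when no window
    qualifies.
    """
    s = np.asarray(is_sleep, dtype=bool)
    if s.shape != (NIGHT_LEN,):
        raise ValueError(f"night axis must have length {NIGHT_LEN}")
    counts = np.convolve(s.astype(np.int32), np.ones(ROLL_WINDOW, dtype=np.int32), mode="valid")
    qualifying = np.flatnonzero(counts >= ROLL_THRESHOLD)
    if qualifying.size == 0:
        return None
    start = int(qualifying[0])
    inside = np.flatnonzero(s[start : start + ROLL_WINDOW])
    return start + int(inside[0])


def detect_offset(is_sleep: np.ndarray) -> int | None:
    """Last sleep minute within the latest qualifying backward 30-min window.

    The backward scan is the mirror image of :func:`detect_onset`: windows
    ``[e-29, e]`` roll back one minute at a time from 09:59 until one holds
    >= 15 sleep-wear minutes.
    """
    rev = np.asarray(is_sleep, dtype=bool)[::-1]
    mirrored = detect_onset(rev)
    if mirrored is None:
        return None
    return NIGHT_LEN - 1 - mirrored


def nightly_sleep_window(is_sleep: np.ndarray, participant_id=None, anchor_date=None):
    """Detect one night's (onset, offset, midpoint); None if undetectable.

    Returns a dict with ``onset``, ``offset`` (integer night-axis indices) and
    ``midpoint`` (may be half-integer), or None when either detector fails or
    they cross (offset < onset).
    """
    onset = detect_onset(is_sleep)
    if onset is None:
        return None
    offset = detect_offset(is_sleep)
    if offset is None or offset < onset:
        return None
    rec = {
        "onset": onset,
        "offset": offset,
        "midpoint": (onset + offset) / 2.0,
    }
    if participant_id is not None:
        rec["participant_id"] = participant_id
    if anchor_date is not None:
        rec["anchor_date"] = anchor_date
    return rec


def night_label_matrix(minutes: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray]:
    """Assemble per-night sleep-label rows from a minute table.

    Every minute with clock time in [20:00, 24:00) anchors to its own date,
    and [00:00, 10:00) to the previous date. Minutes absent from the record
    are treated as not-sleep. Returns (keys, labels): ``keys`` has one row per
    (participant_id, anchor_date); ``labels`` is the matching boolean matrix
    of shape (n_nights, 840).
    """
    t = minutes["timestamp"]
    mod = t.dt.hour * 60 + t.dt.minute
    evening = mod >= NIGHT_START_MINUTE
    morning = mod < 10 * 60
    in_window = evening | morning

    sub = minutes.loc[in_window]
    mod = mod[in_window]
    anchor = sub["timestamp"].dt.normalize() - pd.to_timedelta((mod < NIGHT_START_MINUTE).astype(int), unit="D")
    idx_in_night = np.where(mod >= NIGHT_START_MINUTE, mod - NIGHT_START_MINUTE, mod + (1440 - NIGHT_START_MINUTE))

    keys = pd.DataFrame({"participant_id": sub["participant_id"].to_numpy(), "anchor_date": anchor.to_numpy()})
    codes, uniques = pd.factorize(pd.MultiIndex.from_frame(keys))
    labels = np.zeros((len(uniques), NIGHT_LEN), dtype=bool)
    is_sleep = (sub["wear_class"] == SLEEP_WEAR).to_numpy()
    labels[codes, idx_in_night] = is_sleep
    key_df = pd.DataFrame(uniques.to_list(), columns=["participant_id", "anchor_date"])
    return key_df, labels


def nightly_sleep_windows(minutes: pd.DataFrame) -> pd.DataFrame:
    """Run the detectors on every participant-night of a minute table.

    Nights on which no sleep bout is detectable are dropped (they contribute
    nothing to the averages). Returns columns participant_id, anchor_date,
    onset, offset, midpoint (night-axis units).
    """
    keys, labels = night_label_matrix(minutes)
    rows = []
    for i in range(len(keys)):
        rec = nightly_sleep_window(labels[i])
        if rec is None:
            continue
        rows.append(
            {
                "participant_id": keys.at[i, "participant_id"],
                "anchor_date": keys.at[i, "anchor_date"],
                **rec,
            }
        )
    cols = ["participant_id", "anchor_date", "onset", "offset", "midpoint"]
    if not rows:
        return pd.DataFrame(columns=cols)
    return pd.DataFrame(rows)[cols].sort_values(["participant_id", "anchor_date"]).reset_index(drop=True)


def summarize_sleep(windows: pd.DataFrame) -> pd.DataFrame:
    """Per-participant sleep-timing summary.

    Onset and offset are averaged arithmetically on the 20:00-anchored night
    axis (the search window precludes wrap-around), and the overall midpoint
    is the midpoint of the two averages. The weekend midpoint is computed the
    same way over nights anchored on a Friday or Saturday, and is missing for
    participants with no such night.
    """

    def _one(g: pd.DataFrame) -> pd.Series:
        mean_onset = g["onset"].mean()
        mean_offset = g["offset"].mean()
        wk = g[pd.to_datetime(g["anchor_date"]).dt.dayofweek.isin([4, 5])]
        if len(wk):
            weekend_mid = (wk["onset"].mean() + wk["offset"].mean()) / 2.0
        else:
            weekend_mid = np.nan
        return pd.Series(
            {
                "mean_onset": mean_onset,
                "mean_offset": mean_offset,
                "overall_midpoint": (mean_onset + mean_offset) / 2.0,
                "weekend_midpoint": weekend_mid,
                "n_nights": len(g),
            }
        )

    if windows.empty:
        return pd.DataFrame(
            columns=["participant_id", "mean_onset", "mean_offset", "overall_midpoint", "weekend_midpoint", "n_nights"]
        )
    out = windows.groupby("participant_id", observed=True).apply(_one, include_groups=False).reset_index()
    out["n_nights"] = out["n_nights"].astype(int)
    return out


def axis_to_clock_minutes(axis_index) -> np.ndarray:
    """Convert a night-axis position to minutes after midnight (mod 1440)."""
    return np.mod(np.asarray(axis_index, dtype=float) + NIGHT_START_MINUTE, 1440.0)


def format_clock(minutes_after_midnight) -> str:
    """Format fractional minutes after midnight as HH:MM:SS (24 h)."""
    total = float(minutes_after_midnight) % 1440.0
    seconds = int(round(total * 60))
    h, rem = divmod(seconds, 3600)
    m, s = divmod(rem, 60)
    return f"{h % 24:02d}:{m:02d}:{s:02d}"


def write_sleep_tables(windows: pd.DataFrame, summary: pd.DataFrame, nights_path, summary_path) -> None:
    """Write per-night and per-participant sleep tables as TSV with clock strings."""
    w = windows.copy()
    for col, src in [("onset_clock", "onset"), ("offset_clock", "offset"), ("midpoint_clock", "midpoint")]:
        w[col] = [format_clock(v) for v in axis_to_clock_minutes(w[src])]
    w[["participant_id", "anchor_date", "onset_clock", "offset_clock", "midpoint_clock"]].to_csv(
        nights_path, sep="\t", index=False
    )

    s = summary.copy()
    for col, src in [
        ("mean_onset_clock", "mean_onset"),
        ("mean_offset_clock", "mean_offset"),
        ("overall_midpoint_clock", "overall_midpoint"),
    ]:
        s[col] = [format_clock(v) for v in axis_to_clock_minutes(s[src])]
    s["weekend_midpoint_clock"] = [
        format_clock(axis_to_clock_minutes(v)) if np.isfinite(v) else "" for v in s["weekend_midpoint"]
    ]
    s.to_csv(summary_path, sep="\t", index=False)
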